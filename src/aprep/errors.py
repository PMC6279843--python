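"""Exception types used across the package."""


class AprepError(Exception):
    """Base class for package-specific errors."""


class NonTilingError(AprepError, ValueError):
    """A particle-cell set that was required to tile the image does not."""


class UnsupportedVersionError(AprepError, RuntimeError):
    """An APR file was written with an unknown format version."""


class ResourceGuardError(AprepError, RuntimeError):
    """A brute-force oracle was asked to run on a domain too large for it."""


class InternalInconsistencyError(AprepError, RuntimeError):
    """An internal invariant of the representation was violated."""
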