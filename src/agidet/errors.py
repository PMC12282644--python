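"""Exception hierarchy shared across the package."""


class AgidetError(Exception):
    """Base class for all package errors."""


class FormatError(AgidetError):
    """A file or payload does not match the expected format."""


class DataError(AgidetError):
    """Well-formed input violates a domain invariant."""


class ConfigError(AgidetError):
    """A configuration object is internally inconsistent or infeasible."""


class ProtocolError(AgidetError):
    """An evaluation protocol cannot be carried out on the given data."""


class ContractError(AgidetError):
    """Caller violated an API contract (mismatched manifests, splits, ...)."""
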