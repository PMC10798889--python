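"""Error hierarchy shared across the package."""


class CsfsubError(Exception):
    """Base class for all package-specific errors."""


class LayoutMismatchError(CsfsubError):
    """A channel key in a matrix does not line up with the plex layout."""


class DuplicateRecordError(CsfsubError):
    """An identifier that must be unique occurs more than once."""


class DomainError(CsfsubError):
    """A value is outside the domain an operation is defined on."""


class ContractError(CsfsubError):
    """A caller violated an operation's precondition."""


class DegenerateChannelError(CsfsubError):
    """A channel cannot be scaled (e.g. zero median)."""


class ConfigError(CsfsubError):
    """An invalid simulation or pipeline configuration."""
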