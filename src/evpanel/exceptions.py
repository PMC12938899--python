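"""Error hierarchy shared by all pipeline stages.

The CLI maps these onto exit codes: :class:`ConfigurationError` -> 2,
:class:`DataIntegrityError` (and subclasses) -> 3.
"""


class EvPanelError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EvPanelError, ValueError):
    """An invalid parameter, threshold, or pipeline configuration."""


class DataIntegrityError(EvPanelError, ValueError):
    """Input data violates a structural contract (missing controls, bad values)."""


class InsufficientDataError(DataIntegrityError):
    """Too few observations for the requested statistical operation."""


class ContractError(EvPanelError, TypeError):
    """An object was used outside its documented contract (e.g. VIP on a PCA model)."""
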