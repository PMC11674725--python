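"""Exception hierarchy."""


class BremspectError(Exception):
    """Base class for all package errors."""


class GeometryError(BremspectError):
    """Invalid phantom geometry (overlapping or out-of-body inserts)."""


class ExtentError(BremspectError):
    """Voxel grid does not enclose the phantom."""


class DomainError(BremspectError):
    """Argument outside the modelled physical range."""


class AlignmentError(BremspectError):
    """Arrays defined on mismatched grids."""


class DegenerateInputError(BremspectError):
    """Input is formally valid but carries no information (e.g. zero counts)."""


class ConfigurationError(BremspectError):
    """Inconsistent correction flags / missing model components."""


class AggregationError(BremspectError):
    """Repetition results with mismatched keys cannot be aggregated."""
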