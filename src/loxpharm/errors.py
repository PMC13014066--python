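"""Exception hierarchy shared across the package."""


class LoxPharmError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(LoxPharmError):
    """A PDB file could not be parsed."""


class EmptyInputError(LoxPharmError):
    """An input file or collection was empty where content is required."""


class ChainNotFoundError(LoxPharmError, KeyError):
    """A requested chain id is absent from the model."""


class DegenerateFitError(LoxPharmError):
    """Too few atom pairs to determine a rigid superposition."""


class ConsistencyError(LoxPharmError):
    """Model contents contradict supplied reference information."""


class AnchorFailureError(LoxPharmError):
    """No valid anchor window could be found beside a gap."""


class IncompleteDonorError(LoxPharmError):
    """A donor structure lacks atoms needed for a graft segment."""


class EnsembleError(LoxPharmError):
    """Frames of an ensemble disagree on atom inventory."""


class UndefinedMetricError(LoxPharmError):
    """A benchmark metric is undefined for the given inputs."""
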