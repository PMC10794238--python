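"""Exception hierarchy shared across the pipeline stages."""


class TcsEvoError(Exception):
    """Base class for all package-specific errors."""


class InputError(TcsEvoError):
    """Missing or empty input."""


class AlignmentFormatError(TcsEvoError):
    """Ragged or otherwise malformed alignment."""


class ConfigurationError(TcsEvoError):
    """Invalid configuration value (ranges, thresholds, backgrounds...)."""


class EmptyAlignmentError(TcsEvoError):
    """Filtering removed every sequence."""


class DegenerateColumnError(TcsEvoError):
    """A column contains no observed (non-gap) residues."""


class NumericGuardError(TcsEvoError):
    """A frequency hit an exact 0/1 boundary where a logarithm is required."""


class FitError(TcsEvoError):
    """Too few usable histogram bins for the spectrum fit."""


class SelectionError(TcsEvoError):
    """Requested chain/residue absent from the structure."""


class MappingError(TcsEvoError):
    """Alignment-to-structure mapping is not monotone / inconsistent."""


class NoContactError(TcsEvoError):
    """Frustration requested at a position with no incident contacts."""


class DegenerateDecoyError(TcsEvoError):
    """Decoy energy distribution has zero variance."""


class DegenerateEnsembleError(TcsEvoError):
    """Conformation-ensemble energies have zero variance."""


class GenerationError(TcsEvoError):
    """A synthetic generator exhausted its attempt budget."""


class SpecError(TcsEvoError):
    """Contradictory synthetic-data specification."""


class DecoyFormatError(TcsEvoError):
    """Malformed decoy exchange file."""


class InitializationError(TcsEvoError):
    """Could not build a valid initial population."""


class UndefinedCorrelationError(TcsEvoError):
    """Correlation undefined (constant profile or too few shared positions)."""
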