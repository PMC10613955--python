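"""Exception hierarchy for study validation, I/O and pipeline failures."""


class ShiftcalError(Exception):
    """Base class for all shiftcal errors."""


class IncompleteConformerError(ShiftcalError):
    """A conformer is missing an atom required by an equivalence group."""


class AssignmentInconsistencyError(ShiftcalError):
    """Assignment table disagrees with atom elements or group key sets."""


class DuplicateGroupError(ShiftcalError):
    """Two equivalence groups share one group_id."""


class MalformedLogError(ShiftcalError):
    """An engine log violates the expected shielding-block layout."""


class FormatError(ShiftcalError):
    """An interchange table violates its schema."""


class EmptyStudyError(ShiftcalError):
    """A study bundle with no conformers or no groups."""


class EmptyEnsembleError(ShiftcalError):
    """Window filtering or weighting applied to an empty conformer set."""


class InvalidTemperatureError(ShiftcalError):
    """Non-positive temperature passed to Boltzmann weighting."""


class UnderdeterminedError(ShiftcalError):
    """Fewer than two points supplied to the scaling regression."""


class DegenerateRegressionError(ShiftcalError):
    """Zero variance in the predictor, or a zero fitted slope."""


class EmptyMetricsError(ShiftcalError):
    """Error statistics requested for an empty deviation set."""


class InvalidSelectionError(ShiftcalError):
    """top-k selection with k exceeding the number of screened cells."""


class InvalidGeneratorSpecError(ShiftcalError):
    """Synthetic-study generator spec with inadmissible field values."""
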