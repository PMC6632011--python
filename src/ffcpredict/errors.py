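"""Exception hierarchy shared across the pipeline."""


class FFCPredictError(Exception):
    """Base class for all package errors."""


class FormatError(FFCPredictError):
    """An input file does not follow the expected dialect."""


class EmptyInputError(FFCPredictError):
    """An input contains no usable rows after validation."""


class ConfigurationError(FFCPredictError):
    """A configuration value is out of range or names an unknown entity."""


class InsufficientDataError(FFCPredictError):
    """A signal or segment is too short for the requested operation."""


class LayoutError(FFCPredictError):
    """Descriptor layouts of participants or models do not match."""


class ProtocolError(FFCPredictError):
    """The evaluation protocol's structural preconditions are violated."""


class DegenerateTrainingError(FFCPredictError):
    """A training set contains a single class where two are required."""
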