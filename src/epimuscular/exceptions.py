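"""Exception hierarchy shared by all modules."""


class ModelError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(ModelError, ValueError):
    """A numeric input is non-finite or otherwise unusable."""


class ParameterError(ModelError, ValueError):
    """A model parameter is outside its admissible range."""


class StructuralError(ModelError, ValueError):
    """Two objects that must share structure (positions, breakpoints,
    channels, pathways) do not."""


class ExtrapolationError(ModelError, ValueError):
    """A relative position falls outside the displacement span covered by
    the fitted stiffness segments.  Extrapolation is never silent."""


class ExtractionError(ModelError, ValueError):
    """Isometric force extraction from a waveform is impossible with the
    requested window."""


class InsufficientDataError(ModelError, ValueError):
    """Too few samples for the requested statistic."""
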