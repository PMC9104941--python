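"""Exception types shared across the toolkit."""


class RadarVitalsError(Exception):
    """Base class for all toolkit errors."""


class InvalidArgumentError(RadarVitalsError, ValueError):
    """A parameter violates its contract."""


class AliasingError(InvalidArgumentError):
    """A requested frequency exceeds the Nyquist limit of the sampling rate."""


class LengthError(RadarVitalsError, ValueError):
    """An input sequence has the wrong length or shape."""


class NoTargetError(RadarVitalsError):
    """Range-bin selection found no energy in any bin."""


class CannotSynthesizeError(RadarVitalsError):
    """Too few peaks to reconstruct a heartbeat train."""


class SingleClassError(RadarVitalsError):
    """Training was requested on a dataset containing only one class."""
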