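"""Exception hierarchy shared by all luces modules."""


class LucesError(Exception):
    """Base class for all package errors."""


class ArgumentError(LucesError, ValueError):
    """An operation was called with inconsistent or out-of-range arguments."""


class ConfigError(LucesError):
    """A scenario / pipeline configuration is missing keys or infeasible."""


class FormatError(LucesError):
    """A file does not conform to the expected on-disk format."""


class TrainingError(LucesError):
    """Suitability-model training failed (e.g. non-finite loss)."""


class SimulationError(LucesError):
    """The cellular-automata allocation cannot satisfy its demand."""
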