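"""Exception types shared across the pipeline."""


class MesocamError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MesocamError):
    """A config file, schema mapping, or parameter set is invalid."""


class EmptyInputError(MesocamError):
    """An input file or table contained no usable rows."""


class DataConsistencyError(MesocamError):
    """Inputs contradict each other (e.g. detections with zero effort)."""


class SolarEventMissing(MesocamError):
    """The sun never crosses the requested altitude on the given date."""
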