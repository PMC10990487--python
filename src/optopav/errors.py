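"""Exception hierarchy for the optopav pipeline.

Every stage raises a subclass of :class:`OptoPavError` so that the pipeline
driver can abort with the stage name and context attached.
"""


class OptoPavError(Exception):
    """Base class for all optopav errors."""


class ConfigError(OptoPavError):
    """Invalid task or pipeline configuration."""


class ScheduleError(OptoPavError):
    """Trial-schedule generation failed (e.g. infeasible run-length constraint)."""


class SimulationError(OptoPavError):
    """Forward simulation produced an invalid trace (e.g. non-positive fluorescence)."""


class DegenerateFitError(OptoPavError):
    """Isosbestic regression is undefined (constant control channel)."""


class PreprocessError(OptoPavError):
    """dF/F0 computation or filtering failed."""


class AlignmentError(OptoPavError):
    """Peri-event alignment produced no usable trials."""


class AnalysisError(OptoPavError):
    """AUC / kinetics computation received invalid inputs."""


class StatsError(OptoPavError):
    """Statistical test received an invalid design (missing cells, n too small)."""


class IOFormatError(OptoPavError):
    """A serialized schedule/trace/config file is malformed."""
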