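"""Exception hierarchy for the spherolec pipeline."""


class SpherolecError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpherolecError, ValueError):
    """Invalid parameter or configuration value."""


class CalibrationError(SpherolecError, ValueError):
    """Voxel calibration missing or inconsistent."""


class GridMismatchError(SpherolecError, ValueError):
    """Operands live on different grids or calibrations."""


class UndefinedStatisticError(SpherolecError, ArithmeticError):
    """A statistic is undefined for the given input (e.g. division by zero)."""


class PipelineStageError(SpherolecError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
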