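"""Exception hierarchy shared across the package."""


class DentalCascadeError(Exception):
    """Base class for all package-specific errors."""


class InvalidMeasurementError(DentalCascadeError, ValueError):
    """A morphometric quantity violated its physical domain (e.g. area <= 0)."""


class SchemaError(DentalCascadeError, ValueError):
    """A tabular input failed schema validation; message names the row."""


class SimulationError(DentalCascadeError, RuntimeError):
    """The reaction-diffusion integrator detected an unstable or invalid state."""


class PipelineStageError(DentalCascadeError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
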