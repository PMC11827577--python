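"""Exception hierarchy shared across the pipeline stages."""


class PhenosyncError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PhenosyncError, ValueError):
    """A simulator or stage configuration violates its invariants."""


class CoverageError(PhenosyncError, ValueError):
    """Required input (weather days, DEM extent) does not cover a request."""


class DegenerateSeriesError(PhenosyncError, ValueError):
    """A series is flat or a pool has zero range where variation is required."""


class MissingWindowError(PhenosyncError, ValueError):
    """A window-open component required by the WO composite is absent."""


class SchemaError(PhenosyncError, ValueError):
    """An input table does not match the expected schema."""


class SampleSizeError(PhenosyncError, ValueError):
    """Too few observations for the requested fit."""


class FitError(PhenosyncError, ValueError):
    """A smoothing/regression fit cannot be carried out as configured."""
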