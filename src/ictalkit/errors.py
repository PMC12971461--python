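"""Exception hierarchy shared across the toolkit.

All errors derive from :class:`IctalkitError` so callers can catch the
package's failures with one clause while still distinguishing bad user
parameters from malformed data.
"""


class IctalkitError(Exception):
    """Base class for all ictalkit errors."""


class SpecError(IctalkitError, ValueError):
    """A synthetic-data specification violates its invariants."""


class ParameterError(IctalkitError, ValueError):
    """An analysis parameter is out of its valid domain."""


class ScheduleError(SpecError):
    """Scheduled ictal events overlap or fall outside the recording."""


class PlacementError(SpecError):
    """Synthetic puncta could not be placed without overlap."""


class MontageError(IctalkitError, ValueError):
    """Channel labels cannot be mapped onto the canonical montage."""


class ClassificationError(IctalkitError, ValueError):
    """A feature needed by the seizure classifier is missing or invalid."""


class UndefinedFeatureError(IctalkitError, ValueError):
    """A biomarker is undefined for the given input (e.g. all-zero PSD)."""
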