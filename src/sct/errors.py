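"""Exception hierarchy for the SCT toolkit.

All errors derive from :class:`SCTError` (itself a ``ValueError``) so callers
can catch the whole family or any specific failure mode.
"""


class SCTError(ValueError):
    """Base class for all SCT model errors."""


class GeometryError(SCTError):
    """A physical dimension is non-positive or inconsistent (e.g. a tip as
    wide as the cell it is meant to aspirate)."""


class EquilibriumError(SCTError):
    """The sealed-headspace balance has no real solution (negative
    discriminant of the rise quadratic)."""


class ModelViolationError(SCTError):
    """The balance has roots, but none in the physically admissible band
    ``0 < h2 < dP/(rho*g)``."""


class HeadspaceExhaustedError(SCTError):
    """The aspirated column would consume the entire sealed gas volume."""


class SamplingError(SCTError):
    """Negative sampled volume: final fluid length shorter than the
    pre-sampling length."""


class GridError(SCTError):
    """Design-space grid with an empty axis."""


class TrialError(SCTError):
    """A trial row violates the count invariants (e.g. target count of
    zero, released exceeding captured)."""


class RankDeficiencyError(SCTError):
    """Least-squares fit requested on degenerate abscissae."""


class NoInformationError(SCTError):
    """Estimator called on a table carrying no spiked cells."""


class ConfigError(SCTError):
    """Invalid configuration: unknown key, bad unit, or non-physical value.
    The message always names the offending key."""
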