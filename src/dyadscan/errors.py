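"""Exception hierarchy for dyadscan.

All package-specific failures derive from :class:`DyadscanError` so callers
(and the CLI) can map them onto exit codes: validation problems exit 2,
degenerate statistics exit 3.
"""


class DyadscanError(Exception):
    """Base class for all dyadscan errors."""


class SchemaError(DyadscanError):
    """The input table does not conform to the cohort schema."""


class CohortValidationError(DyadscanError):
    """Row-level or table-level validation failure."""


class SampleSizeError(DyadscanError):
    """A model subset is too small to fit the requested model."""


class DegenerateTableError(DyadscanError):
    """A dyad table has an empty case or control margin."""


class DegenerateEstimateError(DyadscanError):
    """An effect estimate is zero/infinite; a continuity mode may help."""


class RankDeficiencyError(DyadscanError):
    """Design matrix is rank deficient; message names collinear terms."""


class SeparationError(DyadscanError):
    """Perfect separation in a logistic fit; Wald statistics are invalid."""


class ConvergenceError(DyadscanError):
    """Iterative fit failed to converge within the iteration cap."""


class UnknownScenarioError(DyadscanError):
    """Unknown simulation preset name; message lists valid presets."""


class SimulationError(DyadscanError):
    """The simulator could not satisfy its target within its iteration cap."""
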