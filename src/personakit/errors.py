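"""Exception hierarchy for personakit."""


class PersonakitError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PersonakitError):
    """A value, column, or declaration violates the survey schema."""


class FormatError(PersonakitError):
    """An input file could not be parsed."""


class ConfigurationError(PersonakitError):
    """A rule, override, or generator configuration is invalid."""


class UndefinedDistanceError(PersonakitError):
    """All variables are missing in a record pair under pairwise deletion."""


class InfeasibleError(PersonakitError):
    """A clustering request cannot be satisfied (e.g. K exceeds distinct records)."""


class UndefinedSilhouetteError(PersonakitError):
    """Silhouette requested with fewer than two clusters present."""


class InconsistencyError(PersonakitError):
    """Observed counts contradict the marginal counts they must respect."""
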