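"""Exception hierarchy shared across the package."""


class StadnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StadnetError):
    """A run was configured inconsistently (missing columns, bad flags...)."""


class DataError(StadnetError):
    """The input data violates an invariant (duplicate ranks, unmapped codes...)."""


class DegenerateCohortError(DataError):
    """No pair of profiles in the cohort shares a single code, so the
    similarity matrix cannot be normalized into a distance matrix."""
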