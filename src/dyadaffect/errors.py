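"""Exception taxonomy shared across the pipeline."""


class DyadAffectError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(DyadAffectError, ValueError):
    """An argument violates an operation's precondition."""


class QualityError(DyadAffectError):
    """A signal segment is unusable (too few events, no excursions, ...).

    Dataset assembly treats a quality failure in any segment as grounds
    for excluding the whole dyad, mirroring dyad-level exclusion for
    noisy recordings in human studies.
    """


class SchemaError(DyadAffectError):
    """Feature-name sets disagree where they must match."""


class FormatError(DyadAffectError):
    """A recording directory or manifest is malformed."""


class UndefinedValueError(DyadAffectError):
    """A requested statistic is undefined for the given input."""
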