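"""Exception hierarchy shared across the package."""


class PicosearchError(Exception):
    """Base class for all package-specific errors."""


class InvalidTermError(PicosearchError, ValueError):
    """A search term is blank or all-whitespace."""


class InvalidQuestionError(PicosearchError, ValueError):
    """A PICO question violates its invariants (e.g. empty population)."""


class UnsupportedStrategyError(PicosearchError, ValueError):
    """The operation cannot render this strategy (related-articles searches
    have no query text; their outputs are supplied externally or simulated)."""


class NotEvaluableError(PicosearchError, ValueError):
    """The gold standard has no PubMed-indexed article, so no search can be
    scored against it."""


class InvalidCutoffError(PicosearchError, ValueError):
    """Screening cutoff is not a positive integer (or the literal 'full')."""


class UndefinedNNRError(PicosearchError, ZeroDivisionError):
    """PPV is zero: no relevant article in the screened output, so the
    number needed to read is undefined."""


class SchemaError(PicosearchError, ValueError):
    """An input file violates its declared schema."""


class IntegrityError(PicosearchError, ValueError):
    """An input file is schema-valid but internally inconsistent
    (duplicate ranks, outputs without a gold standard, ...)."""


class CorruptedFixtureError(PicosearchError, RuntimeError):
    """The packaged benchmark fixture does not match its embedded digest."""


class ConfigError(PicosearchError, ValueError):
    """A simulation configuration violates its invariants."""
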