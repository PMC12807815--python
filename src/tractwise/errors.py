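"""Exception hierarchy for tractwise.

All errors raised deliberately by the package derive from
:class:`TractwiseError`, so callers can catch one base class at pipeline
boundaries while tests can assert on the specific subclass.
"""


class TractwiseError(Exception):
    """Base class for all tractwise errors."""


class ValidationError(TractwiseError, ValueError):
    """A specification or argument violates a documented invariant."""


class ParseError(TractwiseError, ValueError):
    """A data file is malformed; the message names the offending row."""


class DegenerateInputError(TractwiseError, ValueError):
    """Input is formally valid but the statistic is undefined on it
    (e.g. zero residual variance, all-zero eigenvalues)."""


class CollinearityError(TractwiseError, ValueError):
    """Covariate matrix is rank-deficient after adding an intercept."""


class SampleSizeError(TractwiseError, ValueError):
    """Too few usable observations for the requested analysis."""


class SchemaError(TractwiseError, ValueError):
    """A required column is missing from a subject or profile table."""


class ConfigurationError(TractwiseError, ValueError):
    """A study configuration file is invalid or incomplete."""
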