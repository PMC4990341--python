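"""Exception hierarchy shared across seqfx modules."""


class SeqfxError(Exception):
    """Base class for all seqfx errors."""


class FormatError(SeqfxError, ValueError):
    """A file does not conform to the expected schema."""


class ValidationError(SeqfxError, ValueError):
    """Data violate a documented invariant (e.g. a choice outside {0, 1})."""


class InsufficientDataError(SeqfxError, ValueError):
    """Too few trials for the requested operation."""


class DegenerateDataError(SeqfxError, ValueError):
    """Data carry no information for the requested fit (e.g. constant responses)."""


class RegimeError(SeqfxError, ValueError):
    """A cross-validation regime's preconditions are not met."""
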