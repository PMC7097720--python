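"""Exception hierarchy.

Data outcomes (an NDC unknown to the terminology, a pair removed during
cleaning) are *not* exceptions; exceptions mark contract violations or
infrastructure failures.
"""


class RxMatchError(Exception):
    """Base class for all rxmatch errors."""


class ValidationError(RxMatchError):
    """A raw NDC string cannot be normalized to the 11-digit 5-4-2 form.

    ``code`` is a stable machine-readable reason:

    - ``non_digit``         non-digit content outside hyphens
    - ``segment_count``     not exactly three hyphenated segments
    - ``segment_lengths``   segment lengths match no known dialect
    - ``length``            unhyphenated input is not 10 or 11 digits
    - ``ambiguous_10_digit`` unhyphenated 10-digit code, dialect unknowable
    - ``empty``             blank after trimming
    - ``internal_space``    whitespace inside the code
    """

    def __init__(self, message: str, code: str = "invalid"):
        super().__init__(message)
        self.code = code


class FormatError(RxMatchError):
    """An input record file is missing required columns or is unreadable."""


class BackendUnavailable(RxMatchError):
    """The live terminology service could not be reached after retries."""


class ResolutionError(RxMatchError):
    """A non-clinical-level concept has no related clinical drug concept."""


class UnknownConcept(RxMatchError):
    """An rxcui does not exist in the terminology snapshot."""


class AttributeUnavailable(RxMatchError):
    """A curated clinical drug concept lacks structured attributes."""


class ConfigError(RxMatchError):
    """A generator or run configuration violates its invariants."""


class GenerationError(RxMatchError):
    """The synthetic terminology lacks a concept needed for a requested error category."""
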