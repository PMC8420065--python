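"""Exception hierarchy for the emtrn pipeline."""


class EmtrnError(Exception):
    """Base class for all emtrn errors."""


class FormatError(EmtrnError):
    """A file does not conform to the expected tabular format."""


class ParameterError(EmtrnError):
    """A parameter value is outside its admissible range."""


class IntegrityError(EmtrnError):
    """Cross-referenced identifiers are inconsistent between tables."""


class InvariantError(EmtrnError):
    """An internal invariant of a domain object is violated."""
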