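"""Exception hierarchy shared across the package."""


class EvoIndexError(Exception):
    """Base class for all evoindex errors."""


class ValidationError(EvoIndexError):
    """An input table or parameter violates a documented invariant."""


class ParseError(EvoIndexError):
    """A file could not be parsed in the declared dialect."""


class UndefinedIndexError(EvoIndexError):
    """A weighted index has no defined value (all weights zero / all values missing)."""


class UltrametricityError(EvoIndexError):
    """A tree is not ultrametric within tolerance; carries the worst deviation."""

    def __init__(self, message: str, worst_deviation: float = float("nan")):
        super().__init__(message)
        self.worst_deviation = worst_deviation
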