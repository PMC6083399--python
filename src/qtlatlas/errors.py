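"""Exception hierarchy shared across the pipeline stages."""


class QtlAtlasError(Exception):
    """Base class for all package errors."""


class InputError(QtlAtlasError):
    """Malformed or inconsistent user-supplied input."""


class ParameterError(QtlAtlasError):
    """A numeric or structural parameter outside its valid range."""


class GenerationError(QtlAtlasError):
    """A synthetic-data request that cannot be satisfied (e.g. genome too
    short for the requested amplicons, or an unsatisfiable overlap spec)."""


class Gff3ParseError(InputError):
    """GFF3 syntax problem, carrying the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"GFF3 line {lineno}: {message}")
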