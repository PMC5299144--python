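"""Exception hierarchy shared across the toolkit."""


class GosemtkError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(GosemtkError, ValueError):
    """A structural contract was violated (cycles, multiple roots, bad metadata)."""


class DomainError(GosemtkError, ValueError):
    """Arguments are outside the mathematical domain of an operation."""


class UnknownTermError(DomainError, KeyError):
    """A term accession does not resolve in the ontology graph."""

    def __init__(self, term_id: str):
        super().__init__(f"unknown term id: {term_id!r}")
        self.term_id = term_id


class UnscoredTermError(DomainError):
    """A term has no occurrence count and therefore no information content."""

    def __init__(self, term_id: str):
        super().__init__(
            f"term {term_id!r} has zero corpus occurrences and no information content"
        )
        self.term_id = term_id
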