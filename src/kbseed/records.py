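"""Model-independent intermediate containers shared by connectors and the
integration engine: typed values, per-record selector results, SQL result
tables and SPARQL SELECT result sets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple


class Term(NamedTuple):
    """A selected value with its term kind (``literal``, ``uri`` or ``bnode``).

    CSV/XML/SQL values are always literals; SPARQL bindings keep the kind of
    the original RDF term so triplification can replicate it.
    """

    text: str
    kind: str = "literal"


@dataclass
class SkipRecord:
    """One source row/record that was skipped, and why."""

    index: int
    reason: str


@dataclass
class RecordSet:
    """Connector output: one record per source row/node/solution.

    A record maps selector position (index into ``selectors`` of the driving
    resource) to the list of :class:`Term` values that selector produced for
    the record — possibly empty, never missing.
    """

    records: list[dict[int, list[Term]]] = field(default_factory=list)
    source_uri: str = ""
    skips: list[SkipRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ResultTable:
    """A SQL query result: column names plus rows of optional strings."""

    columns: list[str]
    rows: list[list[str | None]]


@dataclass
class SparqlResults:
    """A SPARQL SELECT/ASK result set in lexical form."""

    vars: list[str] = field(default_factory=list)
    rows: list[dict[str, Term]] = field(default_factory=list)
    boolean: bool | None = None  # ASK result
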