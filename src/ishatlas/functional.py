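"""GO fold enrichment between gene lists and morbidmap disease linkage.

Fold enrichment compares two gene lists A and B term by term: the
percentage of A carrying a GO term divided by the percentage of B carrying
it.  A fold above 1 indicates over-representation in A, below 1
under-representation.  No significance testing or multiple-testing
correction is layered on top — the statistic is the raw percentage ratio —
and GO ancestry is not propagated: each gene's terms are taken as listed.

Morbidmap linkage joins a gene list against an OMIM-morbidmap-style
disorder table; multi-gene rows are indexed under every listed symbol.
"""
from __future__ import annotations

import dataclasses
import logging
import math
import re
from collections.abc import Iterable, Mapping
from pathlib import Path

import pandas as pd

from .annotation import canonical_gene
from .levels import round_pct
from .sieve import GeneList

logger = logging.getLogger(__name__)

#: GO aspect aliases -> canonical single-letter code.
_ASPECTS = {
    "f": "F", "mf": "F", "molecular_function": "F",
    "p": "P", "bp": "P", "biological_process": "P",
    "c": "C", "cc": "C", "cellular_component": "C",
}

_TERM_ID_RE = re.compile(r"^GO:\d{7}$")


@dataclasses.dataclass(frozen=True)
class GOTerm:
    term_id: str
    name: str = ""
    aspect: str = "F"

    def __post_init__(self) -> None:
        if not _TERM_ID_RE.match(self.term_id):
            raise ValueError(f"malformed GO term id: {self.term_id!r}")
        if self.aspect not in {"F", "P", "C"}:
            raise ValueError(f"unknown GO aspect: {self.aspect!r}")


class GOTable:
    """Mapping canonical gene id -> set of :class:`GOTerm`.

    A gene absent from the table, or present with an empty term set,
    counts as "NoGO" (no assigned GO term).
    """

    def __init__(self, mapping: Mapping[str, Iterable[GOTerm]] | None = None) -> None:
        self._terms: dict[str, frozenset] = {}
        for gene, terms in (mapping or {}).items():
            self._terms[canonical_gene(gene)] = frozenset(terms)

    def terms(self, gene: str, aspect: str | None = None) -> frozenset:
        out = self._terms.get(canonical_gene(gene), frozenset())
        if aspect is not None:
            code = normalize_aspect(aspect)
            out = frozenset(t for t in out if t.aspect == code)
        return out

    def has_terms(self, gene: str) -> bool:
        return bool(self._terms.get(canonical_gene(gene)))

    @property
    def genes(self) -> set:
        return set(self._terms)

    def __len__(self) -> int:
        return len(self._terms)


def normalize_aspect(aspect: str) -> str:
    try:
        return _ASPECTS[aspect.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown GO aspect: {aspect!r}") from None


def load_go_table(path: str | Path) -> GOTable:
    """Load a gene->GO TSV: ``gene<TAB>term_id<TAB>term_name<TAB>aspect``.

    A row with an empty term id records the gene with no terms (explicit
    NoGO entry).  ``#`` comment lines allowed.
    """
    mapping: dict[str, set] = {}
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields")
            gene, term_id, name, aspect = fields
            bucket = mapping.setdefault(gene, set())
            if term_id:
                bucket.add(GOTerm(term_id, name, normalize_aspect(aspect)))
    return GOTable(mapping)


@dataclasses.dataclass(frozen=True)
class EnrichmentRecord:
    """Per-term comparison of two gene lists by percentage ratio."""

    term: GOTerm
    count_a: int
    count_b: int
    pct_a: float
    pct_b: float
    fold: float  # math.inf when pct_b == 0 < pct_a

    @property
    def fold_defined(self) -> bool:
        return math.isfinite(self.fold)


def fold_enrichment(
    list_a: GeneList,
    list_b: GeneList,
    go: GOTable,
    aspect: str | None = "molecular_function",
    sort: str = "desc",
    include_undefined: bool = False,
    min_pct: float = 0.0,
) -> list[EnrichmentRecord]:
    """Fold enrichment of every GO term attached to a gene of A or B.

    ``fold = pct_A / pct_B`` with ``pct_X = 100 * count_X / |X|``; terms
    absent from B but present in A get an infinite-fold flag and are
    excluded from the ranking unless `include_undefined` is set.  The
    aspect filter defaults to molecular function; pass ``None`` for all
    aspects.  `min_pct` is a display threshold: keep terms reaching that
    percentage in at least one list.
    """
    if len(list_a) == 0 or len(list_b) == 0:
        raise ValueError("both gene lists must be non-empty")
    code = None if aspect is None else normalize_aspect(aspect)
    terms: set = set()
    for gene in set(list_a.members) | set(list_b.members):
        terms |= go.terms(gene, aspect=code)
    records = []
    for term in terms:
        count_a = sum(1 for g in list_a.members if term in go.terms(g))
        count_b = sum(1 for g in list_b.members if term in go.terms(g))
        pct_a = 100.0 * count_a / len(list_a)
        pct_b = 100.0 * count_b / len(list_b)
        fold = pct_a / pct_b if pct_b > 0 else math.inf
        records.append(
            EnrichmentRecord(term, count_a, count_b, pct_a, pct_b, fold)
        )
    records = [r for r in records if max(r.pct_a, r.pct_b) >= min_pct]
    if not include_undefined:
        records = [r for r in records if r.fold_defined]
    reverse = {"desc": True, "asc": False}[sort]
    records.sort(key=lambda r: (r.fold, r.term.term_id), reverse=reverse)
    return records


def enrichment_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    rows = [
        {
            "term_id": r.term.term_id,
            "term_name": r.term.name,
            "aspect": r.term.aspect,
            "count_a": r.count_a,
            "count_b": r.count_b,
            "pct_a": r.pct_a,
            "pct_b": r.pct_b,
            "fold": r.fold,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def nogo_fraction(genes: GeneList, go: GOTable) -> tuple[int, float]:
    """(count, percentage) of list genes with no assigned GO term.

    The percentage is relative to the list size, rounded to one decimal.
    """
    if len(genes) == 0:
        raise ValueError("gene list must be non-empty")
    count = sum(1 for g in genes.members if not go.has_terms(g))
    return count, round_pct(count, len(genes))


# -- morbidmap -------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MorbidRecord:
    disorder: str
    genes: tuple
    mim_number: str = ""
    cyto_location: str = ""


class MorbidMap:
    """Disorder records indexed by every associated gene symbol."""

    def __init__(self, records: Iterable[MorbidRecord] = ()) -> None:
        self.records = list(records)
        self._index: dict[str, list[MorbidRecord]] = {}
        for rec in self.records:
            for gene in rec.genes:
                self._index.setdefault(canonical_gene(gene), []).append(rec)

    def disorders(self, gene: str) -> list[MorbidRecord]:
        return list(self._index.get(canonical_gene(gene), []))

    def __len__(self) -> int:
        return len(self.records)


def load_morbidmap(path: str | Path) -> MorbidMap:
    """Parse a morbidmap-style table: ``disorder | gene symbols | MIM | cyto``.

    Fields are separated by `` | `` (pipe dialect) or tabs; gene symbols
    within a field are comma-separated.  Malformed records are skipped
    with a logged warning, not fatal.
    """
    records = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in (
                line.split("|") if "|" in line else line.split("\t")
            )]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                logger.warning("%s:%d: malformed morbidmap record, skipped", path, lineno)
                continue
            genes = tuple(g.strip() for g in fields[1].split(",") if g.strip())
            if not genes:
                logger.warning("%s:%d: record without gene symbols, skipped", path, lineno)
                continue
            mim = fields[2] if len(fields) > 2 else ""
            cyto = fields[3] if len(fields) > 3 else ""
            records.append(MorbidRecord(fields[0], genes, mim, cyto))
    return MorbidMap(records)


def disease_links(genes: GeneList, morbid: MorbidMap) -> pd.DataFrame:
    """Table of (gene, disorders) for the list genes with >=1 disorder.

    One row per gene; the ``disorders`` column holds the sorted disorder
    names; ``n_linked_genes`` is available as ``len(frame)``.
    """
    rows = []
    for gene in sorted(genes.members):
        recs = morbid.disorders(gene)
        if recs:
            rows.append(
                {
                    "gene": gene,
                    "n_disorders": len(recs),
                    "disorders": "; ".join(sorted({r.disorder for r in recs})),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "n_disorders", "disorders"])
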