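"""Gene x tissue annotation matrices: loading, validation, summary statistics.

The central container is :class:`AnnotationMatrix`, a dense gene x tissue
grid of five-state ordinal expression calls.  Every cell holds exactly one
state; "absent" is encoded explicitly as ``na`` (not analyzed), never by
omission.  Optional per-cell comments carry a small controlled keyword
vocabulary describing the spatial pattern (patchy, spotted, generalized)
plus free text; they are opaque metadata and enter no computation.
"""
from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from .levels import (
    ORDINAL_VALUE,
    STATE_ORDER,
    EXPRESSED_STATES,
    ExpressionLevel,
    parse_level,
    round_pct,
)

#: Controlled keyword vocabulary for expression-pattern comments.
CONTROLLED_KEYWORDS = frozenset({"patchy", "spotted", "generalized"})


class AnnotationError(ValueError):
    """Invalid annotation data (parse or validation failure)."""


def canonical_gene(gene: str) -> str:
    """Canonical form of a gene identifier, used for joins across modules.

    Case-insensitive matching; the original spelling is preserved for
    display wherever the matrix is written back out.
    """
    return gene.strip().casefold()


@dataclasses.dataclass(frozen=True)
class Tissue:
    """A tissue/structure of the annotation panel."""

    tissue_id: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.tissue_id:
            raise AnnotationError("tissue_id must be non-empty")


@dataclasses.dataclass(frozen=True)
class Comment:
    """Optional per-cell annotation comment: controlled keywords + free text."""

    keywords: frozenset = frozenset()
    text: str = ""

    def __post_init__(self) -> None:
        bad = set(self.keywords) - CONTROLLED_KEYWORDS
        if bad:
            raise AnnotationError(
                f"comment keywords outside controlled vocabulary: {sorted(bad)}"
            )


class AnnotationMatrix:
    """Dense gene x tissue grid of :class:`ExpressionLevel` calls.

    Parameters
    ----------
    states:
        DataFrame indexed by gene id with one column per tissue id.  Cells
        may be state tokens (aliases accepted) or :class:`ExpressionLevel`
        members; they are normalized to canonical tokens on construction.
    tissue_names:
        Optional mapping tissue_id -> free-text name.
    comments:
        Optional mapping ``(gene, tissue) -> Comment``.
    """

    def __init__(
        self,
        states: pd.DataFrame,
        tissue_names: Mapping[str, str] | None = None,
        comments: Mapping[tuple[str, str], Comment] | None = None,
    ) -> None:
        if states.shape[0] == 0 or states.shape[1] == 0:
            raise AnnotationError("annotation matrix must have >=1 gene and >=1 tissue")
        genes = [str(g) for g in states.index]
        seen: dict[str, str] = {}
        for g in genes:
            key = canonical_gene(g)
            if key in seen:
                raise AnnotationError(f"duplicate gene id (case-insensitive): {g!r}")
            seen[key] = g
        tissues = [str(t) for t in states.columns]
        if len(set(tissues)) != len(tissues):
            raise AnnotationError("duplicate tissue ids in panel")

        norm = pd.DataFrame(index=genes, columns=tissues, dtype=object)
        for t in tissues:
            col = states[t]
            for g, v in zip(genes, col):
                if isinstance(v, ExpressionLevel):
                    lv = v
                else:
                    try:
                        lv = parse_level(str(v))
                    except ValueError as exc:
                        raise AnnotationError(
                            f"gene {g!r}, tissue {t!r}: {exc}"
                        ) from None
                norm.at[g, t] = lv.value
        self._states = norm
        self._tissue_names = dict(tissue_names or {})
        self._comments: dict[tuple[str, str], Comment] = {}
        for (g, t), c in (comments or {}).items():
            if g not in norm.index or t not in norm.columns:
                raise AnnotationError(f"comment on unknown cell ({g!r}, {t!r})")
            if not isinstance(c, Comment):
                raise AnnotationError("comments must be Comment instances")
            self._comments[(g, t)] = c

    # -- basic accessors ---------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self._states.index)

    @property
    def canonical_genes(self) -> list[str]:
        return [canonical_gene(g) for g in self._states.index]

    @property
    def tissue_ids(self) -> list[str]:
        return list(self._states.columns)

    @property
    def tissues(self) -> list[Tissue]:
        return [Tissue(t, self._tissue_names.get(t, "")) for t in self._states.columns]

    @property
    def comments(self) -> dict[tuple[str, str], Comment]:
        return dict(self._comments)

    @property
    def shape(self) -> tuple[int, int]:
        return self._states.shape

    def level(self, gene: str, tissue: str) -> ExpressionLevel:
        return ExpressionLevel(self._states.at[gene, tissue])

    def to_frame(self) -> pd.DataFrame:
        """Copy of the state grid as canonical lowercase tokens."""
        return self._states.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationMatrix):
            return NotImplemented
        return (
            self._states.equals(other._states)
            and list(self._states.index) == list(other._states.index)
            and list(self._states.columns) == list(other._states.columns)
            and self._comments == other._comments
        )

    def __repr__(self) -> str:
        n, m = self.shape
        return f"<AnnotationMatrix {n} genes x {m} tissues>"


# -- I/O -------------------------------------------------------------------

def load_annotations(
    path: str | Path,
    tissue_names: Mapping[str, str] | None = None,
    comments_path: str | Path | None = None,
) -> AnnotationMatrix:
    """Load an annotation matrix from TSV.

    Format: header ``gene<TAB>T1<TAB>...``; one row per gene; cells are
    state tokens (case-insensitive, aliases such as ``n.a.`` accepted).
    Row and column order are preserved.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 2:
            raise AnnotationError(f"{path}: header must name at least one tissue")
        tissue_ids = cols[1:]
        rows: list[list[str]] = []
        genes: list[str] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise AnnotationError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            genes.append(fields[0])
            rows.append(fields[1:])
    frame = pd.DataFrame(rows, index=genes, columns=tissue_ids, dtype=object)
    comments = _read_comments(comments_path) if comments_path else None
    return AnnotationMatrix(frame, tissue_names=tissue_names, comments=comments)


def write_annotations(
    matrix: AnnotationMatrix,
    path: str | Path,
    comments_path: str | Path | None = None,
) -> None:
    """Write the matrix as TSV with canonical lowercase state tokens."""
    path = Path(path)
    frame = matrix.to_frame()
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(frame.columns) + "\n")
        for g in frame.index:
            fh.write(g + "\t" + "\t".join(frame.loc[g]) + "\n")
    if comments_path is not None:
        _write_comments(matrix.comments, comments_path)


def _read_comments(path: str | Path) -> dict[tuple[str, str], Comment]:
    out: dict[tuple[str, str], Comment] = {}
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise AnnotationError(f"{path}:{lineno}: expected 4 fields")
            g, t, kw, text = fields
            keywords = frozenset(k for k in kw.split(",") if k)
            out[(g, t)] = Comment(keywords=keywords, text=text)
    return out


def _write_comments(
    comments: Mapping[tuple[str, str], Comment], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene\ttissue\tkeywords\ttext\n")
        for (g, t), c in comments.items():
            fh.write(f"{g}\t{t}\t{','.join(sorted(c.keywords))}\t{c.text}\n")


# -- summaries and encodings ----------------------------------------------

_COUNT_COLS = {
    ExpressionLevel.NOT_ANALYZED: "n_na",
    ExpressionLevel.NEGATIVE: "n_negative",
    ExpressionLevel.WEAK: "n_weak",
    ExpressionLevel.MEDIUM: "n_medium",
    ExpressionLevel.STRONG: "n_strong",
}


def score_summary(matrix: AnnotationMatrix) -> pd.DataFrame:
    """Per-tissue counts and percentages of each expression state.

    Returns a DataFrame indexed by tissue id with count columns
    ``n_na, n_negative, n_weak, n_medium, n_strong, n_expressed`` and the
    matching one-decimal percentage columns (``pct_*``), where
    expressed = weak + medium + strong.  For every tissue
    ``n_na + n_negative + n_expressed`` equals the number of genes.
    """
    frame = matrix.to_frame()
    total = len(frame.index)
    records = []
    for t in frame.columns:
        counts = frame[t].value_counts()
        row: dict[str, object] = {"tissue": t}
        for level, col in _COUNT_COLS.items():
            row[col] = int(counts.get(level.value, 0))
        row["n_expressed"] = sum(
            int(counts.get(lv.value, 0)) for lv in EXPRESSED_STATES
        )
        for level, col in _COUNT_COLS.items():
            row["pct_" + col[2:]] = round_pct(row[col], total)
        row["pct_expressed"] = round_pct(row["n_expressed"], total)
        name = matrix.tissues[list(frame.columns).index(t)].name
        row["name"] = name
        records.append(row)
    summary = pd.DataFrame.from_records(records).set_index("tissue")
    summary.attrs["n_genes"] = total
    return summary


def write_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """Write a score summary as TSV (counts + percentages per state)."""
    summary.to_csv(path, sep="\t")


def encode_ordinal(matrix: AnnotationMatrix) -> pd.DataFrame:
    """Numeric gene x tissue grid: negative/weak/medium/strong -> 0/2/3/4.

    NOT_ANALYZED cells are masked as NaN and must be excluded from any
    rank computation downstream.  Shape, row and column order match the
    input matrix.
    """
    frame = matrix.to_frame()
    mapping = {lv.value: v for lv, v in ORDINAL_VALUE.items()}
    mapping[ExpressionLevel.NOT_ANALYZED.value] = np.nan
    out = frame.apply(lambda col: col.map(mapping)).astype(float)
    return out
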