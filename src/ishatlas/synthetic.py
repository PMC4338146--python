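"""Synthetic data with the statistical structure the analyses assume.

The real atlas (the expert-annotated 2000-gene matrix, the STRING snapshot
it was mined against, the GO and morbidmap joins) is not public; every
generator here produces matched synthetic stand-ins so the full pipeline is
testable offline:

* annotation matrices with exact per-tissue marginal state frequencies,
  planted blocks of correlated tissues (a latent-factor-plus-threshold
  construction), a forced never-expressed gene subset and sprinkled
  not-analyzed cells;
* planted-partition interactomes whose confidence scores make a 0.7
  threshold retain mostly intra-module edges;
* gene->GO tables with an exact NoGO fraction and skewed term popularity;
* morbidmap-style disorder tables with an exact linked-gene fraction and
  occasional multi-gene rows.

All generators are pure functions of (config, seed).  A single master seed
fans out to per-component child streams through ``numpy.random.SeedSequence``
spawn keys, so adding a generator never perturbs the draws of another.
"""
from __future__ import annotations

import dataclasses
import json
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import reference
from .annotation import AnnotationMatrix
from .functional import GOTable, GOTerm, MorbidMap, MorbidRecord
from .levels import ExpressionLevel

# Child-stream identifiers for the master-seed fan-out.
_STREAM_NEVER = 0
_STREAM_LATENT = 1
_STREAM_NA = 2
_STREAM_INTERACTOME = 3
_STREAM_GO = 4
_STREAM_MORBID = 5


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent child generator for one component of the simulation."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclasses.dataclass(frozen=True)
class TissueBlockSpec:
    """A block of tissues sharing one latent expression factor.

    `marginals` maps each member tissue to its target state frequencies,
    either 5 values ``(na, negative, weak, medium, strong)`` or 4 values
    ``(negative, weak, medium, strong)``; in the 4-value form the
    simulation's global ``na_rate`` is applied and the four are scaled to
    the non-NA mass.  `strength` is the within-block correlation of the
    latent intensities, in [0, 1].
    """

    label: str
    tissues: tuple
    strength: float
    marginals: dict

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("block strength must be in [0, 1]")
        missing = set(self.tissues) - set(self.marginals)
        if missing:
            raise ValueError(f"block {self.label}: no marginals for {sorted(missing)}")
        for t in self.tissues:
            probs = self.marginals[t]
            if len(probs) not in (4, 5):
                raise ValueError(f"{t}: marginals must have 4 or 5 entries")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{t}: marginal probabilities must sum to 1")
            if any(p < 0 for p in probs):
                raise ValueError(f"{t}: negative marginal probability")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one synthetic annotation matrix."""

    n_genes: int
    blocks: tuple
    never_expressed_fraction: float = reference.NEVER_EXPRESSED_FRACTION
    na_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0.0 <= self.never_expressed_fraction <= 1.0:
            raise ValueError("never_expressed_fraction must be in [0, 1]")
        if not 0.0 <= self.na_rate <= 1.0:
            raise ValueError("na_rate must be in [0, 1]")
        seen: set = set()
        for block in self.blocks:
            overlap = seen & set(block.tissues)
            if overlap:
                raise ValueError(f"tissue blocks overlap on {sorted(overlap)}")
            seen |= set(block.tissues)

    @property
    def tissue_ids(self) -> list:
        return [t for b in self.blocks for t in b.tissues]


def _resolve_marginals(probs: Sequence[float], na_rate: float) -> np.ndarray:
    """Return 5-state marginals (na, neg, weak, medium, strong)."""
    probs = np.asarray(probs, dtype=float)
    if len(probs) == 5:
        return probs
    return np.concatenate([[na_rate], probs * (1.0 - na_rate)])


def _conditional_thresholds(
    marginals: np.ndarray, never_fraction: float, tissue: str
) -> np.ndarray:
    """Latent-normal cut points hitting the marginals among the pool of
    genes that are neither never-expressed nor masked NA.

    Solves for the conditional state probabilities c so that the
    unconditional frequencies equal the target marginals once the forced
    never-expressed (all NEGATIVE) subset and the NA mask are layered in.
    """
    p_na = marginals[0]
    non_na = marginals[1:] / (1.0 - p_na)
    f = never_fraction
    c_neg = (non_na[0] - f) / (1.0 - f) if f < 1.0 else 1.0
    if c_neg < -1e-9:
        raise ValueError(
            f"{tissue}: negative-state marginal {non_na[0]:.3f} below the "
            f"never-expressed fraction {f:.3f}; marginals are infeasible"
        )
    cond = np.concatenate([[max(c_neg, 0.0)], non_na[1:] / (1.0 - f)])
    cond = cond / cond.sum()  # absorb rounding slack
    return norm.ppf(np.cumsum(cond)[:-1])


_STATE_TOKENS = np.array(
    [
        ExpressionLevel.NEGATIVE.value,
        ExpressionLevel.WEAK.value,
        ExpressionLevel.MEDIUM.value,
        ExpressionLevel.STRONG.value,
    ]
)


def generate_annotation_matrix(config: SimulationConfig) -> AnnotationMatrix:
    """Draw a synthetic gene x tissue annotation matrix.

    Per gene and block, one latent standard-normal intensity is drawn and
    mixed with per-tissue noise so that within-block latent correlation
    equals the block's strength; each tissue's latent column (marginally
    N(0,1)) is cut at quantile thresholds to hit its target state
    frequencies.  An exact ``round(never_expressed_fraction * n_genes)``
    gene subset is forced NEGATIVE everywhere, and NA cells are sprinkled
    per tissue at the NA marginal.  Deterministic given the config seed.
    """
    n = config.n_genes
    tissues = config.tissue_ids
    genes = [f"g{i:04d}" for i in range(1, n + 1)]

    rng_never = child_rng(config.seed, _STREAM_NEVER)
    n_never = int(round(config.never_expressed_fraction * n))
    never_idx = rng_never.choice(n, size=n_never, replace=False)
    never_mask = np.zeros(n, dtype=bool)
    never_mask[never_idx] = True

    rng_latent = child_rng(config.seed, _STREAM_LATENT)
    rng_na = child_rng(config.seed, _STREAM_NA)

    columns: dict[str, np.ndarray] = {}
    for block in config.blocks:
        z_block = rng_latent.standard_normal(n)
        w = np.sqrt(block.strength)
        for tissue in block.tissues:
            marginals = _resolve_marginals(block.marginals[tissue], config.na_rate)
            eps = rng_latent.standard_normal(n)
            latent = w * z_block + np.sqrt(1.0 - block.strength) * eps
            cuts = _conditional_thresholds(
                marginals, config.never_expressed_fraction, tissue
            )
            states = _STATE_TOKENS[np.digitize(latent, cuts)]
            states = states.copy()
            states[never_mask] = ExpressionLevel.NEGATIVE.value
            na_cells = rng_na.random(n) < marginals[0]
            states[na_cells] = ExpressionLevel.NOT_ANALYZED.value
            columns[tissue] = states
    frame = pd.DataFrame(columns, index=genes)
    return AnnotationMatrix(frame)


def table1_config(
    seed: int,
    n_genes: int = reference.N_GENES,
    strength: float = 0.6,
) -> SimulationConfig:
    """Preset mirroring the published atlas: the 25-tissue panel with its
    printed marginal state frequencies, three correlated tissue blocks
    matching the main dendrogram branches, and the published
    never-expressed fraction."""
    marginals = reference.marginal_frequencies()
    blocks = tuple(
        TissueBlockSpec(
            label=label,
            tissues=members,
            strength=strength,
            marginals={t: marginals[t] for t in members},
        )
        for label, members in reference.DENDROGRAM_BRANCHES.items()
    )
    return SimulationConfig(n_genes=n_genes, blocks=blocks, seed=seed)


# -- interactome -----------------------------------------------------------

def generate_interactome(
    n_genes: int,
    n_modules: int,
    intra_p: float,
    inter_p: float,
    seed: int,
    intra_conf: tuple = (0.71, 0.99),
    inter_conf: tuple = (0.15, 0.85),
    gene_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Planted-partition interactome edge list.

    Genes are split into `n_modules` contiguous modules; within-module
    pairs get an edge with probability `intra_p`, cross-module pairs with
    `inter_p` (must be smaller).  Intra-module confidences are drawn
    uniformly from `intra_conf` (above the 0.7 threshold by default) and
    inter-module confidences from `inter_conf`, so thresholding retains
    mostly intra-module edges.  Returns (edge DataFrame with columns
    gene_a/gene_b/confidence, gene -> module-label mapping).
    """
    if not intra_p > inter_p:
        raise ValueError("intra_p must exceed inter_p")
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    gene_ids = list(gene_ids)
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    modules = {
        g: f"M{(i * n_modules) // n_genes + 1}" for i, g in enumerate(gene_ids)
    }
    rng = child_rng(seed, _STREAM_INTERACTOME)
    ii, jj = np.triu_indices(n_genes, k=1)
    mod = np.array([modules[g] for g in gene_ids])
    same = mod[ii] == mod[jj]
    p = np.where(same, intra_p, inter_p)
    keep = rng.random(len(ii)) < p
    conf = np.where(
        same,
        rng.uniform(intra_conf[0], intra_conf[1], size=len(ii)),
        rng.uniform(inter_conf[0], inter_conf[1], size=len(ii)),
    )
    names = np.array(gene_ids)
    edges = pd.DataFrame(
        {
            "gene_a": names[ii[keep]],
            "gene_b": names[jj[keep]],
            "confidence": np.round(conf[keep], 4),
        }
    )
    return edges, modules


def write_interactome(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", header=False, index=False)


# -- GO tables and morbidmaps ---------------------------------------------

#: Name pool for synthetic molecular-function terms (reused cyclically).
_MF_NAMES = (
    "protein binding",
    "nucleic acid binding",
    "ion channel activity",
    "G-protein coupled receptor activity",
    "structural constituent of ribosome",
    "translation initiation factor activity",
    "transcription factor activity",
    "kinase activity",
    "transferase activity",
    "hydrolase activity",
    "oxidoreductase activity",
    "transporter activity",
)


def generate_go_table(
    gene_ids: Sequence[str],
    seed: int,
    nogo_fraction: float = reference.NOGO_FRACTION,
    n_terms: int = 40,
    mean_extra_terms: float = 1.5,
) -> GOTable:
    """Synthetic gene -> GO-term table with an exact NoGO count.

    Exactly ``round(nogo_fraction * n)`` genes receive no terms.  Each
    annotated gene gets ``1 + Poisson(mean_extra_terms)`` distinct terms
    sampled with Zipf-skewed popularity, so a few terms (protein binding,
    nucleic acid binding, ...) dominate as in real molecular-function
    distributions.  All terms are aspect F.
    """
    genes = list(gene_ids)
    n = len(genes)
    rng = child_rng(seed, _STREAM_GO)
    n_nogo = int(round(nogo_fraction * n))
    order = rng.permutation(n)
    nogo_set = {genes[i] for i in order[:n_nogo]}
    pool = [
        GOTerm(
            term_id=f"GO:{k + 1:07d}",
            name=_MF_NAMES[k % len(_MF_NAMES)]
            + ("" if k < len(_MF_NAMES) else f" {k // len(_MF_NAMES) + 1}"),
            aspect="F",
        )
        for k in range(n_terms)
    ]
    weights = 1.0 / np.arange(1, n_terms + 1)
    weights /= weights.sum()
    mapping: dict[str, set] = {}
    for gene in genes:
        if gene in nogo_set:
            mapping[gene] = set()
            continue
        k = 1 + rng.poisson(mean_extra_terms)
        k = min(k, n_terms)
        picks = rng.choice(n_terms, size=k, replace=False, p=weights)
        mapping[gene] = {pool[i] for i in picks}
    return GOTable(mapping)


def write_go_table(go: GOTable, path: str | Path) -> None:
    """Write the table in the 4-column dialect, with explicit NoGO rows."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene\tterm_id\tterm_name\taspect\n")
        for gene in sorted(go.genes):
            terms = sorted(go.terms(gene), key=lambda t: t.term_id)
            if not terms:
                fh.write(f"{gene}\t\t\tF\n")
            for term in terms:
                fh.write(f"{gene}\t{term.term_id}\t{term.name}\t{term.aspect}\n")


def generate_morbidmap(
    gene_ids: Sequence[str],
    seed: int,
    linked_fraction: float = reference.MORBID_LINKED_FRACTION,
    multi_gene_fraction: float = 0.1,
) -> MorbidMap:
    """Synthetic morbidmap with an exact linked-gene count.

    Exactly ``round(linked_fraction * n)`` genes appear in >=1 disorder
    record; a `multi_gene_fraction` share of records list 2-3 gene symbols
    (all drawn from the linked set), exercising the multi-symbol indexing
    rule.
    """
    genes = list(gene_ids)
    n = len(genes)
    rng = child_rng(seed, _STREAM_MORBID)
    n_linked = int(round(linked_fraction * n))
    linked = [genes[i] for i in rng.permutation(n)[:n_linked]]
    records = []
    i = 0
    rec_no = 0
    while i < len(linked):
        rec_no += 1
        size = 1
        if rng.random() < multi_gene_fraction and i + 1 < len(linked):
            size = int(rng.integers(2, 4))
            size = min(size, len(linked) - i)
        symbols = tuple(linked[i : i + size])
        i += size
        mim = str(100000 + rec_no)
        cyto = f"{int(rng.integers(1, 23))}p{int(rng.integers(11, 37))}"
        records.append(
            MorbidRecord(
                disorder=f"Synthetic disorder {rec_no:03d}, {mim} (3)",
                genes=symbols,
                mim_number=mim,
                cyto_location=cyto,
            )
        )
    return MorbidMap(records)


def write_morbidmap(morbid: MorbidMap, path: str | Path) -> None:
    """Write records in the pipe dialect: disorder | genes | MIM | cyto."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in morbid.records:
            fh.write(
                f"{rec.disorder} | {', '.join(rec.genes)} | "
                f"{rec.mim_number} | {rec.cyto_location}\n"
            )


# -- bundles ---------------------------------------------------------------

def simulate_bundle(
    out_dir: str | Path,
    seed: int,
    preset: str = "table1",
    n_genes: int = reference.N_GENES,
    strength: float = 0.6,
    n_modules: int = 5,
    intra_p: float = 0.12,
    inter_p: float = 0.002,
) -> dict:
    """Emit a matched set of fixture files plus a parameter manifest.

    Writes ``annotations.tsv``, ``edges.tsv``, ``go.tsv``, ``morbidmap.txt``
    and ``manifest.json`` under `out_dir`; returns the manifest dict.
    """
    if preset != "table1":
        raise ValueError(f"unknown preset {preset!r}")
    from .annotation import write_annotations

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = table1_config(seed=seed, n_genes=n_genes, strength=strength)
    matrix = generate_annotation_matrix(config)
    write_annotations(matrix, out / "annotations.tsv")
    edges, modules = generate_interactome(
        n_genes=n_genes,
        n_modules=n_modules,
        intra_p=intra_p,
        inter_p=inter_p,
        seed=seed,
        gene_ids=matrix.genes,
    )
    write_interactome(edges, out / "edges.tsv")
    go = generate_go_table(matrix.genes, seed=seed)
    write_go_table(go, out / "go.tsv")
    morbid = generate_morbidmap(matrix.genes, seed=seed)
    write_morbidmap(morbid, out / "morbidmap.txt")
    manifest = {
        "preset": preset,
        "seed": seed,
        "n_genes": n_genes,
        "tissues": config.tissue_ids,
        "block_strength": strength,
        "never_expressed_fraction": config.never_expressed_fraction,
        "na_rate": config.na_rate,
        "interactome": {
            "n_modules": n_modules,
            "intra_p": intra_p,
            "inter_p": inter_p,
        },
        "go": {"nogo_fraction": reference.NOGO_FRACTION},
        "morbidmap": {"linked_fraction": reference.MORBID_LINKED_FRACTION},
        "files": ["annotations.tsv", "edges.tsv", "go.tsv", "morbidmap.txt"],
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )
    return manifest
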