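"""Published summary data for the E14.5 mouse ear/sensory tissue panel.

The 25-tissue panel (T1-T25) and its per-tissue expression-state counts
over the 2000-gene ISH screen are the published marginal summary of the
atlas; the underlying gene x tissue matrix is not public.  These counts
serve two purposes here: as the marginal state frequencies the synthetic
generator emulates, and as a printed fixture from which a count-matched
matrix can be rebuilt to exercise the summary arithmetic.

KUROV denotes the five presumptive sensory tissues: Kolliker's organ
(cochlea, T9), Utricle sensory region (T14), sensory Retina (T22),
Olfactory organ (T23) and Vibrissae follicles (T25).
"""
from __future__ import annotations

import pandas as pd

from .annotation import AnnotationMatrix
from .levels import STATE_ORDER

#: Published totals: genes screened and tissues annotated.
N_GENES = 2000

#: tissue_id -> (name, n_na, n_negative, n_weak, n_medium, n_strong)
TISSUE_STATE_COUNTS: dict[str, tuple] = {
    "T1": ("External acoustic meatus", 6, 977, 685, 284, 48),
    "T2": ("Middle ear ossicles", 28, 1248, 538, 166, 20),
    "T3": ("Middle ear tympanic membrane", 7, 1090, 749, 136, 18),
    "T4": ("Middle ear mesenchyme", 4, 868, 757, 305, 66),
    "T5": ("Otic capsule", 10, 1277, 449, 205, 59),
    "T6": ("Inner ear mesenchyme", 8, 905, 752, 290, 45),
    "T7": ("Stato-acoustic ganglion", 5, 892, 739, 288, 76),
    "T8": ("Inner spiral sulcus", 1, 1132, 664, 178, 25),
    "T9": ("Kolliker organ", 0, 1215, 614, 153, 18),
    "T10": ("Stria vascularis", 3, 1477, 412, 92, 16),
    "T11": ("Outer spiral sulcus", 5, 1561, 360, 65, 9),
    "T12": ("Saccule sensory region", 10, 1116, 661, 187, 26),
    "T13": ("Saccule other cells", 8, 1133, 671, 167, 21),
    "T14": ("Utricule sensory region", 10, 1114, 663, 188, 25),
    "T15": ("Utricule other cells", 8, 1131, 671, 166, 24),
    "T16": ("Crista sensory region", 10, 1110, 662, 192, 26),
    "T17": ("Crista other cells", 9, 1132, 670, 164, 25),
    "T18": ("Semi-circular canals", 11, 1112, 649, 198, 30),
    "T19": ("Endolymphatic organ", 35, 1386, 470, 97, 12),
    "T20": ("Choroide plexus 4th ventricle", 6, 1022, 651, 264, 57),
    "T21": ("Hindbrain", 0, 455, 793, 570, 182),
    "T22": ("Sensory retina", 12, 824, 725, 378, 61),
    "T23": ("Olfactory organ", 6, 818, 830, 299, 47),
    "T24": ("Cartilage primordium of ribs", 11, 1216, 571, 153, 49),
    "T25": ("Follicles of vibrissae", 14, 894, 685, 326, 81),
}

#: The five presumptive sensory tissues (KUROV).
KUROV_TISSUES = ("T9", "T14", "T22", "T23", "T25")

#: Fraction of screened genes with no ISH signal in any tissue.
NEVER_EXPRESSED_FRACTION = 0.165

#: Fraction of screened genes with no assigned GO (molecular function) term.
NOGO_FRACTION = 0.183

#: Fraction of the co-expressed sensory gene set linked to Mendelian disorders.
MORBID_LINKED_FRACTION = 0.12

#: Main dendrogram branches of the published tissue tree: A, inner ear
#: (vestibular/cochlear) tissues; B, mesoderm-derived mesenchymal and
#: skeletal tissues; C, nervous tissues plus skin-derived organs.
DENDROGRAM_BRANCHES: dict[str, tuple] = {
    "A": ("T12", "T13", "T14", "T15", "T16", "T17", "T18"),
    "B": ("T2", "T4", "T5", "T6", "T10", "T11", "T19", "T24"),
    "C": ("T1", "T3", "T7", "T8", "T9", "T20", "T21", "T22", "T23", "T25"),
}


def tissue_names() -> dict[str, str]:
    return {t: row[0] for t, row in TISSUE_STATE_COUNTS.items()}


def state_counts_frame() -> pd.DataFrame:
    """Counts per tissue and state as a DataFrame indexed by tissue id."""
    rows = []
    for tid, (name, na, neg, weak, med, strong) in TISSUE_STATE_COUNTS.items():
        rows.append(
            {
                "tissue": tid,
                "name": name,
                "n_na": na,
                "n_negative": neg,
                "n_weak": weak,
                "n_medium": med,
                "n_strong": strong,
            }
        )
    return pd.DataFrame(rows).set_index("tissue")


def marginal_frequencies() -> dict[str, tuple]:
    """Per-tissue (na, negative, weak, medium, strong) fractions of 2000."""
    return {
        tid: tuple(c / N_GENES for c in row[1:])
        for tid, row in TISSUE_STATE_COUNTS.items()
    }


def counts_matrix() -> AnnotationMatrix:
    """Rebuild a 2000-gene matrix whose per-tissue state counts equal the
    published summary exactly.

    The joint distribution across tissues is arbitrary (each column is
    filled independently in state order); only the marginal counts are
    meaningful, which is all the summary arithmetic consumes.
    """
    genes = [f"g{i:04d}" for i in range(1, N_GENES + 1)]
    columns = {}
    for tid, (_, *counts) in TISSUE_STATE_COUNTS.items():
        if sum(counts) != N_GENES:
            raise AssertionError(f"{tid}: counts do not sum to {N_GENES}")
        col = []
        for level, count in zip(STATE_ORDER, counts):
            col.extend([level.value] * count)
        columns[tid] = col
    frame = pd.DataFrame(columns, index=genes)
    return AnnotationMatrix(frame, tissue_names=tissue_names())
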