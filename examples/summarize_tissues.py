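"""Per-tissue expression-state summary of an annotation matrix.

Rebuilds a 2000-gene matrix whose per-tissue state counts equal the
published atlas marginals, then recomputes the summary table.
"""
from ishatlas import reference, score_summary

matrix = reference.counts_matrix()
summary = score_summary(matrix)

cols = ["n_negative", "n_weak", "n_medium", "n_strong", "n_expressed", "pct_expressed"]
print(summary.loc[["T9", "T14", "T21", "T22", "T23", "T25"], cols].to_string())
print()
print(
    "Each row: how many of the 2000 genes score negative/weak/medium/strong\n"
    "in that tissue; 'expressed' = weak+medium+strong. The hindbrain (T21)\n"
    "expresses the most genes (77.2%); Kolliker's organ (T9) the fewest of\n"
    "the five sensory tissues (39.2%)."
)
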