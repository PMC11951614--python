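"""Per-cell marker-pair co-expression in panel-based single-cell data.

Simulates a control sample and a transition-rich sample over a 500-gene
panel with acinar/duct/PanIN marker programs.  For each cell the observed
acinar-duct marker-pair proportion x*y/C(g,2) is compared with the
without-replacement random expectation m_A*m_B/C(N,2); the per-cell score
is log2(signal/random).  Samples are compared with a Wilcoxon rank-sum
test, and the spot-purity / pseudobulk helpers are shown on the side.
"""

import pandas as pd

from methylmemory import (
    CellSimConfig,
    compare_groups,
    pseudobulk_profile,
    score_dataset,
    simulate_cell_panel,
    spot_purity_filter,
)

frames = []
for label, tf, seed in (("control", 0.0, 31), ("adm_d2", 0.25, 32)):
    counts, meta, panel, truth = simulate_cell_panel(
        CellSimConfig(transition_fraction=tf, sample_label=label, seed=seed)
    )
    frames.append(score_dataset(counts, meta, panel, [("acinar", "duct")]))
scores = pd.concat(frames, ignore_index=True)

defined = scores.groupby("sample")["defined"].mean()
medians = scores[scores["defined"]].groupby("sample")["log2fc"].median()
print("fraction of cells with a defined acinar-duct score:")
print(defined.to_string())
print("\nmedian log2(signal/random) among defined cells:")
print(medians.to_string())
print(compare_groups(scores).to_string(index=False))
print(
    "\ntransition cells co-express both programs, so the transition-rich"
    "\nsample shows more defined scores and a higher score distribution."
)

# spot utilities: pick pure acinar pseudo-spots and build a training profile
proportions = pd.DataFrame(
    {"acinar": [0.95, 0.45, 0.30], "duct": [0.03, 0.50, 0.40], "other": [0.02, 0.05, 0.30]},
    index=["spot1", "spot2", "spot3"],
)
pure = spot_purity_filter(proportions, "acinar", pct=60)
profile = pseudobulk_profile(counts.iloc[:20], n=10, seed=0)
print(f"\npure acinar spots: {pure}; pseudobulk profile sums {int(profile.sum())} counts")
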