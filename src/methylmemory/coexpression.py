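"""Per-cell marker-pair co-expression scoring for panel-based single-cell
spatial data, plus spot-purity and pseudobulk utilities.

For a cell detecting ``g`` of the ``N`` panel genes, with ``x`` detected
markers of program A (panel set size ``m_A``) and ``y`` of program B
(``m_B``, disjoint from A):

    observed_prop = x * y / C(g, 2)
    expected_prop = m_A * m_B / C(N, 2)
    score         = log2(observed_prop / expected_prop)   (defined iff x*y > 0)

``expected_prop`` is the closed form of the expected A-B pair proportion
when ``g`` panel genes are drawn uniformly without replacement: under the
multivariate hypergeometric, E[x_r * y_r] = g(g-1) m_A m_B / (N(N-1)), and
dividing by C(g, 2) leaves m_A m_B / C(N, 2) — notably independent of ``g``.
A resampling-based expectation is provided for sensitivity analysis.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb, log2

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerPanel",
    "PairScore",
    "detected_genes",
    "pair_score",
    "score_dataset",
    "compare_groups",
    "expected_pair_proportion_mc",
    "spot_purity_filter",
    "pseudobulk_profile",
    "make_panel",
]


@dataclass(frozen=True)
class MarkerPanel:
    """A fixed gene panel with disjoint per-program marker sets."""

    genes: tuple[str, ...]
    marker_sets: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        universe = set(self.genes)
        seen: set[str] = set()
        for label, ms in self.marker_sets.items():
            s = set(ms)
            if not s <= universe:
                raise ValueError(f"marker set {label!r} not a subset of the panel")
            if s & seen:
                raise ValueError(f"marker set {label!r} overlaps another set")
            seen |= s
        if len(self.genes) < len(seen):
            raise ValueError("panel smaller than the union of marker sets")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def make_panel(genes, marker_sets: dict) -> MarkerPanel:
    """Build a panel, dropping genes shared between marker sets (assigned to
    neither, with a warning) so the pair-count algebra stays valid."""
    counts: dict[str, int] = {}
    for ms in marker_sets.values():
        for g in ms:
            counts[g] = counts.get(g, 0) + 1
    shared = {g for g, c in counts.items() if c > 1}
    if shared:
        warnings.warn(f"genes in multiple marker sets dropped from all: {sorted(shared)}")
    cleaned = {k: tuple(g for g in v if g not in shared) for k, v in marker_sets.items()}
    return MarkerPanel(genes=tuple(genes), marker_sets=cleaned)


@dataclass
class PairScore:
    cell_id: str
    type_pair: tuple[str, str]
    x: int
    y: int
    g: int
    observed_prop: float
    expected_prop: float
    log2fc: float  # NaN when undefined (x*y == 0 or g < 2)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.log2fc)


def detected_genes(counts, min_count: int = 1) -> tuple[set[str], int]:
    """Genes with count >= ``min_count`` and their number g."""
    if isinstance(counts, pd.Series):
        det = set(counts.index[counts >= min_count])
    else:
        det = {g for g, c in counts.items() if c >= min_count}
    return det, len(det)


def pair_score(
    counts,
    set_a,
    set_b,
    n_panel: int,
    min_count: int = 1,
    cell_id: str = "",
    type_pair: tuple[str, str] = ("A", "B"),
    prop_denominator: str = "detected",
    continuity: float = 0.0,
) -> PairScore:
    """Score one cell for one (unordered) program pair.

    ``prop_denominator``: "detected" uses C(g, 2) (the cell's detected
    genes); "panel" uses C(N, 2).  ``continuity`` > 0 substitutes x*y -> c
    when x*y == 0 instead of leaving the score undefined.
    """
    sa, sb = set(set_a), set(set_b)
    if sa & sb:
        raise ValueError("marker sets overlap; pair scoring requires disjoint sets")
    det, g = detected_genes(counts, min_count)
    x = len(det & sa)
    y = len(det & sb)
    expected = len(sa) * len(sb) / comb(n_panel, 2)
    if g < 2:
        return PairScore(cell_id, type_pair, x, y, g, float("nan"), expected, float("nan"))
    denom = comb(g, 2) if prop_denominator == "detected" else comb(n_panel, 2)
    xy = float(x * y)
    if xy == 0.0 and continuity > 0:
        xy = continuity
    observed = xy / denom
    lfc = log2(observed / expected) if observed > 0 else float("nan")
    return PairScore(cell_id, type_pair, x, y, g, observed, expected, lfc)


def expected_pair_proportion_mc(
    n_panel: int, m_a: int, m_b: int, g: int, n_draws: int = 100_000, seed: int = 0
) -> float:
    """Resampling expectation of the pair proportion: draw ``g`` of the
    ``n_panel`` genes without replacement and average x*y / C(g, 2)."""
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric([m_a, m_b, n_panel - m_a - m_b], g, size=n_draws)
    return float(np.mean(draws[:, 0] * draws[:, 1]) / comb(g, 2))


def score_dataset(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    panel: MarkerPanel,
    pairs: list[tuple[str, str]],
    min_count: int = 1,
    prop_denominator: str = "detected",
) -> pd.DataFrame:
    """One row per (cell, pair): x, y, g, observed/expected proportions and
    log2fc (NaN when undefined), with the cell's sample label attached."""
    for a, b in pairs:
        for lbl in (a, b):
            if lbl not in panel.marker_sets:
                raise ValueError(f"unknown marker-set label {lbl!r}")
    panel_cols = [g for g in panel.genes if g in counts.columns]
    mat = counts[panel_cols].to_numpy() >= min_count
    g_per_cell = mat.sum(axis=1)
    col_idx = {g: i for i, g in enumerate(panel_cols)}
    sample_of = dict(zip(metadata["cell_id"], metadata["sample"]))
    N2 = comb(panel.n_genes, 2)
    out = []
    for a, b in pairs:
        ia = [col_idx[g] for g in panel.marker_sets[a] if g in col_idx]
        ib = [col_idx[g] for g in panel.marker_sets[b] if g in col_idx]
        x = mat[:, ia].sum(axis=1)
        y = mat[:, ib].sum(axis=1)
        m_a = len(panel.marker_sets[a])
        m_b = len(panel.marker_sets[b])
        expected = m_a * m_b / N2
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.array(
                [comb(int(gg), 2) if gg >= 2 else 0 for gg in g_per_cell], dtype=float
            )
            if prop_denominator == "panel":
                denom = np.where(g_per_cell >= 2, float(N2), 0.0)
            observed = np.where(denom > 0, x * y / np.maximum(denom, 1.0), np.nan)
            lfc = np.where(observed > 0, np.log2(np.maximum(observed, 1e-300) / expected), np.nan)
        for i, cid in enumerate(counts.index):
            out.append(
                (cid, sample_of.get(cid, ""), f"{a}-{b}", int(x[i]), int(y[i]), int(g_per_cell[i]),
                 observed[i], expected, lfc[i])
            )
    df = pd.DataFrame(
        out,
        columns=["cell_id", "sample", "pair", "x", "y", "g", "observed_prop", "expected_prop", "log2fc"],
    )
    df["defined"] = np.isfinite(df["log2fc"])
    return df


def _rank_sum_p(a: np.ndarray, b: np.ndarray, alternative: str = "two-sided") -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # every rank assignment identical
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    scores: pd.DataFrame,
    value_col: str = "log2fc",
    group_col: str = "sample",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Wilcoxon rank-sum (Mann-Whitney U) between every pair of groups on
    the defined scores; exact when both n <= 20 and tie-free, else normal
    approximation with tie and continuity correction.  Groups with no
    defined score are skipped with a warning."""
    groups: dict[str, np.ndarray] = {}
    for label, sub in scores.groupby(group_col):
        vals = sub[value_col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            warnings.warn(f"group {label!r} has no defined scores; skipped")
            continue
        groups[label] = vals
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with defined scores")
    rows = []
    for (la, va), (lb, vb) in itertools.combinations(groups.items(), 2):
        stat, p = _rank_sum_p(va, vb, alternative)
        rows.append((la, lb, len(va), len(vb), stat, p))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "statistic", "p"])


# ---------------------------------------------------------------------------
# Spatial-spot utilities


def spot_purity_filter(
    proportions: pd.DataFrame, celltype: str, pct: float = 90.0
) -> list:
    """Spots in the top ``pct``-th percentile of ``celltype``'s deconvolved
    proportion with no other cell type's proportion greater in that spot.

    Percentile is linear-interpolation; both comparisons are inclusive, so
    a tie with the threshold or with another cell type still passes.
    Rows must sum to ~1 (tolerance 1e-3)."""
    if celltype not in proportions.columns:
        raise ValueError(f"cell type {celltype!r} not in the proportion table")
    sums = proportions.sum(axis=1).to_numpy()
    if np.any(np.abs(sums - 1.0) > 1e-3):
        raise ValueError("proportion rows must sum to 1 (tolerance 1e-3)")
    col = proportions[celltype].to_numpy()
    thresh = np.percentile(col, pct)
    others = proportions.drop(columns=[celltype]).to_numpy()
    other_max = others.max(axis=1) if others.shape[1] else np.zeros(len(col))
    keep = (col >= thresh) & (other_max <= col)
    return list(proportions.index[keep])


def pseudobulk_profile(counts: pd.DataFrame, n: int = 10, seed: int = 0) -> pd.Series:
    """Per-gene count sum of ``n`` cells sampled uniformly without
    replacement (a deconvolution training profile)."""
    if len(counts) < n:
        raise ValueError(f"need >= {n} cells, have {len(counts)}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(counts), size=n, replace=False)
    return counts.iloc[pick].sum(axis=0)
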