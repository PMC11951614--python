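"""DMR-to-gene mapping, Fisher's-exact gene-set overrepresentation, and
feature enrichment against randomly placed length-matched control regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "GenomicInterval",
    "dmr_gene_overlap",
    "fisher_gsea",
    "random_matched_regions",
    "feature_enrichment",
    "benjamini_hochberg",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def _as_interval_frame(regions) -> pd.DataFrame:
    """Accept a DataFrame with chrom/start/end or a list of objects carrying
    those attributes (Dmr, GenomicInterval)."""
    if isinstance(regions, pd.DataFrame):
        return regions
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
        }
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone, capped at 1)."""
    return stats.false_discovery_control(np.asarray(p, dtype=float), method="bh")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description] + sorted(genes)) + "\n")


# ---------------------------------------------------------------------------
# Interval overlap


def dmr_gene_overlap(dmrs, annotation: pd.DataFrame, feature_classes=None) -> set[str]:
    """Gene ids whose annotated intervals intersect any DMR by >= 1 bp.

    ``annotation`` columns: chrom, start, end (0-based half-open), gene_id,
    feature.  ``feature_classes``: restrict to these feature labels (default
    all).  Half-open semantics: abutting intervals do not overlap.
    """
    dmr_df = _as_interval_frame(dmrs)
    ann = annotation
    if feature_classes is not None:
        ann = ann[ann["feature"].isin(set(feature_classes))]
    if len(dmr_df) and len(ann):
        dmr_chroms = set(dmr_df["chrom"])
        ann_chroms = set(ann["chrom"])
        if not (dmr_chroms & ann_chroms):
            raise ValueError(
                "chromosome naming mismatch between DMRs and annotation: "
                f"{sorted(dmr_chroms)[:3]} vs {sorted(ann_chroms)[:3]}"
            )
    trees: dict[str, IntervalTree] = {}
    for row in ann.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.gene_id)
    hits: set[str] = set()
    for row in dmr_df.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(row.start, row.end):
            hits.add(iv.data)
    return hits


# ---------------------------------------------------------------------------
# Fisher's GSEA


def fisher_gsea(
    query_genes: set[str],
    universe_genes: set[str],
    gene_sets: dict[str, set[str]],
    alternative: str = "greater",
) -> pd.DataFrame:
    """One-sided (enrichment) hypergeometric overrepresentation per gene set,
    BH-adjusted jointly across testable sets.

    The universe defaults to the caller-supplied gene list (e.g. all genes in
    the annotation); each set is intersected with it before testing.  Odds
    ratios use a Haldane 0.5 correction when any 2x2 cell is zero.  Sets
    disjoint from the universe are reported with ``testable=False``.
    """
    query = set(query_genes)
    universe = set(universe_genes)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    n = len(query)
    N = len(universe)
    rows = []
    for set_id, genes in gene_sets.items():
        in_uni = genes & universe
        K = len(in_uni)
        if K == 0:
            rows.append((set_id, 0, n, 0, N, np.nan, np.nan, False))
            continue
        k = len(query & in_uni)
        if alternative == "greater":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            table = [[k, n - k], [K - k, N - n - K + k]]
            p = float(stats.fisher_exact(table, alternative=alternative)[1])
        a, b, c, d = k, n - k, K - k, N - n - K + k
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        rows.append((set_id, k, n, K, N, (a * d) / (b * c), p, True))
    df = pd.DataFrame(
        rows, columns=["set_id", "overlap", "query_n", "set_n", "universe_n", "odds_ratio", "p", "testable"]
    )
    df["p_adj"] = np.nan
    mask = df["testable"].to_numpy()
    if mask.any():
        df.loc[mask, "p_adj"] = benjamini_hochberg(df.loc[mask, "p"].to_numpy())
    return df.sort_values("p", na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Random control regions and feature enrichment


def random_matched_regions(
    dmrs, chrom_sizes: dict[str, int], n_draws: int, seed: int
) -> pd.DataFrame:
    """For each draw, every DMR is replaced by a uniformly placed interval of
    identical length on the same chromosome.  Columns: draw, chrom, start, end.
    """
    dmr_df = _as_interval_frame(dmrs)
    rng = np.random.default_rng(seed)
    chroms = dmr_df["chrom"].to_numpy()
    lengths = (dmr_df["end"] - dmr_df["start"]).to_numpy()
    for chrom, ln in zip(chroms, lengths):
        if chrom not in chrom_sizes:
            raise ValueError(f"no size for chromosome {chrom}")
        if ln > chrom_sizes[chrom]:
            raise ValueError(f"DMR of length {ln} exceeds chromosome {chrom}")
    max_start = np.array([chrom_sizes[c] for c in chroms]) - lengths
    out = []
    for d in range(n_draws):
        starts = rng.integers(0, max_start + 1)
        out.append(pd.DataFrame({"draw": d, "chrom": chroms, "start": starts, "end": starts + lengths}))
    return pd.concat(out, ignore_index=True)


def _overlap_fraction(query: pd.DataFrame, feat_starts: dict, feat_ends: dict) -> float:
    """Fraction of query intervals overlapping any merged feature interval."""
    n_hit = 0
    for row in query.itertuples(index=False):
        st = feat_starts.get(row.chrom)
        if st is None:
            continue
        en = feat_ends[row.chrom]
        i = np.searchsorted(en, row.start, side="right")
        if i < len(st) and st[i] < row.end:
            n_hit += 1
    return n_hit / len(query)


def _merge_intervals(df: pd.DataFrame) -> tuple[dict, dict]:
    starts, ends = {}, {}
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom"):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        ms, me = [s[0]], [e[0]]
        for a, b in zip(s[1:], e[1:]):
            if a <= me[-1]:
                me[-1] = max(me[-1], b)
            else:
                ms.append(a)
                me.append(b)
        starts[chrom] = np.array(ms)
        ends[chrom] = np.array(me)
    return starts, ends


def feature_enrichment(
    dmrs,
    features: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int],
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per feature class: observed DMR-overlap fraction vs the fraction in
    ``n_draws`` random length/chromosome-matched placements.

    empirical p = (1 + #draws >= observed) / (1 + n_draws);
    ratio = observed / mean(null).
    """
    dmr_df = _as_interval_frame(dmrs)
    if len(dmr_df) == 0:
        raise ValueError("no DMRs supplied")
    if n_draws < 100:
        warnings.warn(f"n_draws={n_draws} < 100: empirical p-values will be unstable")
    draws = random_matched_regions(dmr_df, chrom_sizes, n_draws, seed)
    rows = []
    for feat_name, feat_df in features.items():
        st, en = _merge_intervals(feat_df)
        observed = _overlap_fraction(dmr_df, st, en)
        null = np.array(
            [_overlap_fraction(sub, st, en) for _, sub in draws.groupby("draw", sort=True)]
        )
        p = (1 + int(np.sum(null >= observed))) / (1 + n_draws)
        mean_null = float(null.mean())
        ratio = observed / mean_null if mean_null > 0 else np.inf if observed > 0 else np.nan
        rows.append((feat_name, observed, mean_null, ratio, p))
    return pd.DataFrame(rows, columns=["feature", "observed", "null_mean", "ratio", "p"])
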