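"""Meta-region methylation profiles and DNA-methylation memory
classification for recovered (post-transition) samples.

A meta-region profile rescales every DMR to relative coordinates [0, 1]
with flanks of ``buffer_frac`` times the region width on each side
(default 0.5, i.e. the profiled genomic span is twice the DMR width) and
averages smoothed methylation into fixed bins per group, unweighted across
regions.

Memory classification compares, over each DMR's member CpGs, the recovered
group's departure from the control mean (d_rec) with the transition group's
departure (d_adm): ``reverted`` (|d_rec| <= tol), ``opposite`` (signs
disagree), ``more_extreme`` (|d_rec| >= |d_adm|) or ``intermediate``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import dmr_gene_overlap

__all__ = [
    "MetaRegionProfile",
    "MemoryOverlap",
    "meta_region_profile",
    "classify_recovery",
    "memory_overlap",
    "extreme_subset",
    "dmr_group_means",
]

RECOVERY_CLASSES = ("reverted", "intermediate", "more_extreme", "opposite")


@dataclass
class MetaRegionProfile:
    """Binned group-mean methylation over rescaled DMRs.

    ``table`` columns: bin (index), bin_center (relative coordinate in
    [-buffer_frac, 1 + buffer_frac]), group, mean, n_regions (regions
    contributing to the bin).  ``in_region`` marks bins inside [0, 1].
    """

    table: pd.DataFrame
    n_regions: int
    buffer_frac: float
    n_bins_region: int
    n_bins_flank: int

    def group_matrix(self) -> pd.DataFrame:
        """bins x groups pivot of the mean methylation."""
        return self.table.pivot(index="bin_center", columns="group", values="mean")


def meta_region_profile(
    dmrs,
    group_values: dict[str, pd.DataFrame],
    buffer_frac: float = 0.5,
    n_bins_region: int = 30,
    n_bins_flank: int = 15,
    directions: str | None = None,
) -> MetaRegionProfile:
    """Average group methylation over DMRs rescaled to [0, 1] + flanks.

    ``group_values``: per group a DataFrame (chrom, pos, value) of smoothed
    methylation — typically the replicate mean per group.  Each DMR
    contributes its per-bin CpG mean; bins are then averaged unweighted
    across DMRs (a region with no CpG in a bin simply does not contribute
    there).  ``directions``: restrict to "hyper" or "hypo" DMRs.
    """
    dmr_list = list(dmrs)
    if directions is not None:
        dmr_list = [d for d in dmr_list if d.direction == directions]
    if not dmr_list:
        raise ValueError("no DMRs to profile")
    edges = np.linspace(-buffer_frac, 1.0 + buffer_frac, 2 * n_bins_flank + n_bins_region + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins = len(centers)

    indexed = {
        g: df.set_index(["chrom", "pos"]).sort_index() for g, df in group_values.items()
    }
    sums = {g: np.zeros(n_bins) for g in group_values}
    counts = {g: np.zeros(n_bins, dtype=int) for g in group_values}
    for d in dmr_list:
        w = d.end - d.start
        lo = d.start - buffer_frac * w
        hi = d.end + buffer_frac * w
        for g, df in indexed.items():
            try:
                sub = df.loc[d.chrom]
            except KeyError:
                continue
            pos = sub.index.to_numpy()
            sel = (pos - 1 >= lo) & (pos - 1 < hi)
            if not sel.any():
                continue
            rel = (pos[sel] - 1 - d.start) / w
            vals = sub["value"].to_numpy()[sel]
            ok = np.isfinite(vals)
            if not ok.any():
                continue
            which = np.clip(np.digitize(rel[ok], edges) - 1, 0, n_bins - 1)
            binsum = np.zeros(n_bins)
            np.add.at(binsum, which, vals[ok])
            cnt = np.bincount(which, minlength=n_bins)
            nonzero = cnt > 0
            sums[g][nonzero] += binsum[nonzero] / cnt[nonzero]
            counts[g][nonzero] += 1
    rows = []
    in_region = (centers >= 0.0) & (centers <= 1.0)
    for g in group_values:
        with np.errstate(invalid="ignore"):
            means = np.where(counts[g] > 0, sums[g] / np.maximum(counts[g], 1), np.nan)
        for i in range(n_bins):
            rows.append((i, centers[i], bool(in_region[i]), g, means[i], int(counts[g][i])))
    table = pd.DataFrame(
        rows, columns=["bin", "bin_center", "in_region", "group", "mean", "n_regions"]
    )
    return MetaRegionProfile(
        table=table,
        n_regions=len(dmr_list),
        buffer_frac=buffer_frac,
        n_bins_region=n_bins_region,
        n_bins_flank=n_bins_flank,
    )


def classify_recovery(
    mean_control: float, mean_adm: float, mean_recovered: float, tol: float = 0.01
) -> str:
    """Label the recovered group's methylation at one DMR relative to the
    control -> transition axis.  Raises if the region is not differential
    for the trio (|mean_adm - mean_control| <= tol)."""
    d_adm = mean_adm - mean_control
    d_rec = mean_recovered - mean_control
    if abs(d_adm) <= tol:
        raise ValueError("not a differential region for this trio (|d_adm| <= tol)")
    if abs(d_rec) <= tol:
        return "reverted"
    if np.sign(d_rec) != np.sign(d_adm):
        return "opposite"
    if abs(d_rec) >= abs(d_adm):
        return "more_extreme"
    return "intermediate"


@dataclass
class MemoryOverlap:
    """Gene-level overlap of two DMR sets.

    All three denominators are reported explicitly: the first set, the
    second set, and their union."""

    genes_a: set[str]
    genes_b: set[str]

    @property
    def shared(self) -> set[str]:
        return self.genes_a & self.genes_b

    @property
    def fraction_of_a(self) -> float:
        return len(self.shared) / len(self.genes_a) if self.genes_a else 0.0

    @property
    def fraction_of_b(self) -> float:
        return len(self.shared) / len(self.genes_b) if self.genes_b else 0.0

    @property
    def fraction_of_union(self) -> float:
        union = self.genes_a | self.genes_b
        return len(self.shared) / len(union) if union else 0.0

    def summary(self) -> dict:
        return {
            "n_a": len(self.genes_a),
            "n_b": len(self.genes_b),
            "n_shared": len(self.shared),
            "fraction_of_a": self.fraction_of_a,
            "fraction_of_b": self.fraction_of_b,
            "fraction_of_union": self.fraction_of_union,
        }


def memory_overlap(dmrs_recovered, dmrs_adm, annotation: pd.DataFrame, feature_classes=None) -> MemoryOverlap:
    """Genes overlapped by recovered-vs-control DMRs intersected with genes
    overlapped by transition-vs-control DMRs."""
    if annotation is None or len(annotation) == 0:
        raise ValueError("empty annotation")
    return MemoryOverlap(
        genes_a=dmr_gene_overlap(dmrs_recovered, annotation, feature_classes),
        genes_b=dmr_gene_overlap(dmrs_adm, annotation, feature_classes),
    )


def dmr_group_means(dmrs, group_values: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Mean of each group's (smoothed) methylation over every DMR's member
    CpGs.  Rows align with ``dmrs``; columns are group labels."""
    indexed = {g: df.set_index(["chrom", "pos"]).sort_index() for g, df in group_values.items()}
    rows = []
    for d in dmrs:
        row = {}
        for g, df in indexed.items():
            try:
                sub = df.loc[d.chrom]
            except KeyError:
                row[g] = np.nan
                continue
            pos = sub.index.to_numpy()
            sel = (pos - 1 >= d.start) & (pos - 1 < d.end)
            vals = sub["value"].to_numpy()[sel]
            row[g] = float(np.nanmean(vals)) if sel.any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _more_extreme(d_rec: float, d_adm: float, tol: float) -> bool:
    # sign of a sub-tolerance ADM difference is noise; compare magnitudes only
    if abs(d_adm) <= tol:
        return abs(d_rec) >= abs(d_adm)
    return np.sign(d_rec) == np.sign(d_adm) and abs(d_rec) >= abs(d_adm)


def extreme_subset(
    dmrs,
    group_means: pd.DataFrame,
    control: str = "acinar",
    adm_groups: tuple[str, str] = ("adm_d2", "adm_d4"),
    recovered: str = "recovered",
    tol: float = 0.01,
):
    """DMRs where the recovered methylation is more extreme than BOTH
    transition timepoints relative to the control (conjunctive rule).

    ``group_means``: one row per DMR (aligned), columns naming the groups.
    A missing (NaN) mean raises, naming the DMR."""
    dmr_list = list(dmrs)
    needed = [control, recovered, *adm_groups]
    out = []
    for i, d in enumerate(dmr_list):
        row = group_means.iloc[i]
        for col in needed:
            if col not in group_means.columns or not np.isfinite(row[col]):
                raise ValueError(f"missing group mean {col!r} for DMR {d.chrom}:{d.start}-{d.end}")
        d_rec = row[recovered] - row[control]
        if all(_more_extreme(d_rec, row[g] - row[control], tol) for g in adm_groups):
            out.append(d)
    return out
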