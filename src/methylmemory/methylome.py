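"""Smoothed differential-methylation analysis of WGBS CpG reports.

The model: per-sample raw methylation ``M/(M+U)`` at each CpG is smoothed with
a coverage-weighted local quadratic fit (tricube kernel over the smallest
window holding at least ``ns`` CpGs and spanning at least ``2h`` bp).  Between
two replicate groups a per-CpG t-statistic is formed from the smoothed means,
with a pooled replicate standard deviation that is floored at a genome-wide
quantile and then smoothed over ``k`` CpGs, and optionally corrected by
subtracting a coarse local trend.  Candidate DMRs are maximal sign-pure runs
of CpGs beyond empirical t quantiles; they are split at inter-CpG gaps over
300 bp and filtered on CpG count and mean methylation difference.

Coordinates: CpG positions are 1-based (Bismark CpG-report dialect); emitted
DMR intervals are 0-based half-open (BED).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "MethylationSample",
    "SmoothParams",
    "TStatParams",
    "Dmr",
    "read_cpg_report",
    "write_cpg_report",
    "filter_sites",
    "smooth_sample",
    "group_tstat",
    "call_dmrs",
    "refine_dmrs",
    "recheck_dmr",
    "pca_methylomes",
    "dmr_pipeline",
    "dmrs_to_frame",
]

_SEX_CHROMS = {"X", "Y", "M", "MT", "W", "Z"}


class CpgReportParseError(ValueError):
    """Raised for malformed CpG-report lines; carries the line number."""


@dataclass
class MethylationSample:
    """Per-CpG methylated/unmethylated read counts for one replicate.

    ``data`` has columns ``chrom`` (str), ``pos`` (1-based int), ``m`` and
    ``u`` (non-negative read counts), sorted by (chrom, pos) with unique
    positions per chromosome.
    """

    sample_id: str
    group: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        missing = {"chrom", "pos", "m", "u"} - set(d.columns)
        if missing:
            raise ValueError(f"sample data missing columns {sorted(missing)}")
        if len(d) and ((d["m"] < 0).any() or (d["u"] < 0).any()):
            raise ValueError("negative read counts")
        if not d.groupby("chrom", sort=False)["pos"].is_monotonic_increasing.all():
            self.data = d.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
            warnings.warn(f"sample {self.sample_id}: input not sorted; sorted by (chrom, pos)")

    @property
    def coverage(self) -> pd.Series:
        return self.data["m"] + self.data["u"]


@dataclass(frozen=True)
class SmoothParams:
    """Local-regression smoothing window: >= ``min_cpgs_per_window`` CpGs and
    half-width >= ``min_halfwidth`` bp."""

    min_cpgs_per_window: int = 70
    min_halfwidth: int = 1000

    def __post_init__(self) -> None:
        if self.min_cpgs_per_window < 1 or self.min_halfwidth < 1:
            raise ValueError("smoothing parameters must be >= 1")


@dataclass(frozen=True)
class TStatParams:
    k: int = 21
    local_correct: bool = True
    var_floor_quantile: float = 0.75
    correct_halfwidth: int = 25_000
    qlow: float = 0.05
    qhigh: float = 0.95

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 3")
        if not (0.0 < self.qlow < self.qhigh < 1.0):
            raise ValueError("require 0 < qlow < qhigh < 1")
        if not (0.0 <= self.var_floor_quantile < 1.0):
            raise ValueError("var_floor_quantile must be in [0, 1)")


@dataclass
class Dmr:
    """A called differentially methylated region (BED-style half-open)."""

    chrom: str
    start: int
    end: int
    n_cpg: int
    mean_diff: float
    direction: str  # "hyper" => group A more methylated than group B
    area_stat: float
    positions: np.ndarray = field(default=None, repr=False)  # 1-based member CpGs
    diffs: np.ndarray = field(default=None, repr=False)
    tstats: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# I/O


def read_cpg_report(path, sample_id: str | None = None, group: str = "") -> MethylationSample:
    """Read a Bismark-style CpG report (optionally gzipped).

    Expected tab-separated columns: chrom, pos (1-based), strand, count
    methylated, count unmethylated; extra columns (context, trinucleotide)
    are ignored.  +/- records belonging to the same CpG dinucleotide (minus
    strand at pos+1) are collapsed onto the plus-strand coordinate with
    summed counts.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    chroms: list[str] = []
    poss: list[int] = []
    ms: list[int] = []
    us: list[int] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                parts = line.split()
            if len(parts) < 5:
                raise CpgReportParseError(f"{path}:{lineno}: expected >= 5 fields, got {len(parts)}")
            chrom, pos_s, strand, m_s, u_s = parts[:5]
            try:
                pos, m, u = int(pos_s), int(m_s), int(u_s)
            except ValueError as exc:
                raise CpgReportParseError(f"{path}:{lineno}: {exc}") from None
            if strand == "-":
                pos -= 1  # collapse onto the plus-strand C of the dinucleotide
            chroms.append(chrom)
            poss.append(pos)
            ms.append(m)
            us.append(u)
    df = pd.DataFrame({"chrom": chroms, "pos": poss, "m": ms, "u": us})
    if len(df):
        df = (
            df.groupby(["chrom", "pos"], sort=True, as_index=False)[["m", "u"]]
            .sum()
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
    if sample_id is None:
        sample_id = str(path)
    return MethylationSample(sample_id=sample_id, group=group, data=df)


def write_cpg_report(sample: MethylationSample, path) -> None:
    """Write plus-strand-collapsed counts in the CpG-report dialect."""
    with open(path, "w") as fh:
        for row in sample.data.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t+\t{row.m}\t{row.u}\tCG\tCGN\n")


# ---------------------------------------------------------------------------
# Site filtering


def is_autosome(chrom: str) -> bool:
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return name.upper() not in _SEX_CHROMS and name.isdigit()


def cpg_universe(samples: list[MethylationSample]) -> pd.DataFrame:
    """Outer-join the (chrom, pos) sets of all samples, sorted."""
    frames = [s.data[["chrom", "pos"]] for s in samples]
    uni = pd.concat(frames).drop_duplicates().sort_values(["chrom", "pos"], kind="mergesort")
    return uni.reset_index(drop=True)


def filter_sites(
    samples: list[MethylationSample],
    min_cov: int = 2,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """CpGs covered >= ``min_cov`` in EVERY replicate (absent = coverage 0),
    optionally restricted to autosomes.  Returns the kept (chrom, pos) table.
    """
    uni = cpg_universe(samples)
    idx = pd.MultiIndex.from_frame(uni)
    keep = np.ones(len(uni), dtype=bool)
    for s in samples:
        cov = pd.Series(
            (s.data["m"] + s.data["u"]).to_numpy(),
            index=pd.MultiIndex.from_frame(s.data[["chrom", "pos"]]),
        )
        cov = cov.reindex(idx, fill_value=0)
        keep &= cov.to_numpy() >= min_cov
    if autosomes_only:
        keep &= uni["chrom"].map(is_autosome).to_numpy()
    kept = uni.loc[keep].reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError("no CpG passed the coverage/autosome filter")
    return kept


# ---------------------------------------------------------------------------
# Smoothing


def _smooth_chrom(pos: np.ndarray, raw: np.ndarray, cov: np.ndarray, ns: int, h: int) -> np.ndarray:
    """BSmooth-style local quadratic fit along one chromosome.

    ``raw`` entries at coverage-0 sites are placeholders with zero weight.
    Returns fitted values clamped to [0, 1]; NaN where no covered CpG falls
    inside the window.
    """
    n = len(pos)
    out = np.empty(n)
    ns_eff = min(ns, n)
    posf = pos.astype(float)
    L = 0
    for i in range(n):
        # smallest ns_eff-CpG window (nearest neighbours in a sorted array)
        while L + ns_eff <= n - 1 and (
            L + ns_eff - 1 < i or (posf[L + ns_eff] - posf[i]) < (posf[i] - posf[L])
        ):
            L += 1
        hw = max(float(h), posf[i] - posf[L], posf[L + ns_eff - 1] - posf[i])
        a = np.searchsorted(posf, posf[i] - hw, side="left")
        b = np.searchsorted(posf, posf[i] + hw, side="right")
        d = (posf[a:b] - posf[i]) / hw
        tri = (1.0 - np.minimum(np.abs(d), 1.0) ** 3) ** 3
        w = tri * cov[a:b]
        sw = w.sum()
        if sw <= 0.0:
            out[i] = np.nan
            continue
        y = raw[a:b]
        d2 = d * d
        s0 = sw
        s1 = (w * d).sum()
        s2 = (w * d2).sum()
        s3 = (w * d * d2).sum()
        s4 = (w * d2 * d2).sum()
        t0 = (w * y).sum()
        t1 = (w * y * d).sum()
        t2 = (w * y * d2).sum()
        A = np.array([[s0, s1, s2], [s1, s2, s3], [s2, s3, s4]])
        c = np.array([t0, t1, t2])
        try:
            beta = np.linalg.solve(A, c)
            val = beta[0]
        except np.linalg.LinAlgError:
            val = t0 / s0
        if not np.isfinite(val):
            val = t0 / s0
        out[i] = min(1.0, max(0.0, val))
    return out


def smooth_sample(
    sample: MethylationSample,
    params: SmoothParams | None = None,
    at: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Smooth one sample's raw methylation per chromosome.

    ``at``: optional (chrom, pos) table of evaluation sites (a shared CpG
    universe); sites absent from the sample enter with coverage 0 and thus
    zero weight.  Returns columns chrom, pos, smoothed, flagged — ``flagged``
    marks chromosomes with < 3 CpGs where raw ratios are returned as-is.
    """
    params = params or SmoothParams()
    d = sample.data
    if at is not None:
        idx = pd.MultiIndex.from_frame(at[["chrom", "pos"]])
        own = d.set_index(["chrom", "pos"])[["m", "u"]].reindex(idx, fill_value=0)
        d = own.reset_index()
        d.columns = ["chrom", "pos", "m", "u"]
    out_frames = []
    for chrom, sub in d.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        cov = (sub["m"] + sub["u"]).to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(cov > 0, sub["m"].to_numpy(dtype=float) / np.maximum(cov, 1.0), 0.5)
        if len(pos) < 3:
            vals = np.where(cov > 0, raw, np.nan)
            flagged = True
        else:
            vals = _smooth_chrom(pos, raw, cov, params.min_cpgs_per_window, params.min_halfwidth)
            flagged = False
        out_frames.append(
            pd.DataFrame({"chrom": chrom, "pos": pos, "smoothed": vals, "flagged": flagged})
        )
    if not out_frames:
        return pd.DataFrame(columns=["chrom", "pos", "smoothed", "flagged"])
    return pd.concat(out_frames, ignore_index=True)


def smooth_group(
    samples: list[MethylationSample],
    params: SmoothParams | None = None,
    at: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Smoothed values for several samples on a common (chrom, pos) index.

    Returns a DataFrame indexed by (chrom, pos) with one column per sample.
    """
    if at is None:
        at = cpg_universe(samples)
    cols = {}
    for s in samples:
        sm = smooth_sample(s, params, at=at)
        cols[s.sample_id] = sm["smoothed"].to_numpy()
    idx = pd.MultiIndex.from_frame(at[["chrom", "pos"]])
    return pd.DataFrame(cols, index=idx)


def group_mean_tracks(
    samples: list[MethylationSample],
    smooth_params: SmoothParams | None = None,
    smoothed: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Replicate-mean smoothed methylation per group label.

    Returns ``{group: DataFrame(chrom, pos, value)}`` on the shared CpG
    universe — the input format for meta-region profiles and per-DMR group
    means."""
    if smoothed is None:
        smoothed = smooth_group(samples, smooth_params)
    out: dict[str, pd.DataFrame] = {}
    groups: dict[str, list[str]] = {}
    for s in samples:
        groups.setdefault(s.group, []).append(s.sample_id)
    base = smoothed.index.to_frame(index=False)
    base.columns = ["chrom", "pos"]
    for g, ids in groups.items():
        df = base.copy()
        df["value"] = smoothed[ids].mean(axis=1).to_numpy()
        out[g] = df
    return out


# ---------------------------------------------------------------------------
# t-statistics


def tstat_core(
    mean_a: np.ndarray, mean_b: np.ndarray, sd: np.ndarray, n_a: int, n_b: int
) -> np.ndarray:
    """t = (mean_a - mean_b) / (sd * sqrt(1/n_a + 1/n_b))."""
    return (mean_a - mean_b) / (sd * np.sqrt(1.0 / n_a + 1.0 / n_b))


def _local_trend(pos: np.ndarray, t: np.ndarray, halfwidth: int) -> np.ndarray:
    """Coarse trend of t along the chromosome: bin medians at halfwidth/5
    resolution, running-mean over +-halfwidth, linearly interpolated back."""
    binw = max(1, halfwidth // 5)
    bins = (pos - pos.min()) // binw
    ser = pd.Series(t).groupby(bins).median()
    centers = pos.min() + (ser.index.to_numpy() + 0.5) * binw
    if len(ser) < 2:
        return np.full_like(t, float(np.median(t)))
    smoothed = uniform_filter1d(ser.to_numpy(dtype=float), size=11, mode="nearest")
    return np.interp(pos, centers, smoothed)


def group_tstat(
    group_a: list[MethylationSample],
    group_b: list[MethylationSample],
    params: TStatParams | None = None,
    smooth_params: SmoothParams | None = None,
    sites: pd.DataFrame | None = None,
    smoothed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-CpG smoothed-mean t-statistic track between two replicate groups.

    ``sites``: kept (chrom, pos) from :func:`filter_sites` (computed with
    defaults if omitted).  ``smoothed``: optional precomputed output of
    :func:`smooth_group` over all samples (indexed by (chrom, pos), columns
    = sample ids) to avoid re-smoothing.

    Returns a track with columns chrom, pos, mean_a, mean_b, diff, sd_pool,
    t_raw, t_corrected.  Sign convention: positive t and "hyper" direction
    mean group A is more methylated.
    """
    params = params or TStatParams()
    for label, grp in (("A", group_a), ("B", group_b)):
        if len(grp) < 2:
            raise ValueError(f"group {label} has {len(grp)} replicate(s); >= 2 required")
    samples = list(group_a) + list(group_b)
    if sites is None:
        sites = filter_sites(samples)
    if smoothed is None:
        smoothed = smooth_group(samples, smooth_params, at=cpg_universe(samples))
    idx = pd.MultiIndex.from_frame(sites[["chrom", "pos"]])
    sm = smoothed.reindex(idx)
    ids_a = [s.sample_id for s in group_a]
    ids_b = [s.sample_id for s in group_b]
    mat_a = sm[ids_a].to_numpy()
    mat_b = sm[ids_b].to_numpy()
    n_a, n_b = len(ids_a), len(ids_b)
    mean_a = mat_a.mean(axis=1)
    mean_b = mat_b.mean(axis=1)
    var_a = mat_a.var(axis=1, ddof=1)
    var_b = mat_b.var(axis=1, ddof=1)
    sd_pool = np.sqrt(((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2))
    floor = np.quantile(sd_pool, params.var_floor_quantile)
    if floor <= 0:
        positive = sd_pool[sd_pool > 0]
        floor = float(positive.min()) if len(positive) else 1e-8
    sd_floored = np.maximum(sd_pool, floor)

    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    sd_smooth = np.empty_like(sd_floored)
    t_raw = np.empty_like(sd_floored)
    t_corr = np.empty_like(sd_floored)
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        k = min(params.k, int(m.sum()))
        sd_smooth[m] = uniform_filter1d(sd_floored[m], size=max(k, 1), mode="nearest")
        t_raw[m] = tstat_core(mean_a[m], mean_b[m], sd_smooth[m], n_a, n_b)
        if params.local_correct:
            t_corr[m] = t_raw[m] - _local_trend(pos[m], t_raw[m], params.correct_halfwidth)
        else:
            t_corr[m] = t_raw[m]
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "diff": mean_a - mean_b,
            "sd_pool": sd_smooth,
            "t_raw": t_raw,
            "t_corrected": t_corr,
        }
    )


# ---------------------------------------------------------------------------
# DMR calling


def _make_dmr(chrom: str, pos: np.ndarray, diffs: np.ndarray, t: np.ndarray) -> Dmr:
    mean_diff = float(diffs.mean())
    return Dmr(
        chrom=chrom,
        start=int(pos[0]) - 1,
        end=int(pos[-1]),
        n_cpg=len(pos),
        mean_diff=mean_diff,
        direction="hyper" if mean_diff >= 0 else "hypo",
        area_stat=float(t.sum()),
        positions=pos.copy(),
        diffs=diffs.copy(),
        tstats=t.copy(),
    )


def call_dmrs(track: pd.DataFrame, params: TStatParams | None = None) -> list[Dmr]:
    """Candidate DMRs: maximal sign-pure runs of consecutive retained CpGs
    with t_corrected beyond the empirical (qlow, qhigh) quantiles."""
    params = params or TStatParams()
    if len(track) == 0:
        raise ValueError("empty t-statistic track")
    t_all = track["t_corrected"].to_numpy()
    c_lo, c_hi = np.quantile(t_all, [params.qlow, params.qhigh])
    candidates: list[Dmr] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        t = sub["t_corrected"].to_numpy()
        pos = sub["pos"].to_numpy()
        diffs = sub["diff"].to_numpy()
        state = np.zeros(len(t), dtype=np.int8)
        state[t > c_hi] = 1
        state[t < c_lo] = -1
        if not state.any():
            continue
        boundaries = np.flatnonzero(np.diff(state) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [len(t)]])
        for a, b in zip(starts, ends):
            if state[a] == 0:
                continue
            candidates.append(_make_dmr(chrom, pos[a:b], diffs[a:b], t[a:b]))
    return candidates


def refine_dmrs(
    candidates: list[Dmr],
    min_cpg: int = 5,
    min_diff: float = 0.10,
    max_gap: int = 300,
    order: str = "split-then-filter",
) -> list[Dmr]:
    """Split candidates at inter-CpG gaps > ``max_gap`` bp, then keep
    fragments with >= ``min_cpg`` CpGs and |mean diff| >= ``min_diff``
    (both inclusive; recomputed per fragment).

    ``order="filter-then-split"`` applies the count/difference filters to
    whole candidates before splitting (the literal order in some write-ups);
    the default guarantees every emitted DMR satisfies all constraints.
    """
    if order not in {"split-then-filter", "filter-then-split"}:
        raise ValueError(f"unknown order {order!r}")

    def passes(d: Dmr) -> bool:
        # inclusive threshold with a guard against float summation error
        return d.n_cpg >= min_cpg and abs(d.mean_diff) >= min_diff - 1e-12

    def split(d: Dmr) -> list[Dmr]:
        gaps = np.diff(d.positions)
        cut = np.flatnonzero(gaps > max_gap) + 1
        if len(cut) == 0:
            return [d]
        pieces = []
        for seg_pos, seg_diff, seg_t in zip(
            np.split(d.positions, cut), np.split(d.diffs, cut), np.split(d.tstats, cut)
        ):
            pieces.append(_make_dmr(d.chrom, seg_pos, seg_diff, seg_t))
        return pieces

    out: list[Dmr] = []
    for cand in candidates:
        if order == "filter-then-split" and not passes(cand):
            continue
        for frag in split(cand):
            if passes(frag):
                out.append(frag)
    return out


def recheck_dmr(dmr: Dmr, min_cpg: int = 5, min_diff: float = 0.10, max_gap: int = 300) -> bool:
    """Brute-force re-check of the filter rules from the raw member lists:
    CpG count, |mean diff|, max gap, and t-sign purity."""
    if dmr.positions is None or len(dmr.positions) != dmr.n_cpg:
        return False
    if dmr.n_cpg < min_cpg:
        return False
    if abs(float(np.mean(dmr.diffs))) < min_diff - 1e-12:
        return False
    if dmr.n_cpg > 1 and int(np.max(np.diff(dmr.positions))) > max_gap:
        return False
    signs = np.sign(dmr.tstats)
    if len(set(signs.tolist())) != 1:
        return False
    if dmr.start != int(dmr.positions[0]) - 1 or dmr.end != int(dmr.positions[-1]):
        return False
    return True


def dmrs_to_frame(dmrs: list[Dmr]) -> pd.DataFrame:
    """BED6+ table: name = direction, score = round(1000*|mean_diff|)."""
    return pd.DataFrame(
        {
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "name": [d.direction for d in dmrs],
            "score": [round(1000 * abs(d.mean_diff)) for d in dmrs],
            "strand": ".",
            "n_cpg": [d.n_cpg for d in dmrs],
            "mean_diff": [d.mean_diff for d in dmrs],
            "area_stat": [d.area_stat for d in dmrs],
        }
    )


# ---------------------------------------------------------------------------
# PCA


def pca_methylomes(
    samples: list[MethylationSample],
    smooth_params: SmoothParams | None = None,
    smoothed: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on smoothed methylation, columns centred and scaled to
    unit variance (zero-variance CpGs dropped).  Returns (coordinates indexed
    by sample id with columns PC1.., explained-variance fractions)."""
    if len(samples) < 3:
        raise ValueError("PCA requires >= 3 samples")
    if smoothed is None:
        smoothed = smooth_group(samples, smooth_params)
    mat = smoothed[[s.sample_id for s in samples]].to_numpy().T  # samples x CpGs
    mat = mat[:, np.all(np.isfinite(mat), axis=0)]
    sd = mat.std(axis=0, ddof=1)
    keep = sd > 0
    mat = (mat[:, keep] - mat[:, keep].mean(axis=0)) / sd[keep]
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    coords = u * s
    evr = s**2 / np.sum(s**2)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=[x.sample_id for x in samples], columns=cols), evr


# ---------------------------------------------------------------------------
# End-to-end pipeline


def dmr_pipeline(
    group_a: list[MethylationSample],
    group_b: list[MethylationSample],
    min_cov: int = 2,
    autosomes_only: bool = True,
    smooth_params: SmoothParams | None = None,
    tstat_params: TStatParams | None = None,
    min_cpg: int = 5,
    min_diff: float = 0.10,
    max_gap: int = 300,
    smoothed: pd.DataFrame | None = None,
) -> tuple[list[Dmr], pd.DataFrame]:
    """Coverage filter -> smooth -> t-statistics -> quantile candidates ->
    split/filter refinement.  Returns (refined DMRs, t-statistic track)."""
    sites = filter_sites(list(group_a) + list(group_b), min_cov=min_cov, autosomes_only=autosomes_only)
    track = group_tstat(
        group_a, group_b, tstat_params, smooth_params, sites=sites, smoothed=smoothed
    )
    candidates = call_dmrs(track, tstat_params)
    return refine_dmrs(candidates, min_cpg=min_cpg, min_diff=min_diff, max_gap=max_gap), track
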