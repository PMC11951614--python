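"""Seeded synthetic-data generators with recoverable ground truth.

Emulates the data structure of an acinar-ductal metaplasia (ADM) methylation
study: grouped replicate WGBS methylomes (normal acinar, ADM, recovered,
duct) with planted DMRs and a tunable "memory" level in the recovered group;
genomes with planted transcription-factor motif occurrences; gene annotation
and gene-set collections; and imaging-based cell-by-gene panels with a
tunable fraction of transition cells co-expressing two marker programs.

Methylome model
---------------
CpG positions arise from two superimposed homogeneous point processes
(sparse background + dense islands), reproducing the clustered spacing the
smoother and the 300-bp split rule are sensitive to.  Per-CpG coverage is
negative-binomial; methylated counts are beta-binomial, giving the replicate
overdispersion a t-statistic denominator needs.  Inside each planted DMR the
group mean is shifted by a signed ``delta``; the recovered group is shifted
by ``memory_multiplier * delta`` (0.5 = intermediate recovery, >1 = more
extreme than peak ADM).  A short chromosome named "chrX" is always generated
so the autosome-restriction filter is exercised.  All generators are pure
functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexpression import MarkerPanel
from .enrichment import GenomicInterval
from .methylome import MethylationSample

__all__ = [
    "GroupSpec",
    "MethylomeSimConfig",
    "GenomeSimConfig",
    "AnnotationSimConfig",
    "CellTypeSpec",
    "CellSimConfig",
    "TruthSet",
    "simulate_methylomes",
    "simulate_genome_and_motifs",
    "simulate_annotation",
    "simulate_cell_panel",
    "recovery_stats",
    "write_fasta",
]

_CLAMP_LO, _CLAMP_HI = 0.02, 0.98


@dataclass(frozen=True)
class GroupSpec:
    """One replicate group.

    ``dmr_multiplier`` scales the planted shift inside DMRs: 0 for the
    control group, 1 for the fully shifted (ADM) group, and ``None`` to use
    the config's ``memory_multiplier`` (the recovered group).
    """

    label: str
    n_replicates: int
    baseline_methylation: float
    dmr_multiplier: float | None = 0.0


def _default_groups() -> tuple[GroupSpec, ...]:
    return (
        GroupSpec("acinar", 3, 0.5, 0.0),
        GroupSpec("adm", 3, 0.5, 1.0),
        GroupSpec("recovered", 3, 0.5, None),
    )


@dataclass(frozen=True)
class MethylomeSimConfig:
    n_chrom: int = 1
    chrom_len: int = 2_000_000
    cpg_rate_background: float = 0.01
    island_count: int = 20
    island_len: int = 1000
    island_cpg_rate: float = 0.08
    groups: tuple[GroupSpec, ...] = field(default_factory=_default_groups)
    coverage_mean: float = 12.0
    coverage_dispersion: float = 5.0  # negative-binomial shape; larger = closer to Poisson
    bb_precision: float = 100.0  # beta-binomial a+b; replicate overdispersion
    n_dmrs: int = 20
    dmr_width: int = 2000
    delta: float = 0.3
    memory_multiplier: float | tuple[float, ...] = 0.5
    chrx_len: int = 300_000
    min_dmr_cpgs: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.delta) > 1:
            raise ValueError("|delta| must be <= 1")
        mults = [g.dmr_multiplier for g in self.groups]
        mem = np.atleast_1d(np.asarray(self.memory_multiplier, dtype=float))
        if mem.size not in (1, self.n_dmrs):
            raise ValueError("memory_multiplier must be scalar or length n_dmrs")
        for g in self.groups:
            if g.n_replicates < 2:
                raise ValueError(f"group {g.label}: >= 2 replicates required")
            if not (0.0 <= g.baseline_methylation <= 1.0):
                raise ValueError(f"group {g.label}: baseline outside [0, 1]")
            gm = np.max(np.abs(mem)) if g.dmr_multiplier is None else abs(g.dmr_multiplier)
            extreme = g.baseline_methylation + gm * abs(self.delta)
            low = g.baseline_methylation - gm * abs(self.delta)
            if extreme > 1.0 + 1e-9 or low < -1e-9:
                raise ValueError(
                    f"group {g.label}: delta*multiplier pushes the mean outside [0, 1]"
                )
        del mults

    @property
    def memory_per_dmr(self) -> np.ndarray:
        mem = np.atleast_1d(np.asarray(self.memory_multiplier, dtype=float))
        return np.broadcast_to(mem, (self.n_dmrs,)).copy() if mem.size == 1 else mem


@dataclass
class TruthSet:
    """Ground truth for a simulation; unused components are None/empty."""

    planted_dmrs: pd.DataFrame | None = None  # chrom, start, end, direction, delta, memory
    planted_motif_sites: pd.DataFrame | None = None  # chrom, start, strand, motif_id
    transition_cell_ids: list[str] = field(default_factory=list)
    group_mean_methylation: pd.DataFrame | None = None  # chrom, pos + one column per group


def _simulate_positions(rng: np.random.Generator, length: int, cfg: MethylomeSimConfig) -> np.ndarray:
    """Superimposed background + island point processes; 1-based positions."""
    n_bg = rng.poisson(cfg.cpg_rate_background * length)
    pos = rng.integers(1, length + 1, size=n_bg)
    island_starts = rng.integers(1, max(2, length - cfg.island_len), size=cfg.island_count)
    extra = []
    for s in island_starts:
        n_is = rng.poisson(cfg.island_cpg_rate * cfg.island_len)
        extra.append(s + rng.integers(0, cfg.island_len, size=n_is))
    if extra:
        pos = np.concatenate([pos] + extra)
    return np.unique(pos)


def _plant_dmrs(
    rng: np.random.Generator,
    cfg: MethylomeSimConfig,
    positions: dict[str, np.ndarray],
    autosomes: list[str],
) -> pd.DataFrame:
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in autosomes}
    rows = []
    signs = np.where(np.arange(cfg.n_dmrs) % 2 == 0, 1.0, -1.0)
    signs = rng.permutation(signs)
    mem = cfg.memory_per_dmr
    for i in range(cfg.n_dmrs):
        for attempt in range(1000):
            chrom = autosomes[int(rng.integers(0, len(autosomes)))]
            start = int(rng.integers(0, cfg.chrom_len - cfg.dmr_width))
            end = start + cfg.dmr_width
            if any(start < e and s < end for s, e in placed[chrom]):
                continue
            pos = positions[chrom]
            n_inside = int(np.searchsorted(pos, end) - np.searchsorted(pos, start + 1))
            if n_inside < cfg.min_dmr_cpgs:
                continue
            placed[chrom].append((start, end))
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "direction": "hyper" if signs[i] > 0 else "hypo",
                    "delta": signs[i] * cfg.delta,
                    "memory": mem[i],
                    "n_cpg": n_inside,
                }
            )
            break
        else:
            raise RuntimeError("could not place a non-overlapping DMR in 1000 attempts")
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_methylomes(config: MethylomeSimConfig) -> tuple[list[MethylationSample], TruthSet]:
    """Generate grouped replicate methylomes with planted DMRs.

    Returns all samples (each tagged with its group label) and a TruthSet
    carrying the planted intervals and the exact per-CpG group means.
    """
    rng = np.random.default_rng(config.seed)
    autosomes = [f"chr{i + 1}" for i in range(config.n_chrom)]
    chrom_lens = {c: config.chrom_len for c in autosomes}
    chrom_lens["chrX"] = config.chrx_len
    positions = {c: _simulate_positions(rng, chrom_lens[c], config) for c in chrom_lens}
    truth_dmrs = _plant_dmrs(rng, config, positions, autosomes)

    # exact per-CpG group means
    chrom_col = np.concatenate([[c] * len(positions[c]) for c in chrom_lens])
    pos_col = np.concatenate([positions[c] for c in chrom_lens])
    mem = config.memory_per_dmr
    group_means: dict[str, np.ndarray] = {}
    for g in config.groups:
        mu = np.full(len(pos_col), g.baseline_methylation)
        for _, d in truth_dmrs.iterrows():
            mult = d["memory"] if g.dmr_multiplier is None else g.dmr_multiplier
            inside = (chrom_col == d["chrom"]) & (pos_col - 1 >= d["start"]) & (pos_col - 1 < d["end"])
            mu[inside] = g.baseline_methylation + mult * d["delta"]
        group_means[g.label] = np.clip(mu, _CLAMP_LO, _CLAMP_HI)

    nb_r = config.coverage_dispersion
    nb_p = nb_r / (nb_r + config.coverage_mean)
    samples: list[MethylationSample] = []
    for g in config.groups:
        mu = group_means[g.label]
        a = mu * config.bb_precision
        b = (1.0 - mu) * config.bb_precision
        for rep in range(g.n_replicates):
            cov = rng.negative_binomial(nb_r, nb_p, size=len(pos_col))
            p = rng.beta(a, b)
            m = rng.binomial(cov, p)
            df = pd.DataFrame(
                {"chrom": chrom_col, "pos": pos_col, "m": m, "u": cov - m}
            )
            samples.append(
                MethylationSample(sample_id=f"{g.label}_rep{rep + 1}", group=g.label, data=df)
            )
    means_df = pd.DataFrame({"chrom": chrom_col, "pos": pos_col, **group_means})
    truth = TruthSet(planted_dmrs=truth_dmrs, group_mean_methylation=means_df)
    return samples, truth


def recovery_stats(called, planted: pd.DataFrame) -> dict[str, float]:
    """Sensitivity (planted DMRs intersected by >= 1 called DMR, >= 1 bp)
    and precision (called DMRs intersecting >= 1 planted DMR)."""
    called_iv = [(d.chrom, d.start, d.end) for d in called]
    hit_planted = 0
    for _, p in planted.iterrows():
        if any(c == p["chrom"] and s < p["end"] and p["start"] < e for c, s, e in called_iv):
            hit_planted += 1
    hit_called = 0
    for c, s, e in called_iv:
        sub = planted[planted["chrom"] == c]
        if ((sub["start"] < e) & (s < sub["end"])).any():
            hit_called += 1
    return {
        "sensitivity": hit_planted / len(planted) if len(planted) else float("nan"),
        "precision": hit_called / len(called_iv) if called_iv else float("nan"),
        "n_planted": len(planted),
        "n_called": len(called_iv),
    }


# ---------------------------------------------------------------------------
# Genome + motif simulation

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GenomeSimConfig:
    chrom_len: int = 100_000
    n_chrom: int = 1
    gc: float = 0.42
    consensus: str = "TGACTCA"  # AP-1 (TPA-response element)
    motif_id: str = "planted"
    n_sites: int = 20
    site_in_fg_fraction: float = 0.5  # fraction of planted sites inside foreground regions
    n_fg_regions: int = 20
    fg_width: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not (6 <= len(self.consensus) <= 12):
            raise ValueError("consensus length must be 6-12")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("GC fraction must be in (0, 1)")
        if set(self.consensus) - set("ACGT"):
            raise ValueError("consensus must be ACGT only")


def simulate_genome_and_motifs(
    config: GenomeSimConfig,
) -> tuple[dict[str, str], list[GenomicInterval], TruthSet]:
    """i.i.d. background sequence at the stated GC with exact consensus
    occurrences planted at recorded positions/strands; a fraction of sites
    fall inside designated foreground regions (one site per region).

    Minus-strand plants insert the reverse complement at the recorded
    coordinates.  Overlapping plants are refused (resampled, then error).
    """
    rng = np.random.default_rng(config.seed)
    probs = [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    alphabet = np.array(list("ACGT"))
    genome: dict[str, np.ndarray] = {}
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chrom)]
    for c in chrom_names:
        genome[c] = alphabet[rng.choice(4, size=config.chrom_len, p=probs)]

    # non-overlapping foreground regions on chr1
    fg: list[GenomicInterval] = []
    occupied: list[tuple[int, int]] = []
    for i in range(config.n_fg_regions):
        for _ in range(1000):
            start = int(rng.integers(0, config.chrom_len - config.fg_width))
            end = start + config.fg_width
            if any(start < e and s < end for s, e in occupied):
                continue
            occupied.append((start, end))
            fg.append(GenomicInterval("chr1", start, end, name=f"fg{i:03d}"))
            break
        else:
            raise RuntimeError("could not place non-overlapping foreground regions")

    L = len(config.consensus)
    n_in = int(round(config.n_sites * config.site_in_fg_fraction))
    planted: list[tuple[str, int, str]] = []
    site_spans: list[tuple[str, int, int]] = []

    def try_plant(chrom: str, start: int) -> bool:
        if any(c == chrom and start < e and s < start + L for c, s, e in site_spans):
            return False
        strand = "+" if rng.random() < 0.5 else "-"
        site = config.consensus if strand == "+" else revcomp(config.consensus)
        genome[chrom][start : start + L] = list(site)
        planted.append((chrom, start, strand))
        site_spans.append((chrom, start, start + L))
        return True

    for region in fg[:n_in]:
        for _ in range(1000):
            start = int(rng.integers(region.start, region.end - L))
            if try_plant(region.chrom, start):
                break
        else:
            raise RuntimeError("could not plant a site without overlap")
    for _ in range(config.n_sites - n_in):
        for _ in range(1000):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            start = int(rng.integers(0, config.chrom_len - L))
            in_fg = any(
                r.chrom == chrom and start < r.end and r.start < start + L for r in fg
            )
            if in_fg:
                continue
            if try_plant(chrom, start):
                break
        else:
            raise RuntimeError("could not plant a background site without overlap")

    sites = pd.DataFrame(planted, columns=["chrom", "start", "strand"])
    sites["motif_id"] = config.motif_id
    sites = sites.sort_values(["chrom", "start"]).reset_index(drop=True)
    seqs = {c: "".join(genome[c]) for c in genome}
    return seqs, fg, TruthSet(planted_motif_sites=sites)


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation + gene sets


@dataclass(frozen=True)
class AnnotationSimConfig:
    n_genes: int = 100
    chrom: str = "chr1"
    chrom_len: int = 2_000_000
    gene_len_range: tuple[int, int] = (2000, 10_000)
    gap_range: tuple[int, int] = (1000, 8000)
    promoter_len: int = 1000
    n_sets: int = 10
    set_size: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 50:
            raise ValueError("n_genes must be >= 50")


def simulate_annotation(
    config: AnnotationSimConfig,
    enriched_regions: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Non-overlapping gene bodies with upstream promoters, plus a gene-set
    collection.  If ``enriched_regions`` (e.g. planted DMRs) is given, one
    set named ``planted_set`` collects the genes overlapping those regions,
    so downstream overrepresentation has a known positive.
    """
    rng = np.random.default_rng(config.seed)
    cursor = int(rng.integers(*config.gap_range)) + config.promoter_len
    rows = []
    for i in range(config.n_genes):
        glen = int(rng.integers(*config.gene_len_range))
        if cursor + glen + config.promoter_len >= config.chrom_len:
            raise ValueError("chromosome too short for requested gene count")
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i + 1:04d}"
        start, end = cursor, cursor + glen
        rows.append((config.chrom, start, end, gid, "gene_body", strand))
        if strand == "+":
            rows.append((config.chrom, start - config.promoter_len, start, gid, "promoter", strand))
        else:
            rows.append((config.chrom, end, end + config.promoter_len, gid, "promoter", strand))
        cursor = end + config.promoter_len + int(rng.integers(*config.gap_range))
    ann = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "feature", "strand"])

    genes = ann.loc[ann["feature"] == "gene_body", "gene_id"].tolist()
    gene_sets: dict[str, set[str]] = {}
    for j in range(config.n_sets):
        pick = rng.choice(len(genes), size=min(config.set_size, len(genes)), replace=False)
        gene_sets[f"random_set_{j + 1:02d}"] = {genes[i] for i in pick}
    if enriched_regions is not None:
        from .enrichment import dmr_gene_overlap

        hit = dmr_gene_overlap(enriched_regions, ann, feature_classes={"gene_body"})
        pool = [g for g in genes if g not in hit]
        pad = max(0, config.set_size - len(hit))
        extra = {pool[i] for i in rng.choice(len(pool), size=min(pad, len(pool)), replace=False)}
        gene_sets["planted_set"] = set(hit) | extra
    return ann, gene_sets


# ---------------------------------------------------------------------------
# Cell panel


@dataclass(frozen=True)
class CellTypeSpec:
    label: str
    n_cells: int
    markers: tuple[str, ...]
    marker_mean: float = 5.0
    background_mean: float = 0.1


def _default_cell_types() -> tuple[CellTypeSpec, ...]:
    def mk(prefix: str, n: int) -> tuple[str, ...]:
        return tuple(f"{prefix}_m{i + 1:02d}" for i in range(n))

    return (
        CellTypeSpec("acinar", 200, mk("acinar", 10)),
        CellTypeSpec("duct", 150, mk("duct", 10)),
        CellTypeSpec("panin", 50, mk("panin", 8)),
        CellTypeSpec("pi3k", 0, mk("pi3k", 8)),
        CellTypeSpec("ap1", 0, mk("ap1", 6)),
    )


@dataclass(frozen=True)
class CellSimConfig:
    panel_size: int = 500
    cell_types: tuple[CellTypeSpec, ...] = field(default_factory=_default_cell_types)
    transition_fraction: float = 0.0
    transition_pair: tuple[str, str] = ("acinar", "duct")
    detection_noise: float = 1.0
    sample_label: str = "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.transition_fraction <= 1.0):
            raise ValueError("transition_fraction must be in [0, 1]")
        all_markers = [m for ct in self.cell_types for m in ct.markers]
        if len(all_markers) != len(set(all_markers)):
            raise ValueError("marker sets must be disjoint")
        if self.panel_size < len(all_markers):
            raise ValueError("panel_size smaller than the union of marker sets")


def simulate_cell_panel(
    config: CellSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, MarkerPanel, TruthSet]:
    """Cell-by-gene Poisson counts over a fixed panel.

    Each cell's own markers are Poisson(marker_mean * detection_noise); all
    other genes Poisson(background_mean * detection_noise).  Transition cells
    (a ``transition_fraction`` of the total, appended with their own type
    label) draw marker-level counts from BOTH programs of
    ``transition_pair``.  Returns (counts, metadata, panel, truth).
    """
    rng = np.random.default_rng(config.seed)
    specs = {ct.label: ct for ct in config.cell_types}
    markers = {ct.label: list(ct.markers) for ct in config.cell_types}
    all_markers = [m for ct in config.cell_types for m in ct.markers]
    n_fill = config.panel_size - len(all_markers)
    fillers = [f"gene{i + 1:04d}" for i in range(n_fill)]
    panel_genes = all_markers + fillers
    panel = MarkerPanel(genes=tuple(panel_genes), marker_sets={k: tuple(v) for k, v in markers.items()})

    n_typed = sum(ct.n_cells for ct in config.cell_types)
    n_trans = int(round(config.transition_fraction * n_typed)) if n_typed else 0
    gene_index = {g: i for i, g in enumerate(panel_genes)}
    rows, meta = [], []
    noise = config.detection_noise

    def make_cell(cell_id: str, marker_groups: list[str], mean_bg: float, mean_mk: float, label: str, transition: bool):
        lam = np.full(len(panel_genes), mean_bg * noise)
        for grp in marker_groups:
            for g in markers[grp]:
                lam[gene_index[g]] = mean_mk * noise
        rows.append(rng.poisson(lam))
        meta.append((cell_id, config.sample_label, label, transition))

    i = 0
    for ct in config.cell_types:
        for _ in range(ct.n_cells):
            i += 1
            make_cell(f"{config.sample_label}_c{i:05d}", [ct.label], ct.background_mean, ct.marker_mean, ct.label, False)
    ta, tb = config.transition_pair
    trans_ids = []
    for _ in range(n_trans):
        i += 1
        cid = f"{config.sample_label}_c{i:05d}"
        mean_mk = (specs[ta].marker_mean + specs[tb].marker_mean) / 2
        mean_bg = (specs[ta].background_mean + specs[tb].background_mean) / 2
        make_cell(cid, [ta, tb], mean_bg, mean_mk, "transition", True)
        trans_ids.append(cid)

    counts = pd.DataFrame(rows, columns=panel_genes, index=[m[0] for m in meta])
    counts.index.name = "cell_id"
    metadata = pd.DataFrame(meta, columns=["cell_id", "sample", "cell_type", "is_transition"])
    return counts, metadata, panel, TruthSet(transition_cell_ids=trans_ids)
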