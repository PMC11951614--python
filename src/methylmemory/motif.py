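"""PWM motif scanning at DMR windows and region-level motif enrichment.

Regions of interest are the DMRs plus 50 bp of flank on each side.  Each PWM
is scanned over both strands with log2-odds scores against a background
base composition; a region "has" the motif if any window reaches the score
threshold (ZOOPS counting).  Enrichment is a one-sided Fisher's exact test
of region-level presence in foreground vs a GC- and length-matched sampled
background, BH-corrected across motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import GenomicInterval, benjamini_hochberg

__all__ = [
    "Pwm",
    "expand_regions",
    "scan_pwm",
    "scan_regions",
    "gc_matched_background",
    "motif_enrichment",
    "load_jaspar",
    "random_pwms",
    "read_fasta",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass
class Pwm:
    """Position weight matrix over A, C, G, T (rows) with probabilities.

    Columns sum to 1; probabilities are pseudocount-regularised on
    construction so log-odds are finite.  ``score_threshold`` defaults to
    80% of the maximum attainable log2-odds score.
    """

    motif_id: str
    matrix: np.ndarray  # 4 x L probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    score_threshold: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("matrix must be 4 x L (A, C, G, T rows)")
        if np.any(self.matrix <= 0):  # regularise zeros
            self.matrix = self.matrix + 1e-3
        self.matrix = self.matrix / self.matrix.sum(axis=0, keepdims=True)
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        self.background = np.asarray(self.background, dtype=float)
        self.background = self.background / self.background.sum()
        if self.score_threshold is None:
            self.score_threshold = 0.8 * self.max_score

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """5 x L log2-odds; the fifth (N) row contributes 0."""
        lo = np.log2(self.matrix / self.background[:, None])
        return np.vstack([lo, np.zeros(self.length)])

    @property
    def max_score(self) -> float:
        return float(np.log2(self.matrix / self.background[:, None]).max(axis=0).sum())

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            motif_id=self.motif_id,
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            score_threshold=self.score_threshold,
        )

    @classmethod
    def from_consensus(cls, consensus: str, motif_id: str | None = None, certainty: float = 0.985) -> "Pwm":
        mat = np.full((4, len(consensus)), (1 - certainty) / 3)
        for j, b in enumerate(consensus):
            mat[_BASE_CODE[b], j] = certainty
        return cls(motif_id=motif_id or consensus, matrix=mat)


def load_jaspar(path, background=None) -> list[Pwm]:
    """Load PWMs from a JASPAR-format file via Bio.motifs."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            counts += 0.5  # pseudocount
            pwm = counts / counts.sum(axis=0, keepdims=True)
            out.append(
                Pwm(
                    motif_id=m.matrix_id or m.name,
                    matrix=pwm,
                    background=background if background is not None else np.full(4, 0.25),
                )
            )
    return out


def random_pwms(n: int, length: int = 8, seed: int = 0, prefix: str = "decoy") -> list[Pwm]:
    """Decoy PWMs built from random consensus strings (for calibration)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out = []
    for i in range(n):
        cons = "".join(bases[rng.integers(0, 4, size=length)])
        out.append(Pwm.from_consensus(cons, motif_id=f"{prefix}{i + 1:02d}_{cons}"))
    return out


# ---------------------------------------------------------------------------
# Regions and sequences


def expand_regions(regions, chrom_sizes: dict[str, int], flank: int = 50) -> list[GenomicInterval]:
    """[start - flank, end + flank) clipped to chromosome bounds."""
    out = []
    for r in regions:
        size = chrom_sizes[r.chrom]
        out.append(
            GenomicInterval(
                r.chrom,
                max(0, r.start - flank),
                min(size, r.end + flank),
                name=getattr(r, "name", "") or "",
            )
        )
    return out


def read_fasta(path):
    """Open an (indexed) FASTA file for region extraction.

    The returned pyfaidx.Fasta behaves like the dict-of-sequences genomes
    the scanning functions accept."""
    from pyfaidx import Fasta

    return Fasta(str(path))


def _get_seq(genome, chrom: str, start: int, end: int) -> str:
    seq = genome[chrom]
    if isinstance(seq, str):
        return seq[start:end].upper()
    return str(seq[start:end]).upper()  # pyfaidx.FastaRecord


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        codes[arr == ord(base)] = code
    return codes


def scan_pwm(sequence: str, pwm: Pwm, threshold: float | None = None) -> pd.DataFrame:
    """All windows on both strands with log2-odds score >= threshold.

    N bases contribute 0 log-odds.  Minus-strand hits are scored on the
    reverse complement and reported at their plus-strand window start.
    Returns columns position (0-based window start), strand, score.
    """
    thr = pwm.score_threshold if threshold is None else threshold
    L = pwm.length
    n = len(sequence)
    if L > n:
        return pd.DataFrame(columns=["position", "strand", "score"])
    codes = _encode(sequence)
    hits = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        lo = mat.log_odds
        score = np.zeros(n - L + 1)
        for j in range(L):
            score += lo[codes[j : n - L + 1 + j], j]
        pos = np.flatnonzero(score >= thr)
        for p in pos:
            hits.append((int(p), strand, float(score[p])))
    df = pd.DataFrame(hits, columns=["position", "strand", "score"])
    return df.sort_values(["position", "strand"]).reset_index(drop=True)


def scan_regions(genome, regions, pwm: Pwm, threshold: float | None = None) -> pd.DataFrame:
    """Scan a PWM over genomic regions; positions are genome coordinates.
    Adds region index and name columns."""
    frames = []
    for i, r in enumerate(regions):
        seq = _get_seq(genome, r.chrom, r.start, r.end)
        h = scan_pwm(seq, pwm, threshold)
        if len(h):
            h = h.assign(
                chrom=r.chrom,
                position=h["position"] + r.start,
                region=i,
                region_name=getattr(r, "name", "") or "",
            )
            frames.append(h)
    if not frames:
        return pd.DataFrame(columns=["position", "strand", "score", "chrom", "region", "region_name"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Background sampling and enrichment


def _gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def gc_matched_background(
    fg_regions,
    genome,
    n_per_fg: int = 2,
    gc_tol: float = 0.05,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> list[GenomicInterval]:
    """For each foreground region, sample ``n_per_fg`` length-matched
    regions uniformly over the genome with GC within ``gc_tol`` of the
    foreground's GC.  After ``max_attempts`` rejections the tolerance is
    doubled (with a warning); a still-unmatchable region raises."""
    rng = np.random.default_rng(seed)
    chroms = list(genome.keys()) if isinstance(genome, dict) else [str(c) for c in genome.keys()]
    sizes = np.array([len(genome[c]) for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    out = []
    for r in fg_regions:
        gc_fg = _gc_fraction(_get_seq(genome, r.chrom, r.start, r.end))
        ln = r.end - r.start
        tol = gc_tol
        got = 0
        attempts = 0
        while got < n_per_fg:
            attempts += 1
            if attempts > max_attempts:
                if tol >= 0.5:
                    raise RuntimeError(
                        f"cannot GC-match region {r.chrom}:{r.start}-{r.end} (GC={gc_fg:.2f})"
                    )
                tol *= 2
                attempts = 0
                warnings.warn(f"relaxing GC tolerance to {tol:.3f} for {r.chrom}:{r.start}-{r.end}")
            ci = int(rng.choice(len(chroms), p=weights))
            chrom = chroms[ci]
            if len(genome[chrom]) < ln:
                continue
            start = int(rng.integers(0, len(genome[chrom]) - ln + 1))
            gc = _gc_fraction(_get_seq(genome, chrom, start, start + ln))
            if np.isfinite(gc) and abs(gc - gc_fg) <= tol:
                out.append(GenomicInterval(chrom, start, start + ln, name=f"bg_{len(out):04d}"))
                got += 1
    return out


def motif_enrichment(
    fg_regions,
    bg_regions,
    pwms: list[Pwm],
    genome,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Region-level (ZOOPS) presence of each motif in foreground vs
    background; one-sided Fisher's exact per motif, BH across motifs.

    Motifs longer than every region are reported untestable (p = NaN).
    """
    if not len(fg_regions) or not len(bg_regions):
        raise ValueError("foreground and background must be nonempty")

    def presence(regions, pwm) -> int:
        n_with = 0
        for r in regions:
            seq = _get_seq(genome, r.chrom, r.start, r.end)
            if len(scan_pwm(seq, pwm, threshold)):
                n_with += 1
        return n_with

    max_len = max(max(r.end - r.start for r in fg_regions), max(r.end - r.start for r in bg_regions))
    rows = []
    for pwm in pwms:
        if pwm.length > max_len:
            rows.append((pwm.motif_id, 0, len(fg_regions), 0, len(bg_regions), np.nan, False))
            continue
        fg_with = presence(fg_regions, pwm)
        bg_with = presence(bg_regions, pwm)
        table = [
            [fg_with, len(fg_regions) - fg_with],
            [bg_with, len(bg_regions) - bg_with],
        ]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
        rows.append((pwm.motif_id, fg_with, len(fg_regions), bg_with, len(bg_regions), p, True))
    df = pd.DataFrame(
        rows, columns=["motif_id", "fg_with", "fg_total", "bg_with", "bg_total", "p", "testable"]
    )
    df["p_adj"] = np.nan
    mask = df["testable"].to_numpy()
    if mask.any():
        df.loc[mask, "p_adj"] = benjamini_hochberg(df.loc[mask, "p"].to_numpy())
    return df.sort_values("p", na_position="last").reset_index(drop=True)
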