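"""Unit tests for CpG-report handling, smoothing, t-statistics and the DMR
filter chain."""

import numpy as np
import pandas as pd
import pytest

from methylmemory.methylome import (
    CpgReportParseError,
    SmoothParams,
    TStatParams,
    call_dmrs,
    dmr_pipeline,
    filter_sites,
    group_tstat,
    pca_methylomes,
    read_cpg_report,
    recheck_dmr,
    refine_dmrs,
    smooth_sample,
    tstat_core,
    write_cpg_report,
)

from conftest import make_sample


# ---------------------------------------------------------------------------
# CpG report I/O


class TestReadCpgReport:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("chr1\t100\t+\t3\t1\tCG\tCGA\n")
        s = read_cpg_report(p)
        row = s.data.iloc[0]
        assert (row.chrom, row.pos, row.m, row.u) == ("chr1", 100, 3, 1)

    def test_strand_collapse(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("chr1\t100\t+\t2\t0\nchr1\t101\t-\t1\t4\n")
        s = read_cpg_report(p)
        assert len(s.data) == 1
        row = s.data.iloc[0]
        assert (row.pos, row.m, row.u) == (100, 3, 4)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        assert len(read_cpg_report(p).data) == 0

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("chr1\t100\t+\t3\t1\nchr1\tnope\t+\t1\t1\n")
        with pytest.raises(CpgReportParseError, match=":2:"):
            read_cpg_report(p)

    def test_round_trip(self, tmp_path):
        s = make_sample("chr1", [10, 50, 90], [1, 2, 3], [4, 5, 6])
        p = tmp_path / "out.txt"
        write_cpg_report(s, p)
        back = read_cpg_report(p)
        pd.testing.assert_frame_equal(back.data, s.data)


# ---------------------------------------------------------------------------
# Coverage / autosome filter


class TestFilterSites:
    def _four(self, covs, chrom="chr1"):
        return [
            make_sample(chrom, [100], [c], [0], sample_id=f"r{i}") for i, c in enumerate(covs)
        ]

    def test_boundary_pass_at_min(self):
        kept = filter_sites(self._four([2, 3, 2, 2]), min_cov=2)
        assert len(kept) == 1

    def test_per_replicate_rule_not_mean(self):
        # one replicate at 1X sinks the site even though the mean is high
        with pytest.raises(ValueError):
            filter_sites(self._four([1, 9, 9, 9]), min_cov=2)

    def test_chrx_dropped(self):
        with pytest.raises(ValueError):
            filter_sites(self._four([5, 5, 5, 5], chrom="chrX"), min_cov=2)

    def test_missing_site_counts_as_zero_coverage(self):
        a = make_sample("chr1", [100, 200], [5, 5], [0, 0], sample_id="a")
        b = make_sample("chr1", [100], [5], [0], sample_id="b")
        kept = filter_sites([a, b], min_cov=2)
        assert kept["pos"].tolist() == [100]


# ---------------------------------------------------------------------------
# Smoothing


class TestSmoothing:
    def test_constant_preserved(self):
        pos = np.arange(100, 5100, 50)
        s = make_sample("chr1", pos, np.full(len(pos), 7), np.full(len(pos), 3))
        sm = smooth_sample(s, SmoothParams(10, 200))
        assert np.allclose(sm["smoothed"], 0.7, atol=1e-9)

    def test_linear_signal_reproduced_exactly(self):
        # a degree-2 local fit reproduces a degree-1 signal under uniform coverage
        pos = np.arange(0, 200) * 37 + 1
        m = 200 + 3 * np.arange(200)  # exactly linear in position, integer counts
        s = make_sample("chr1", pos, m, 1000 - m)
        sm = smooth_sample(s, SmoothParams(30, 500))
        raw = m / 1000.0
        assert np.allclose(sm["smoothed"], raw, atol=1e-6)

    def test_isolated_outlier_shrunk_toward_neighbours(self):
        pos = np.arange(100, 3100, 100)
        m = np.full(len(pos), 9)
        u = np.full(len(pos), 1)
        mid = len(pos) // 2
        m[mid], u[mid] = 0, 10
        s = make_sample("chr1", pos, m, u)
        sm = smooth_sample(s, SmoothParams(15, 500))
        assert sm["smoothed"][mid] > 0.5

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(10_000, 120, replace=False)) + 1
        m = rng.integers(0, 10, 120)
        u = 10 - m
        a = smooth_sample(make_sample("chr1", pos, m, u), SmoothParams(20, 300))
        b = smooth_sample(make_sample("chr1", pos + 5000, m, u), SmoothParams(20, 300))
        assert np.allclose(a["smoothed"], b["smoothed"])

    def test_tiny_chromosome_flagged_raw(self):
        s = make_sample("chr1", [100, 200], [4, 1], [1, 4])
        sm = smooth_sample(s)
        assert sm["flagged"].all()
        assert np.allclose(sm["smoothed"], [0.8, 0.2])


# ---------------------------------------------------------------------------
# t-statistics


class TestGroupTstat:
    def test_arithmetic_oracle(self):
        # smoothed means A=(0.8,0.8), B=(0.4,0.4), pooled floored sd 0.1, n=2 each
        t = tstat_core(np.array([0.8, 0.8]), np.array([0.4, 0.4]), np.array([0.1, 0.1]), 2, 2)
        assert np.allclose(t, 4.0)

    def _groups(self, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        pos = np.arange(100, 20100, 100)
        out = []
        for grp, base in (("A", 0.5 + shift), ("B", 0.5)):
            for r in range(2):
                m = rng.binomial(20, base, len(pos))
                out.append(
                    make_sample("chr1", pos, m, 20 - m, sample_id=f"{grp}{r}", group=grp)
                )
        return out[:2], out[2:]

    def test_identical_groups_give_zero_t_raw(self):
        a, _ = self._groups()
        track = group_tstat(a, a, TStatParams(local_correct=False))
        assert np.allclose(track["t_raw"], 0.0)

    def test_group_swap_negates_t(self):
        a, b = self._groups(seed=3, shift=0.1)
        t1 = group_tstat(a, b)
        t2 = group_tstat(b, a)
        assert np.allclose(t1["t_corrected"], -t2["t_corrected"])
        assert np.allclose(t1["t_raw"], -t2["t_raw"])

    def test_single_replicate_group_rejected(self):
        a, b = self._groups()
        with pytest.raises(ValueError, match="group B"):
            group_tstat(a, b[:1])


# ---------------------------------------------------------------------------
# DMR calling and refinement


def _track(t, pos=None, diff=None, chrom="chr1"):
    n = len(t)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(pos if pos is not None else np.arange(1, n + 1) * 50),
            "mean_a": 0.5,
            "mean_b": 0.5,
            "diff": np.asarray(diff if diff is not None else np.sign(t) * 0.2),
            "sd_pool": 0.1,
            "t_raw": np.asarray(t, dtype=float),
            "t_corrected": np.asarray(t, dtype=float),
        }
    )


class TestCallDmrs:
    def test_candidate_fraction_matches_quantiles(self, rng):
        track = _track(rng.normal(size=20_000))
        cands = call_dmrs(track, TStatParams())
        frac = sum(c.n_cpg for c in cands) / len(track)
        assert abs(frac - 0.10) < 0.005  # empirical-quantile construction

    def test_runs_are_maximal_and_sign_pure(self):
        t = np.zeros(20)
        t[5:12] = 10.0
        t[8] = -10.0  # interruption with the opposite sign
        track = _track(t)
        cands = call_dmrs(track, TStatParams(qlow=0.05, qhigh=0.6))
        spans = sorted((c.n_cpg, c.direction) for c in cands)
        # the positive run is split in two by the negative CpG
        assert (1, "hypo") in [(c.n_cpg, c.direction) for c in cands]
        assert sum(1 for c in cands if c.direction == "hyper") == 2
        assert all(len(set(np.sign(c.tstats))) == 1 for c in cands)
        del spans


class TestRefineDmrs:
    def test_split_then_filter_rule(self):
        # pad with null CpGs far away so the quantile cutoff falls below the run
        t = [5.0] * 5 + [0.0] * 15
        pos = [100, 150, 200, 600, 650] + list(100_000 + np.arange(15) * 100)
        track = _track(t, pos=pos, diff=[0.3] * 5 + [0.0] * 15)
        cands = call_dmrs(track, TStatParams(qlow=0.05, qhigh=0.5))
        assert len(cands) == 1
        out = refine_dmrs(cands, min_cpg=5, min_diff=0.10, max_gap=300)
        assert out == []  # 3-CpG and 2-CpG fragments both fail min_cpg
        out2 = refine_dmrs(cands, min_cpg=2, min_diff=0.10, max_gap=300)
        assert [(d.start, d.end) for d in out2] == [(99, 200), (599, 650)]

    @pytest.mark.parametrize("diff,kept", [(0.10, True), (0.09, False)])
    def test_mean_diff_boundary_inclusive(self, diff, kept):
        t = [5.0] * 6 + [0.0] * 14
        pos = list(np.arange(6) * 100 + 100) + list(100_000 + np.arange(14) * 100)
        track = _track(t, pos=pos, diff=[diff] * 6 + [0.0] * 14)
        cands = call_dmrs(track, TStatParams(qlow=0.05, qhigh=0.5))
        out = refine_dmrs(cands)
        assert (len(out) == 1) is kept

    def test_emitted_dmrs_pass_brute_force_recheck(self, small_methylome):
        _, samples, _ = small_methylome
        ga = [s for s in samples if s.group == "acinar"]
        gb = [s for s in samples if s.group == "adm"]
        dmrs, _ = dmr_pipeline(gb, ga)
        assert len(dmrs) > 0
        assert all(recheck_dmr(d) for d in dmrs)


# ---------------------------------------------------------------------------
# PCA


class TestPca:
    def test_geometry_and_variance_fractions(self):
        pos = np.arange(100, 10100, 100)
        lo = make_sample("chr1", pos, np.full(len(pos), 2), np.full(len(pos), 8), "lo1")
        lo2 = make_sample("chr1", pos, np.full(len(pos), 2), np.full(len(pos), 8), "lo2")
        rng = np.random.default_rng(1)
        m = rng.binomial(10, 0.8, len(pos))
        hi = make_sample("chr1", pos, m, 10 - m, "hi")
        coords, evr = pca_methylomes([lo, lo2, hi])
        assert np.allclose(coords.loc["lo1"], coords.loc["lo2"], atol=1e-8)
        assert abs(coords.loc["hi", "PC1"] - coords.loc["lo1", "PC1"]) > 1.0
        assert np.isclose(evr.sum(), 1.0)

    def test_requires_three_samples(self):
        pos = [100, 200, 300]
        s = make_sample("chr1", pos, [1, 2, 3], [3, 2, 1])
        with pytest.raises(ValueError):
            pca_methylomes([s, s])

    def test_recovered_group_is_intermediate(self, small_methylome):
        # emulates the observed intermediate PCA position of recovered samples
        _, samples, _ = small_methylome
        coords, _ = pca_methylomes(samples)
        cent = {
            g: coords.loc[[s.sample_id for s in samples if s.group == g]].mean(axis=0)
            for g in ("acinar", "adm", "recovered")
        }
        axis = cent["adm"] - cent["acinar"]
        axis = axis / np.linalg.norm(axis)
        proj = {g: float(np.dot(cent[g] - cent["acinar"], axis)) for g in cent}
        assert proj["acinar"] < proj["recovered"] < proj["adm"]
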