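import itertools

import numpy as np
import pytest

from polterm.coverage import CoverageTrack, RegionCoverage, extract_region
from polterm.metagene import (
    FLANK,
    MetageneProfile,
    N_BINS,
    average_group,
    band_for,
    bonferroni,
    build_bins,
    per_bin_tests,
    profile_transcript,
    ratio_profile,
    ratio_profiles,
    signed_rank_pvalue,
)

from conftest import make_transcript


def _rc(values, strand="+"):
    return RegionCoverage(values=np.asarray(values, float), chrom="chr1",
                          start=0, strand=strand, sample_id="s")


class TestBuildBins:
    def test_minimum_length_gives_1bp_body_bins(self):
        scheme = build_bins(make_transcript(3_180))
        assert np.all(scheme.widths[90:270] == 1)
        assert np.all(scheme.widths[:90] == 50)
        assert np.all(scheme.widths[270:] == 50)

    def test_divisible_body_gives_equal_bins(self):
        scheme = build_bins(make_transcript(21_000))
        assert np.all(scheme.widths[90:270] == 100)

    def test_indivisible_body_rounds_and_sums_exactly(self):
        scheme = build_bins(make_transcript(18_001))
        body = scheme.widths[90:270]
        assert set(body) == {83, 84}
        assert body.sum() == 15_001

    def test_short_transcript_rejected(self):
        with pytest.raises(ValueError):
            build_bins(make_transcript(3_179))

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_partition_covers_every_base_exactly_once(self, strand, rng):
        for _ in range(25):
            length = int(rng.integers(3_180, 40_000))
            start = int(rng.integers(4_000, 10_000))
            t = make_transcript(length, strand=strand, start=start)
            scheme = build_bins(t)
            ivs = scheme.genomic_intervals()
            assert len(ivs) == N_BINS
            covered = sorted(ivs)
            assert covered[0][0] == start - FLANK
            assert covered[-1][1] == start + length + FLANK
            for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
                assert e1 == s2  # no gap, no overlap


class TestProfileTranscript:
    def test_uniform_coverage_gives_flat_profile(self):
        t = make_transcript(9_000)
        scheme = build_bins(t)
        prof = profile_transcript(_rc(np.full(15_000, 5.0)), scheme)
        assert np.allclose(prof.values, 1.0 / N_BINS)

    def test_zero_coverage_flagged_excluded(self):
        t = make_transcript(9_000)
        prof = profile_transcript(_rc(np.zeros(15_000)), build_bins(t))
        assert prof.excluded and prof.values is None

    def test_matches_per_bin_mean_oracle(self, rng):
        t = make_transcript(7_777)
        scheme = build_bins(t)
        vals = rng.poisson(2.0, 7_777 + 2 * FLANK).astype(float)
        prof = profile_transcript(_rc(vals), scheme)
        oracle = np.array(
            [vals[int(a) : int(b)].mean() for a, b in zip(scheme.edges[:-1], scheme.edges[1:])]
        )
        oracle /= oracle.sum()
        assert np.allclose(prof.values, oracle)
        assert prof.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_errors(self):
        t = make_transcript(9_000)
        with pytest.raises(ValueError, match="length"):
            profile_transcript(_rc(np.ones(100)), build_bins(t))

    def test_strand_symmetry_against_mirrored_twin(self, rng):
        # a '-' transcript profiles identically to its mirrored '+' twin
        n = 30_000
        arr = rng.poisson(3.0, n).astype(float)
        track = CoverageTrack(sample_id="s", library_size=100,
                              chrom_lengths={"chr1": n}, fwd={"chr1": arr})
        mirror = CoverageTrack(sample_id="s", library_size=100,
                               chrom_lengths={"chr1": n}, fwd={"chr1": arr[::-1].copy()})
        t_plus = make_transcript(8_000, strand="+", start=11_000)
        t_minus = make_transcript(8_000, strand="-", start=n - 19_000)
        rc_p = extract_region(track, "chr1", 11_000 - FLANK, 19_000 + FLANK, "+")
        rc_m = extract_region(mirror, "chr1", 11_000 - FLANK, 19_000 + FLANK, "-")
        p_plus = profile_transcript(rc_p, build_bins(t_plus))
        p_minus = profile_transcript(rc_m, build_bins(t_minus))
        assert np.allclose(p_plus.values, p_minus.values)


class TestAverageGroup:
    def _profiles(self, mat, sample="s1"):
        return [
            MetageneProfile(f"t{i}", sample, row) for i, row in enumerate(mat)
        ]

    def test_idempotent_on_identical_profiles(self, rng):
        v = rng.dirichlet(np.ones(N_BINS))
        out = average_group({"s1": [MetageneProfile("t1", "s1", v),
                                    MetageneProfile("t2", "s1", v)]})
        assert np.allclose(out, v)

    def test_exclusion_affects_only_that_sample(self):
        a = np.full(N_BINS, 1.0 / N_BINS)
        b = np.zeros(N_BINS); b[0] = 1.0
        out = average_group({
            "s1": [MetageneProfile("t1", "s1", a), MetageneProfile("t2", "s1", b)],
            "s2": [MetageneProfile("t1", "s2", a),
                   MetageneProfile("t2", "s2", None, excluded=True)],
        })
        expected = ((a + b) / 2 + a) / 2
        assert np.allclose(out, expected)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_stage_mean_differs_from_pooled_on_unequal_sets(self, rng):
        mats = {s: rng.dirichlet(np.ones(N_BINS), 20) for s in ("s1", "s2", "s3")}
        profs = {s: self._profiles(m, s) for s, m in mats.items()}
        # drop some transcripts from s3 only
        for p in profs["s3"][:7]:
            p.values, p.excluded = None, True
        out = average_group(profs)
        oracle = np.mean(
            [mats["s1"].mean(axis=0), mats["s2"].mean(axis=0), mats["s3"][7:].mean(axis=0)],
            axis=0,
        )
        pooled = np.vstack([mats["s1"], mats["s2"], mats["s3"][7:]]).mean(axis=0)
        assert np.allclose(out, oracle)
        assert not np.allclose(out, pooled)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            average_group({"s1": [MetageneProfile("t", "s1", None, excluded=True)]})


def _enumerated_signed_rank_p(d):
    """Exhaustive two-sided signed-rank p over all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = scipy_rankdata(np.abs(d))
    n = len(d)
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(1.0, p)


from scipy.stats import rankdata as scipy_rankdata  # noqa: E402


class TestPerBinTests:
    def test_identical_conditions_give_p_one(self, rng):
        mat = rng.dirichlet(np.ones(10), 8)
        curve = per_bin_tests(mat, mat.copy(), n_bins_tested=10)
        assert np.all(curve.raw_p == 1.0)
        assert all(b == "none" for b in curve.bands)

    def test_eight_positive_pairs_exact_p(self, rng):
        # all 8 differences positive in bin 0: two-sided exact p = 2/2^8
        ctrl = rng.random((8, 3)) + 1.0
        trt = ctrl.copy()
        trt[:, 0] = ctrl[:, 0] - rng.random(8) * 0.5 - 0.01
        curve = per_bin_tests(ctrl, trt, n_bins_tested=3)
        assert curve.raw_p[0] == pytest.approx(2 / 2**8)

    def test_bonferroni_arithmetic_and_band(self):
        assert bonferroni(1e-5, 360) == pytest.approx(3.6e-3)
        assert band_for(3.6e-3) == "none"
        assert band_for(1e-3) == "yellow"
        assert band_for(1e-10) == "orange"
        assert band_for(1e-16) == "red"

    def test_exact_p_matches_enumeration(self, rng):
        for n in (6, 8, 10, 12):
            for _ in range(3):
                x = rng.normal(0, 1, n)
                y = x + rng.normal(0.4, 1, n)
                assert signed_rank_pvalue(x, y) == pytest.approx(
                    _enumerated_signed_rank_p(x - y), rel=1e-12
                )

    def test_too_few_pairs_errors(self, rng):
        mat = rng.random((4, 5))
        with pytest.raises(ValueError, match="6"):
            per_bin_tests(mat, mat + 1)


class TestRatioProfile:
    def test_equal_curves_give_unity(self, rng):
        v = rng.dirichlet(np.ones(N_BINS))
        assert np.allclose(ratio_profile(v, v), 1.0)

    def test_doubled_mark_gives_two(self):
        v = np.full(N_BINS, 1.0 / N_BINS)
        assert np.allclose(ratio_profile(2 * v, v), 2.0, atol=1e-3)

    def test_mismatched_bins_error(self):
        with pytest.raises(ValueError):
            ratio_profile(np.ones(10), np.ones(12))

    def test_per_transcript_ratios_shape(self, rng):
        m = rng.random((5, N_BINS)) + 0.5
        r = ratio_profiles(2 * m, m)
        assert r.shape == m.shape
        assert np.allclose(r, 2.0, atol=1e-3)
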