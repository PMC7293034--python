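import numpy as np
import pandas as pd
import pytest
import scipy.stats

from unwrapseq import (
    CANONICAL_LONGMN,
    H2AZ_LONGMN,
    LandscapeSpec,
    UnwrapStateSpec,
    compute_flp,
    sample_fragment,
    simulate_cbs_landscape,
    simulate_histone_sample,
    simulate_knockdown,
    simulate_tss_landscape,
)
from unwrapseq.groups import FragmentGroupScheme
from unwrapseq.simulate import GROUP_STATES, _draw_lengths


def _fixed_length_state(length, placement):
    # tiny sd makes the drawn length deterministic after rounding
    return UnwrapStateSpec("test", length, 1e-9, placement, 1.0)


class TestSampleFragment:
    def test_symmetric_center_is_dyad(self):
        rng = np.random.default_rng(0)
        f = sample_fragment(1000, _fixed_length_state(147, "symmetric"), rng)
        assert f.center == 1000
        assert f.length == 147

    def test_left_retained_span_and_center(self):
        rng = np.random.default_rng(0)
        f = sample_fragment(1000, _fixed_length_state(60, "left_retained"), rng)
        assert (f.start, f.end) == (927, 987)
        assert f.center == 957  # 43 bp left of the dyad

    def test_right_retained_mirror(self):
        rng = np.random.default_rng(0)
        f = sample_fragment(1000, _fixed_length_state(60, "right_retained"), rng)
        assert (f.start, f.end) == (1013, 1073)
        assert f.center == 1043

    def test_left_right_centers_are_mirror_symmetric(self):
        rng = np.random.default_rng(1)
        for L in (40, 60, 75):
            fl = sample_fragment(2000, _fixed_length_state(L, "left_retained"), rng)
            fr = sample_fragment(2000, _fixed_length_state(L, "right_retained"), rng)
            # spans mirror about the dyad
            assert fl.start - 2000 == -(fr.end - 2000)
            assert fl.end - 2000 == -(fr.start - 2000)

    def test_too_small_dyad_rejected(self):
        with pytest.raises(ValueError):
            sample_fragment(50, _fixed_length_state(60, "symmetric"),
                            np.random.default_rng(0))

    def test_placement_symmetry_sign_test(self):
        """Equal left/right weights give (center - dyad) symmetric about 0."""
        rng = np.random.default_rng(2)
        n = 10_000
        lengths = _draw_lengths(rng, 55, 5, n)
        right = rng.random(n) < 0.5
        centers = np.where(
            right,
            2000 + 73 - np.ceil(lengths / 2).astype(int),
            2000 - 73 + lengths // 2,
        )
        offsets = centers - 2000
        n_pos = int((offsets > 0).sum())
        n_neg = int((offsets < 0).sum())
        p = scipy.stats.binomtest(n_pos, n_pos + n_neg, 0.5).pvalue
        assert p > 0.01


def analytic_group_probs(mixture, scheme):
    """Oracle: P(group) under the rounded-normal mixture (continuity corrected)."""
    probs = np.zeros(len(scheme.bounds))
    for state in mixture:
        for j, (_, lo, hi) in enumerate(scheme.bounds):
            p = scipy.stats.norm.cdf(hi + 0.5, state.length_mode, state.length_sd) - \
                scipy.stats.norm.cdf(lo - 0.5, state.length_mode, state.length_sd)
            probs[j] += state.weight * p
    return probs


class TestSimulateHistoneSample:
    def test_canonical_flp_argmax_at_heaviest_mode(self):
        frags = simulate_histone_sample(CANONICAL_LONGMN, 200_000, seed=1)
        p = compute_flp(frags)
        assert abs(int(np.argmax(p.counts)) - 147) <= 1

    def test_h2az_majority_small_fragments(self):
        frags = simulate_histone_sample(H2AZ_LONGMN, 100_000, seed=2)
        lengths = frags.length
        assert np.mean((lengths >= 30) & (lengths <= 80)) > 0.5

    def test_determinism_under_fixed_seed(self):
        a = simulate_histone_sample(CANONICAL_LONGMN, 500, seed=3)
        b = simulate_histone_sample(CANONICAL_LONGMN, 500, seed=3)
        np.testing.assert_array_equal(a.start, b.start)
        np.testing.assert_array_equal(a.end, b.end)

    def test_single_fragment_reproducible(self):
        a = simulate_histone_sample(CANONICAL_LONGMN, 1, seed=4)
        b = simulate_histone_sample(CANONICAL_LONGMN, 1, seed=4)
        assert (a.start[0], a.end[0]) == (b.start[0], b.end[0])

    def test_invalid_mixture_rejected(self):
        bad = (UnwrapStateSpec("a", 100, 3, "symmetric", 0.5),)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_histone_sample(bad, 10, seed=0)
        with pytest.raises(ValueError):
            simulate_histone_sample(CANONICAL_LONGMN, 0, seed=0)

    def test_group_fractions_match_analytic_mixture_within_3se(self):
        n = 100_000
        frags = simulate_histone_sample(CANONICAL_LONGMN, n, seed=5)
        scheme = FragmentGroupScheme.default()
        codes = scheme.assign_codes(frags.length)
        expected = analytic_group_probs(CANONICAL_LONGMN, scheme)
        for j, p in enumerate(expected):
            observed = np.mean(codes == j)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(observed - p) <= 3 * se, (scheme.labels[j], observed, p)


class TestTssLandscape:
    def test_planted_cluster_overweights_its_group(self):
        land = simulate_tss_landscape(LandscapeSpec(n_refpoints=50, seed=6))
        truth = land.truth
        for letter, col in zip("ABCDE", [f"w_{s.name}" for s in GROUP_STATES]):
            sub = truth[truth["cluster"] == letter]
            # the planted group's weight is the argmax of the class-mean mixture
            means = sub[[f"w_{s.name}" for s in GROUP_STATES]].mean()
            assert means.idxmax() == col

    def test_minus_strand_plus1_upstream_in_coordinates(self):
        land = simulate_tss_landscape(LandscapeSpec(n_refpoints=40, seed=7))
        truth = land.truth
        minus = truth[truth["strand"] == "-"]
        plus = truth[truth["strand"] == "+"]
        assert (minus["plus1_dyad"] < minus["tss"]).all()
        assert (plus["plus1_dyad"] > plus["tss"]).all()
        offs = (truth["plus1_dyad"] - truth["tss"]).abs()
        assert offs.between(50, 200).all()

    def test_ndr_devoid_of_fragment_centers(self):
        land = simulate_tss_landscape(
            LandscapeSpec(n_refpoints=40, seed=8, dyad_jitter_sd=0.0)
        )
        centers = land.fragments.center
        for t in land.tss:
            sign = 1 if t.strand == "+" else -1
            # upstream 300 bp window should hold no fragment centers at all
            lo, hi = (t.pos - 300, t.pos - 40) if sign == 1 else (t.pos + 40, t.pos + 300)
            assert np.sum((centers >= lo) & (centers <= hi)) == 0

    def test_byte_identical_outputs_under_fixed_seed(self, tmp_path):
        spec = LandscapeSpec(n_refpoints=20, seed=9)
        p1 = simulate_tss_landscape(spec).write(tmp_path / "a")
        p2 = simulate_tss_landscape(spec).write(tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_too_few_refpoints_rejected(self):
        with pytest.raises(ValueError):
            simulate_tss_landscape(LandscapeSpec(n_refpoints=5, seed=0))


class TestKnockdown:
    def test_zero_shift_reproduces_wild_type(self):
        wt, kd = simulate_knockdown(LandscapeSpec(n_refpoints=20, seed=10), shift=0.0)
        np.testing.assert_array_equal(wt.fragments.start, kd.fragments.start)
        np.testing.assert_array_equal(wt.fragments.end, kd.fragments.end)

    def test_shift_increases_large_fragment_fraction_by_planted_mass(self):
        shift = 0.2
        wt, kd = simulate_knockdown(LandscapeSpec(n_refpoints=200, seed=11), shift=shift)

        def frac_large(land):
            L = land.fragments.length
            sel = (L >= 30) & (L <= 168)
            return np.mean(L[sel] >= 120)

        observed = frac_large(kd) - frac_large(wt)
        n = len(kd.fragments)
        # transferred mass +/- 3 binomial SE (boundary leakage is < 1 SE here)
        se = np.sqrt(0.5 / n)
        assert abs(observed - shift) <= 3 * se + 0.01

    def test_reference_points_identical_across_conditions(self):
        wt, kd = simulate_knockdown(LandscapeSpec(n_refpoints=30, seed=12), shift=0.3)
        assert [(p.pos, p.strand) for p in wt.tss] == [(p.pos, p.strand) for p in kd.tss]
        pd.testing.assert_frame_equal(
            wt.truth.drop(columns=[c for c in wt.truth if c.startswith("w_")]),
            kd.truth.drop(columns=[c for c in kd.truth if c.startswith("w_")]),
        )

    def test_invalid_shift_rejected(self):
        with pytest.raises(ValueError):
            simulate_knockdown(LandscapeSpec(n_refpoints=20, seed=13), shift=0.99)


class TestCbsLandscape:
    def test_no_footprint_leaves_cbs_center_empty(self):
        land = simulate_cbs_landscape(
            LandscapeSpec(n_refpoints=30, seed=14, footprint_weight=0.0,
                          dyad_jitter_sd=0.0)
        )
        centers = land.fragments.center
        lengths = land.fragments.length
        small = (lengths >= 30) & (lengths <= 55)
        for p in land.cbs:
            near = (np.abs(centers - p.pos) <= 20) & small
            assert near.sum() == 0

    def test_footprint_fragments_concentrate_at_center(self):
        land = simulate_cbs_landscape(
            LandscapeSpec(n_refpoints=30, seed=15, footprint_weight=0.2)
        )
        centers = land.fragments.center
        lengths = land.fragments.length
        small = (lengths >= 30) & (lengths <= 55)
        near_any = np.zeros(len(centers), dtype=bool)
        for p in land.cbs:
            near_any |= np.abs(centers - p.pos) <= 15
        assert (near_any & small).sum() >= 30 * 0.2 * 300 * 0.5

    def test_truth_lists_flanking_dyads(self):
        spec = LandscapeSpec(n_refpoints=15, seed=16)
        land = simulate_cbs_landscape(spec)
        t = land.truth
        np.testing.assert_array_equal(
            t["left_flank_dyad"], t["center"] - spec.ndr_halfwidth
        )
        np.testing.assert_array_equal(
            t["right_flank_dyad"], t["center"] + spec.ndr_halfwidth
        )

    def test_embedded_motif_present_at_each_center(self):
        from unwrapseq.motif import scan_consensus

        land = simulate_cbs_landscape(LandscapeSpec(n_refpoints=15, seed=17))
        seq = land.sequence[land.spec.chrom]
        for p in land.cbs:
            hits = scan_consensus(seq[p.pos - 10 : p.pos + 10], offset=p.pos - 10)
            assert any(h.center == p.pos and h.strand == p.strand for h in hits)
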