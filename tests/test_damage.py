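"""Fragmentation, overhangs and context-dependent deamination."""

import numpy as np
import pytest

from paleombd import (
    DamageParams,
    Fragment,
    SizeModel,
    apply_overhangs,
    damage_fragments,
    deaminate,
    draw_fragments,
    expected_ct_profile,
)
from paleombd.damage import assign_methylation, observed_sequence
from paleombd.genome import MethylomeTrack, ReferenceSet


def flat_methylome():
    return MethylomeTrack({})


class TestExpectedProfile:
    def test_direct_evaluation(self):
        p = DamageParams(delta_s=0.5, delta_d=0.02, lambda_ov=0.5)
        assert expected_ct_profile(p, 1) == pytest.approx(0.5 * 0.5 + 0.02 * 0.5)

    def test_lambda_one_gives_double_strand_rate_everywhere(self):
        p = DamageParams(delta_s=0.4, delta_d=0.01, lambda_ov=1.0)
        for d in (1, 5, 25):
            assert expected_ct_profile(p, d) == pytest.approx(0.01)

    def test_equal_deltas_flatten_profile(self):
        p = DamageParams(delta_s=0.07, delta_d=0.07, lambda_ov=0.3)
        assert {round(expected_ct_profile(p, d), 12) for d in range(1, 26)} == {0.07}

    def test_methylated_scales_by_rho_and_clips(self):
        p = DamageParams(delta_s=0.4, delta_d=0.01, lambda_ov=0.5, rho_meth=4.0)
        assert expected_ct_profile(p, 1, methylated=True) == pytest.approx(
            min(1.0, 4 * expected_ct_profile(p, 1))
        )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            expected_ct_profile(DamageParams(), 0)

    def test_monotone_when_ds_exceeds_dd(self):
        p = DamageParams(delta_s=0.3, delta_d=0.01, lambda_ov=0.4)
        vals = [expected_ct_profile(p, d) for d in range(1, 26)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestOverhangs:
    def test_lambda_one_never_overhangs(self, rng):
        f = Fragment("x", 0, 50, "unique_nuclear")
        for _ in range(50):
            apply_overhangs(f, 1.0, rng)
            assert f.overhang5 == 0 and f.overhang3 == 0

    def test_geometric_mean_matches_closed_form(self, rng):
        # mean of Geometric(lambda) on {0,1,...} is (1-lambda)/lambda = 1 at 0.5
        draws = rng.geometric(0.5, 100_000) - 1
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 1.0) < 3 * se

    def test_paper_range_of_mean_overhangs(self):
        # lambda in [0.26, 0.53] brackets mean overhangs of 0.9-2.8 bp
        for lam, mean in ((1 / (1 + 0.9), 0.9), (1 / (1 + 2.8), 2.8)):
            assert (1 - lam) / lam == pytest.approx(mean)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            apply_overhangs(Fragment("x", 0, 10, "mito"), 0.0)


class TestDrawFragments:
    def test_zero_is_empty(self, toy_ref, default_damage):
        assert draw_fragments(toy_ref, 0, default_damage, seed=1) == []

    def test_all_endogenous_when_fraction_one(self, toy_ref, default_damage):
        frags = draw_fragments(toy_ref, 300, default_damage, endogenous_fraction=1.0, seed=1)
        assert all(f.origin_class != "microbial" for f in frags)

    def test_lognormal_median_recovered(self, toy_ref):
        params = DamageParams(size_model=SizeModel.lognormal(100), min_length=2)
        frags = draw_fragments(toy_ref, 20_000, params, seed=3)
        lengths = np.array([f.length for f in frags])
        # Monte-Carlo tolerance on the median of a lognormal
        assert abs(np.median(lengths) - 100) <= 3

    def test_repetitive_iff_midpoint_in_te(self, toy_ref, default_damage):
        frags = draw_fragments(toy_ref, 2_000, default_damage, seed=4)
        for f in frags:
            if f.contig != "chr1":
                assert f.origin_class in ("mito", "microbial")
                continue
            mid = (f.start + f.end) // 2
            in_te = any(s <= mid < e for _, s, e, _fam in toy_ref.te_intervals)
            assert (f.origin_class == "repetitive") == in_te

    def test_endogenous_share_close_to_target(self, toy_ref, default_damage):
        frags = draw_fragments(toy_ref, 20_000, default_damage, endogenous_fraction=0.35, seed=5)
        share = np.mean([f.origin_class != "microbial" for f in frags])
        assert abs(share - 0.35) < 0.02


class TestDeaminate:
    def test_requires_overhangs(self, toy_ref, toy_methylome):
        f = Fragment("chr1", 0, 50, "unique_nuclear")
        with pytest.raises(RuntimeError):
            deaminate(f, toy_ref, DamageParams(), toy_methylome)

    def test_zero_damage_leaves_no_events(self, toy_ref, toy_methylome, rng):
        params = DamageParams(delta_s=1e-300, delta_d=1e-300)
        frags = draw_fragments(toy_ref, 200, params, seed=rng)
        damage_fragments(frags, toy_ref, params, toy_methylome, seed=rng)
        assert all(not f.deam_events for f in frags)

    def test_certain_deamination_in_overhang(self, rng):
        ref = ReferenceSet(
            contigs={"n": "CAAAAAAAAA", "m": "AAAA"},
            contig_class={"n": "nuclear", "m": "mito"},
        )
        f = Fragment("n", 0, 10, "unique_nuclear", overhang5=1, overhang3=0, meth_states={})
        deaminate(f, ref, DamageParams(delta_s=1.0, delta_d=1e-300), None, rng)
        assert (0, "+") in f.deam_events
        assert observed_sequence(f, ref)[0] == "T"

    def test_g_to_a_in_three_prime_overhang(self, rng):
        ref = ReferenceSet(
            contigs={"n": "AAAAAAAAAG", "m": "AAAA"},
            contig_class={"n": "nuclear", "m": "mito"},
        )
        f = Fragment("n", 0, 10, "unique_nuclear", overhang5=0, overhang3=1, meth_states={})
        deaminate(f, ref, DamageParams(delta_s=1.0, delta_d=1e-300), None, rng)
        assert (9, "-") in f.deam_events
        assert observed_sequence(f, ref)[-1] == "A"

    def test_methylated_rate_ratio_matches_rho(self, rng):
        # double-strand context; equal numbers of methylated-CpG and lone Cs
        seq = "ACGAACAA" * 8  # one CpG C and one lone C per repeat
        ref = ReferenceSet(
            contigs={"n": seq, "m": "AAAA"}, contig_class={"n": "nuclear", "m": "mito"}
        )
        pos = ref.cpg_positions("n")
        track = MethylomeTrack({"n": (pos, np.ones(len(pos)))})
        params = DamageParams(delta_s=0.02, delta_d=0.02, lambda_ov=1.0, rho_meth=8.0)
        meth_hits = lone_hits = 0
        cpg = set(pos.tolist())
        for _ in range(4_000):
            f = Fragment("n", 0, len(seq), "unique_nuclear")
            apply_overhangs(f, 1.0, rng)
            deaminate(f, ref, params, track, rng)
            for off, strand in f.deam_events:
                if strand == "+":
                    if off in cpg:
                        meth_hits += 1
                    else:
                        lone_hits += 1
        assert meth_hits / lone_hits == pytest.approx(8.0, rel=0.15)

    def test_conservation_of_molecules(self, toy_ref, toy_methylome, rng):
        frags = draw_fragments(toy_ref, 500, DamageParams(), seed=rng)
        out = damage_fragments(frags, toy_ref, DamageParams(), toy_methylome, seed=rng)
        assert out is frags and len(out) == 500

    def test_events_only_on_reference_c_or_g(self, toy_ref, toy_methylome, rng):
        params = DamageParams(delta_s=0.8, delta_d=0.2)
        frags = draw_fragments(toy_ref, 100, params, seed=rng)
        damage_fragments(frags, toy_ref, params, toy_methylome, seed=rng)
        for f in frags:
            seq = toy_ref.contigs[f.contig][f.start : f.end]
            for off, strand in f.deam_events:
                assert seq[off] == ("C" if strand == "+" else "G")


class TestPositionalCalibration:
    def test_empirical_profile_tracks_closed_form(self, rng):
        from paleombd import simulate_ct_profile

        params = DamageParams(delta_s=0.4, delta_d=0.02, lambda_ov=0.4)
        sim = simulate_ct_profile(params, n_fragments=6_000, seed=rng)
        expect = np.array([expected_ct_profile(params, d) for d in sim["d"]])
        freq = sim["events"] / sim["sites"]
        se = np.sqrt(expect * (1 - expect) / sim["sites"])
        # pooled chi-square over 25 positions; guards the event sampler
        chi2 = float((((freq - expect) / se) ** 2).sum())
        from scipy import stats

        assert chi2 < stats.chi2.isf(1e-4, 25)

    def test_monotone_nonincreasing_when_ds_gt_dd(self, rng):
        from paleombd import simulate_ct_profile

        params = DamageParams(delta_s=0.5, delta_d=0.01, lambda_ov=0.3)
        sim = simulate_ct_profile(params, n_fragments=20_000, seed=rng)
        cond = sim["conditional"] / sim["sites"]
        assert all(a >= b - 1e-12 for a, b in zip(cond, cond[1:]))


class TestMethylationStates:
    def test_bernoulli_converges_to_track(self, rng):
        ref = ReferenceSet(
            contigs={"n": "ACG" * 200, "m": "AAAA"},
            contig_class={"n": "nuclear", "m": "mito"},
        )
        pos = ref.cpg_positions("n")
        track = MethylomeTrack({"n": (pos, np.full(len(pos), 0.3))})
        hits = total = 0
        for _ in range(300):
            f = Fragment("n", 0, 600, "unique_nuclear")
            assign_methylation(f, track, rng)
            hits += sum(f.meth_states.values())
            total += len(f.meth_states)
        assert hits / total == pytest.approx(0.3, abs=0.01)
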