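"""Misincorporation tables, damage-parameter fits, CpG-context ratio and Ms."""

import numpy as np
import pytest

from paleombd import (
    DamageParams,
    Fragment,
    MisincorporationTable,
    ReadRecord,
    aggregate_ms,
    build_misincorporation_table,
    cpg_context_ratio,
    expected_ct_profile,
    fit_damage_params,
    ms_track,
)
from paleombd.damage import apply_overhangs, deaminate, observed_sequence
from paleombd.genome import MethylomeTrack, ReferenceSet


def read(contig, start, seq, *, dup=False, mq="MQ25", origin="unique_nuclear", frac="MBD_minus", rid="r"):
    return ReadRecord(
        read_id=rid, fragment_id=0, contig=contig, start=start, end=start + len(seq),
        sequence=seq, origin_class=origin, is_duplicate=dup, mq_class=mq, fraction=frac,
    )


def tiny_ref(seq):
    return ReferenceSet(
        contigs={"n": seq, "m": "AAAA"}, contig_class={"n": "nuclear", "m": "mito"}
    )


def table_from_model(params: DamageParams, n_per_d: float = 1e8, d_max: int = 25):
    """Noise-free table carrying exact expected counts under the model."""
    n = np.full(d_max, n_per_d)
    p = np.array([expected_ct_profile(params, d) for d in range(1, d_max + 1)])
    return MisincorporationTable(d_max=d_max, c_sites=n, ct=n * p, g_sites=n, ga=n * p)


class TestTable:
    def test_single_read_worked_example(self):
        ref = tiny_ref("CGAT")
        table = build_misincorporation_table([read("n", 0, "TGAT")], ref)
        assert table.c_sites[0] == 1 and table.ct[0] == 1
        assert table.context_sites["CG"][0] == 1 and table.context_events["CG"][0] == 1
        assert table.ct[1:].sum() == 0

    def test_zero_damage_all_zero(self):
        ref = tiny_ref("ACGTCCGTA" * 10)
        reads = [read("n", i, ref.contigs["n"][i : i + 30]) for i in range(0, 50, 7)]
        table = build_misincorporation_table(reads, ref)
        assert table.ct.sum() == 0 and table.ga.sum() == 0
        assert table.c_sites.sum() > 0

    def test_duplicates_and_mq0_excluded(self):
        ref = tiny_ref("CAAA")
        reads = [
            read("n", 0, "TAAA", dup=True),
            read("n", 0, "TAAA", mq="MQ0_only", origin="repetitive"),
            read("n", 0, "TAAA", origin="microbial"),
        ]
        table = build_misincorporation_table(reads, ref)
        assert table.c_sites.sum() == 0

    def test_three_prime_g_to_a_mirrored(self):
        ref = tiny_ref("AACG")
        table = build_misincorporation_table([read("n", 0, "AACA")], ref)
        assert table.g_sites[0] == 1 and table.ga[0] == 1
        # reverse-strand CpG context: C at p-1, G at p
        assert table.context_sites["CG"][0] == 1 and table.context_events["CG"][0] == 1

    def test_frequencies_match_closed_form_on_simulation(self, rng):
        params = DamageParams(delta_s=0.4, delta_d=0.02, lambda_ov=0.4)
        seq = "C" * 64
        ref = tiny_ref(seq)
        track = MethylomeTrack({})
        reads = []
        for i in range(6_000):
            f = Fragment("n", 0, 64, "unique_nuclear")
            apply_overhangs(f, params.lambda_ov, rng)
            deaminate(f, ref, params, track, rng)
            reads.append(read("n", 0, observed_sequence(f, ref), rid=f"r{i}"))
        table = build_misincorporation_table(reads, ref)
        freq = table.ct_frequency()
        for d in range(1, 26):
            p = expected_ct_profile(params, d)
            se = np.sqrt(p * (1 - p) / table.c_sites[d - 1])
            assert abs(freq[d - 1] - p) < 4 * se

    def test_tsv_round_trip(self, tmp_path):
        ref = tiny_ref("CGAT")
        table = build_misincorporation_table([read("n", 0, "TGAT")], ref)
        path = tmp_path / "t.tsv"
        table.write_tsv(path)
        back = MisincorporationTable.read_tsv(path)
        np.testing.assert_allclose(back.ct, table.ct)
        np.testing.assert_allclose(back.context_sites["CG"], table.context_sites["CG"])


class TestFit:
    def test_flat_profile_flagged_degenerate(self):
        n = np.full(25, 1e8)
        table = MisincorporationTable(d_max=25, c_sites=n, ct=0.01 * n, g_sites=n, ga=0.01 * n)
        fit = fit_damage_params(table)
        assert fit.delta_d_hat == pytest.approx(0.01, abs=1e-4)
        assert fit.degenerate

    def test_all_zero_events_degenerate_zeros(self):
        n = np.full(25, 1e6)
        table = MisincorporationTable(d_max=25, c_sites=n, ct=np.zeros(25), g_sites=n, ga=np.zeros(25))
        fit = fit_damage_params(table)
        assert fit.degenerate and fit.delta_s_hat == 0.0 and fit.delta_d_hat == 0.0

    def test_noise_free_inversion_on_grid(self):
        # exact expected counts -> recovery within 1e-3 (small grid; the full
        # 3x3x3 sweep lives in the acceptance suite)
        for ds, dd, lam in [(0.4, 0.02, 0.4), (0.1, 0.005, 0.2), (0.5, 0.05, 0.8)]:
            truth = DamageParams(delta_s=ds, delta_d=dd, lambda_ov=lam)
            fit = fit_damage_params(table_from_model(truth))
            assert fit.delta_s_hat == pytest.approx(ds, abs=1e-3)
            assert fit.delta_d_hat == pytest.approx(dd, abs=1e-3)
            assert fit.lambda_hat == pytest.approx(lam, abs=1e-3)
            assert not fit.degenerate


class TestCpgContextRatio:
    def test_unit_ratio_without_methylation_effect(self):
        table = MisincorporationTable(d_max=2)
        for ctx in ("CA", "CC", "CG", "CT"):
            table.context_sites[ctx][:] = 1e6
            table.context_events[ctx][:] = 1e4
        assert cpg_context_ratio(table) == pytest.approx(1.0)

    def test_brute_force_recount_on_toy_reads(self):
        ref = tiny_ref("ACGACAACTACC" * 5)
        chrom = ref.contigs["n"]
        reads = []
        rng = np.random.default_rng(2)
        for i in range(60):
            s = int(rng.integers(0, len(chrom) - 12))
            seq = list(chrom[s : s + 12])
            for j, b in enumerate(seq):  # deaminate forward Cs at random
                if b == "C" and rng.random() < 0.3:
                    seq[j] = "T"
            reads.append(read("n", s, "".join(seq), rid=f"r{i}"))
        table = build_misincorporation_table(reads, ref, d_max=12)
        # independent recount straight from the read/reference pairs
        sites = {c: 0 for c in ("CA", "CC", "CG", "CT")}
        events = {c: 0 for c in ("CA", "CC", "CG", "CT")}
        comp = str.maketrans("ACGT", "TGCA")
        for r in reads:
            L = len(r.sequence)
            for d in range(1, min(12, L) + 1):
                i5 = d - 1
                p = r.start + i5
                if chrom[p] == "C" and p + 1 < len(chrom):
                    ctx = "C" + chrom[p + 1]
                    if ctx in sites:
                        sites[ctx] += 1
                        events[ctx] += r.sequence[i5] == "T"
                i3 = L - d
                p = r.start + i3
                if chrom[p] == "G" and p >= 1:
                    ctx = "C" + chrom[p - 1].translate(comp)
                    if ctx in sites:
                        sites[ctx] += 1
                        events[ctx] += r.sequence[i3] == "A"
        cpg_rate = events["CG"] / sites["CG"]
        other_rate = sum(events[c] for c in ("CA", "CC", "CT")) / sum(
            sites[c] for c in ("CA", "CC", "CT")
        )
        assert cpg_context_ratio(table) == pytest.approx(cpg_rate / other_rate, abs=1e-9)

    def test_no_noncpg_events_flagged_infinite(self):
        table = MisincorporationTable(d_max=2)
        table.context_sites["CG"][:] = 100
        table.context_events["CG"][:] = 5
        table.context_sites["CA"][:] = 100
        with pytest.warns(UserWarning):
            assert cpg_context_ratio(table) == np.inf

    def test_rho_recovered_in_precapture_pool(self, rng):
        # all CpGs methylated, rho=4, double-strand only -> per-site ratio ~ 4
        seq = "ACGAACAA" * 40
        ref = tiny_ref(seq)
        pos = ref.cpg_positions("n")
        track = MethylomeTrack({"n": (pos, np.ones(len(pos)))})
        params = DamageParams(delta_s=0.01, delta_d=0.01, lambda_ov=1.0, rho_meth=4.0)
        reads = []
        for i in range(12_000):
            f = Fragment("n", 0, 64, "unique_nuclear")
            apply_overhangs(f, 1.0, rng)
            deaminate(f, ref, params, track, rng)
            reads.append(read("n", 0, observed_sequence(f, ref)[:64], rid=f"r{i}"))
        table = build_misincorporation_table(reads, ref, d_max=25)
        # ~360 expected non-CpG events -> ratio MC sd ~6%; 0.2 is a 3-sigma band
        assert cpg_context_ratio(table) == pytest.approx(4.0, rel=0.2)


class TestMsTrack:
    def test_min_cov_validation(self, toy_ref):
        with pytest.raises(ValueError):
            ms_track([], toy_ref, min_cov=0)

    def test_no_deamination_all_zero(self):
        ref = tiny_ref("CG" + "A" * 200)
        reads = [read("n", 0, "CG" + "A" * 28, rid=f"r{i}") for i in range(60)]
        windows = ms_track(reads, ref, min_cov=50)
        assert len(windows) == 1
        assert windows[0].ms == 0.0 and windows[0].coverage == 60

    def test_threshold_edge_omits_window(self):
        ref = tiny_ref("CG" + "A" * 200)
        reads = [read("n", 0, "CG" + "A" * 28, rid=f"r{i}") for i in range(49)]
        assert ms_track(reads, ref, min_cov=50) == []
        assert len(ms_track(reads, ref, min_cov=49)) == 1

    def test_terminal_mismatches_counted_on_both_strands(self):
        ref = tiny_ref("CGAACG")
        reads = [
            read("n", 0, "TGAACG", rid="a"),  # 5' CpG->TpG
            read("n", 2, "AACA", rid="b"),  # 3' G->A on the CpG at 4
        ]
        windows = ms_track(reads, ref, min_cov=1)
        assert len(windows) == 1
        # read a: 5' CpG->TpG at 0 plus an undamaged 3' G over the CpG at 4;
        # read b: 3' G->A over the CpG at 4
        assert windows[0].coverage == 3 and windows[0].mismatches == 2
        assert aggregate_ms(windows) == pytest.approx(2 / 3)

    def test_duplicate_invariance(self):
        ref = tiny_ref("CG" + "A" * 100)
        base = [read("n", 0, "TG" + "A" * 18, rid=f"r{i}") for i in range(20)]
        with_dups = base + [read("n", 0, "CG" + "A" * 18, dup=True, rid=f"d{i}") for i in range(30)]
        assert ms_track(base, ref, min_cov=1) == ms_track(with_dups, ref, min_cov=1)

    def test_strata_ordering(self, rng):
        from paleombd.fixtures import make_fixture

        ref, track = make_fixture("two-strata-methylome")
        params = DamageParams(delta_s=0.4, delta_d=0.02, lambda_ov=0.35, rho_meth=4.0)
        reads = []
        chrom = ref.contigs["chr1"]
        for i in range(6_000):
            s = int(rng.integers(0, len(chrom) - 60))
            f = Fragment("chr1", s, s + 60, "unique_nuclear")
            apply_overhangs(f, params.lambda_ov, rng)
            deaminate(f, ref, params, track, rng)
            reads.append(read("chr1", s, observed_sequence(f, ref), rid=f"r{i}"))
        windows = ms_track(reads, ref, min_cov=1)
        low = [w for w in windows if w.start < 30_000]
        high = [w for w in windows if w.start >= 30_000]
        assert aggregate_ms(high) > aggregate_ms(low)
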