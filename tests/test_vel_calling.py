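import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import poisson_binom

from velscan.enhancer_catalog import SignalMatrix
from velscan.genomic_core import GenomicInterval, IntervalSet, PairManifest
from velscan.vel_calling import (
    VELParams,
    PairVELSet,
    bh_adjust,
    calibrate_recurrence_threshold,
    call_vels,
    merge_pair_vels,
    pair_vels,
    recurrence_pvalue,
)

from .conftest import catalog_from_loci, signal_from_bundle
from .oracles import bh_stepup, poisson_binomial_tail_enumeration


def make_signal(rpkm: pd.DataFrame) -> SignalMatrix:
    lengths = pd.Series(1000, index=rpkm.index)
    libs = pd.Series(1e6, index=rpkm.columns)
    counts = (rpkm * 1.0).astype(int)
    return SignalMatrix(rpkm=rpkm, counts=counts, lengths=lengths, library_sizes=libs)


def loci_for(index):
    return [
        GenomicInterval("chr1", 1000 * k, 1000 * k + 500, id=i)
        for k, i in enumerate(index)
    ]


class TestPairVels:
    def test_fold_change_boundary_inclusive(self):
        rpkm = pd.DataFrame({"n": [2.0], "t": [4.0]}, index=["E1"])
        cat = catalog_from_loci(loci_for(rpkm.index))
        ps = pair_vels(
            make_signal(rpkm), ("P1", "n", "t"), cat, VELParams(pseudocount=0.0)
        )
        assert [i.id for i in ps.gains] == ["E1"]
        assert len(ps.losses) == 0

    def test_pseudocount_neutralizes_zero_signal(self):
        rpkm = pd.DataFrame({"n": [0.0], "t": [0.0]}, index=["E1"])
        cat = catalog_from_loci(loci_for(rpkm.index))
        ps = pair_vels(make_signal(rpkm), ("P1", "n", "t"), cat, VELParams())
        assert len(ps.gains) == 0 and len(ps.losses) == 0

    def test_missing_sample_names_patient(self):
        rpkm = pd.DataFrame({"n": [1.0]}, index=["E1"])
        cat = catalog_from_loci(loci_for(rpkm.index))
        with pytest.raises(ValueError, match="P1"):
            pair_vels(make_signal(rpkm), ("P1", "n", "t"), cat)

    def test_matches_per_locus_recomputation(self, rng):
        n = 1000
        index = [f"E{i:04d}" for i in range(n)]
        rpkm = pd.DataFrame(
            {"n": rng.gamma(2, 2, n), "t": rng.gamma(2, 2, n)}, index=index
        )
        params = VELParams(pseudocount=0.5, fc_threshold=2.0)
        cat = catalog_from_loci(loci_for(index))
        ps = pair_vels(make_signal(rpkm), ("P1", "n", "t"), cat, params)
        want_gain, want_lost = set(), set()
        for i in index:
            fc = (rpkm.loc[i, "t"] + 0.5) / (rpkm.loc[i, "n"] + 0.5)
            if fc >= 2.0:
                want_gain.add(i)
            if 1.0 / fc >= 2.0:
                want_lost.add(i)
        assert {i.id for i in ps.gains} == want_gain
        assert {i.id for i in ps.losses} == want_lost
        assert ps.testable_count == n
        assert ps.rate_gain == len(want_gain) / n


class TestMergePairVels:
    def mk(self, patient, gains):
        return PairVELSet(
            patient_id=patient,
            gains=IntervalSet(gains),
            losses=IntervalSet([]),
            testable_count=100,
        )

    def test_single_patient_passthrough(self):
        g = [GenomicInterval("chr1", 0, 100, "a"), GenomicInterval("chr1", 500, 600, "b")]
        merged, support = merge_pair_vels([self.mk("P1", g)], "gain")
        assert merged.coordinates() == [("chr1", 0, 100), ("chr1", 500, 600)]
        assert support == [{"P1"}, {"P1"}]

    def test_identical_locus_two_patients(self):
        g = [GenomicInterval("chr1", 0, 100, "a")]
        merged, support = merge_pair_vels([self.mk("P1", g), self.mk("P2", g)], "gain")
        assert len(merged) == 1 and support == [{"P1", "P2"}]

    def test_patient_counts_once_with_multiple_vels(self):
        g1 = [GenomicInterval("chr1", 0, 100, "a"), GenomicInterval("chr1", 50, 150, "b")]
        merged, support = merge_pair_vels([self.mk("P1", g1)], "gain")
        assert len(merged) == 1 and support == [{"P1"}]

    def test_staggered_overlaps_match_bruteforce_patient_sets(self, rng):
        patients = [f"P{k}" for k in range(8)]
        sets = []
        all_tagged = []
        for p in patients:
            ivs = []
            for _ in range(15):
                s = int(rng.integers(0, 5000))
                iv = GenomicInterval("chr1", s, s + int(rng.integers(50, 400)))
                ivs.append(iv)
                all_tagged.append((p, iv))
            sets.append(self.mk(p, ivs))
        merged, support = merge_pair_vels(sets, "gain")
        # brute force: a patient supports a merged locus iff one of its
        # intervals lies within the merged span
        for m, supp in zip(merged, support):
            want = {
                p
                for p, iv in all_tagged
                if iv.chrom == m.chrom and iv.start >= m.start and iv.end <= m.end
            }
            assert supp == want


class TestRecurrencePvalue:
    def test_impossible_event(self):
        assert recurrence_pvalue(1, [0.0, 0.0, 0.0]) == 0.0

    def test_all_half_top(self):
        assert recurrence_pvalue(4, [0.5] * 4) == pytest.approx(0.0625)

    def test_r_zero_is_one(self):
        assert recurrence_pvalue(0, [0.2, 0.9]) == 1.0

    def test_rejects_bad_rates(self):
        with pytest.raises(ValueError, match="outside"):
            recurrence_pvalue(1, [0.5, 1.2])

    def test_matches_exhaustive_enumeration(self, rng):
        rates = rng.uniform(0, 1, size=10)
        for r in range(11):
            got = recurrence_pvalue(r, rates)
            want = poisson_binomial_tail_enumeration(r, rates)
            assert got == pytest.approx(want, abs=1e-12)

    def test_matches_scipy_poisson_binom(self, rng):
        rates = rng.uniform(0, 1, size=25)
        for r in range(1, 26):
            want = float(poisson_binom.sf(r - 1, rates))
            assert recurrence_pvalue(r, rates) == pytest.approx(want, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_nonincreasing_in_r(self, seed):
        rates = np.random.default_rng(seed).uniform(0, 1, size=12)
        tail = [recurrence_pvalue(r, rates) for r in range(13)]
        assert all(a >= b - 1e-15 for a, b in zip(tail, tail[1:]))

    def test_binomial_mean_agrees_for_equal_rates(self):
        rates = [0.3] * 15
        for r in range(16):
            assert recurrence_pvalue(r, rates, "binomial_mean") == pytest.approx(
                recurrence_pvalue(r, rates, "poisson_binomial"), abs=1e-12
            )


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_equal_ps_fixed_point(self):
        assert bh_adjust([0.2] * 7) == pytest.approx([0.2] * 7)

    def test_empty(self):
        assert len(bh_adjust([])) == 0

    def test_matches_independent_stepup(self, rng):
        p = rng.uniform(0, 1, size=200)
        assert np.allclose(bh_adjust(p), bh_stepup(p), atol=1e-15)

    def test_never_decreases_and_monotone(self, rng):
        p = rng.uniform(0, 1, size=100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestCalibration:
    def table(self, recurrences, padjs):
        return pd.DataFrame({"recurrence": recurrences, "padj": padjs})

    def test_all_significant_gives_one(self):
        t = self.table([1, 2, 3], [0.001] * 3)
        assert calibrate_recurrence_threshold(t, VELParams(), n_pairs=5) == 1

    def test_hand_enumerated_scan(self):
        # padj <= alpha exactly for loci with r >= 3
        t = self.table([1, 1, 2, 3, 3, 4], [0.5, 0.9, 0.2, 0.01, 0.02, 0.001])
        # frac(1) = 3/6, frac(2) = 3/4, frac(3) = 3/3 -> r* = 3
        assert calibrate_recurrence_threshold(t, VELParams(), n_pairs=6) == 3

    def test_none_qualifies_returns_n_pairs(self):
        t = self.table([1, 2], [0.9, 0.9])
        assert calibrate_recurrence_threshold(t, VELParams(), n_pairs=4) == 4

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            calibrate_recurrence_threshold(
                self.table([], []), VELParams(), n_pairs=4
            )

    def test_matches_bruteforce_scan(self, rng):
        for _ in range(20):
            n = 8
            t = self.table(
                rng.integers(1, n + 1, size=40), rng.uniform(0, 1, size=40)
            )
            params = VELParams(percent_cutoff=0.6)
            got = calibrate_recurrence_threshold(t, params, n_pairs=n)
            want = n
            for r in range(1, n + 1):
                sub = t[t["recurrence"] >= r]
                if len(sub) and (sub["padj"] <= params.alpha).mean() >= 0.6:
                    want = r
                    break
            assert got == want


class TestCallVels:
    def test_requires_two_pairs(self):
        rpkm = pd.DataFrame({"n": [1.0], "t": [1.0]}, index=["E1"])
        cat = catalog_from_loci(loci_for(rpkm.index))
        with pytest.raises(ValueError, match=">= 2 pairs"):
            call_vels(make_signal(rpkm), cat, PairManifest([("P1", "n", "t")]))

    def test_noise_free_planted_gains_recovered_with_designed_recurrence(self):
        from velscan.synthetic_cohort import CohortConfig, PlantSpec, simulate_cohort

        cfg = CohortConfig(
            n_pairs=5,
            n_enhancers=60,
            n_genes=20,
            genome=(("chr1", 2_000_000),),
            planted=(PlantSpec("gain", n_loci=8, recurrence_design=3),),
            pair_noise_log2_sd=0.0,
            library_size_range=(20_000_000, 20_000_000),
            baseline_log2_mean=5.0,
            baseline_log2_sd=0.0,
            seed=5,
        )
        bundle = simulate_cohort(cfg)
        cat, sig = signal_from_bundle(bundle)
        res = call_vels(sig, cat, bundle.manifest)
        gains = res.gain_table.set_index("id")
        truth = bundle.truth
        assert len(res.gain_table) == len(truth)
        called = {
            (r.chrom, r.start, r.end): r.recurrence
            for r in res.gain_table.itertuples()
        }
        for t in truth.itertuples():
            assert called[(t.chrom, t.start, t.end)] == t.recurrence_design

    def test_patient_order_permutation_invariant(self, tiny_bundle, rng):
        cat, sig = signal_from_bundle(tiny_bundle)
        res1 = call_vels(sig, cat, tiny_bundle.manifest)
        perm = PairManifest(
            [tiny_bundle.manifest.pairs[i] for i in rng.permutation(len(tiny_bundle.manifest))]
        )
        res2 = call_vels(sig, cat, perm)
        for a, b in ((res1.gain_table, res2.gain_table), (res1.lost_table, res2.lost_table)):
            pd.testing.assert_frame_equal(
                a.sort_values("id").reset_index(drop=True),
                b.sort_values("id").reset_index(drop=True),
            )

    def test_deterministic_across_reruns(self, tiny_bundle):
        cat, sig = signal_from_bundle(tiny_bundle)
        res1 = call_vels(sig, cat, tiny_bundle.manifest)
        res2 = call_vels(sig, cat, tiny_bundle.manifest)
        pd.testing.assert_frame_equal(res1.gain_table, res2.gain_table)
        pd.testing.assert_frame_equal(res1.lost_table, res2.lost_table)
        assert res1.r_star_gain == res2.r_star_gain

    def test_padj_at_least_pvalue_and_recurrence_consistency(self, tiny_bundle):
        cat, sig = signal_from_bundle(tiny_bundle)
        res = call_vels(sig, cat, tiny_bundle.manifest)
        for table in (res.gain_table, res.lost_table):
            assert (table["padj"] >= table["p_value"] - 1e-15).all()
            assert (
                table["recurrence"]
                == table["supporting_patients"].str.split(",").str.len()
            ).all()
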