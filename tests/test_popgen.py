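import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import naive_reference as ref
from conftest import random_alignment
from refugia.errors import InsufficientDataError
from refugia.popgen import (
    divergence_stats,
    diversity_stats,
    effective_length,
    fu_li_Dstar_Fstar,
    hudson_fst,
    nucleotide_diversity,
    pairwise_difference_moments,
    rarest_allele_moments,
    segregating_sites,
    summary_vector,
    tajimas_D,
    watterson_theta,
)
from refugia.seq_io import Alignment, PopulationAssignment


class TestToyValues:
    """Hand-enumerated expectations on the worked toy alignment."""

    def test_segregating_sites(self, toy_alignment):
        seg = segregating_sites(toy_alignment)
        assert seg.count == 2
        assert seg.positions == (6, 10)

    def test_pairwise_differences(self, toy_alignment):
        K, vK, pairs = pairwise_difference_moments(toy_alignment)
        assert sorted(pairs) == [0, 1, 1, 1, 2, 2]
        assert K == pytest.approx(7 / 6)
        assert vK == pytest.approx(np.var([1, 2, 2, 1, 1, 0]))

    def test_nucleotide_diversity(self, toy_alignment):
        assert nucleotide_diversity(toy_alignment) == pytest.approx(7 / 60)

    def test_watterson_theta(self, toy_alignment):
        per_site, per_locus = watterson_theta(toy_alignment)
        assert per_locus == pytest.approx(2 / (1 + 0.5 + 1 / 3))
        assert per_site == pytest.approx(per_locus / 10)

    def test_tajimas_d_positive(self, toy_alignment):
        # verified against an independent loop-based implementation
        assert tajimas_D(toy_alignment) == pytest.approx(0.5915801398995, abs=1e-9)
        assert tajimas_D(toy_alignment) == pytest.approx(
            ref.tajima_d([toy_alignment.sequence(i) for i in range(4)])
        )

    def test_fu_li_star_statistics(self, toy_alignment):
        # D* hand-derived: eta=2, eta_s=1, n=4 -> 0.8333/sqrt(1.9844)
        dstar, fstar = fu_li_Dstar_Fstar(toy_alignment)
        assert dstar == pytest.approx(0.591580, abs=1e-5)
        nd, nf = ref.fu_li([toy_alignment.sequence(i) for i in range(4)])
        assert dstar == pytest.approx(nd)
        assert fstar == pytest.approx(nf)

    def test_rarest_allele_moments(self, toy_alignment):
        mean, var = rarest_allele_moments(toy_alignment)
        assert (mean, var) == (1.5, 0.25)

    def test_hudson_fst_split(self, toy_split):
        assert hudson_fst(*toy_split) == pytest.approx(2 / 3)

    def test_divergence(self, toy_split):
        d = divergence_stats(*toy_split)
        assert d.Kxy == pytest.approx(1.5)
        assert d.Dxy == pytest.approx(0.15)
        assert d.Da == pytest.approx(0.10)


class TestEdgeCases:
    def test_monomorphic(self):
        a = Alignment.from_strings(["ACGT"] * 5)
        assert segregating_sites(a).count == 0
        assert nucleotide_diversity(a) == 0.0
        assert watterson_theta(a)[1] == 0.0
        assert math.isnan(tajimas_D(a))
        assert all(math.isnan(x) for x in rarest_allele_moments(a))

    def test_two_sequences_extremes(self):
        same = Alignment.from_strings(["ACGTACGTAC"] * 2)
        assert pairwise_difference_moments(same)[0] == 0.0
        diff = Alignment.from_strings(["AAAAAAAAAA", "CCCCCCCCCC"])
        assert pairwise_difference_moments(diff)[0] == 10.0
        # n=2, S=1 -> theta per locus = 1 (a_1 = 1)
        s1 = Alignment.from_strings(["AAAA", "AAAC"])
        assert watterson_theta(s1)[1] == pytest.approx(1.0)

    def test_insufficient_data(self):
        single = Alignment.from_strings(["ACGT"])
        with pytest.raises(InsufficientDataError):
            segregating_sites(single)
        three = Alignment.from_strings(["AAAA", "AAAC", "AACC"])
        with pytest.raises(InsufficientDataError):
            tajimas_D(three)

    def test_fixed_haplotypes_fst_one(self):
        a1 = Alignment.from_strings(["AAAA"] * 3)
        a2 = Alignment.from_strings(["AACC"] * 3)
        assert hudson_fst(a1, a2) == pytest.approx(1.0)
        d = divergence_stats(a1, a2)
        assert d.Dxy == pytest.approx(0.5)
        assert d.Da == pytest.approx(0.5)

    def test_no_singletons_balanced_dstar_positive(self):
        a = Alignment.from_strings(["AAAA"] * 4 + ["AACC"] * 4)
        dstar, _ = fu_li_Dstar_Fstar(a)
        assert dstar > 0

    def test_complete_deletion_drops_missing_columns(self):
        a = Alignment.from_strings(["ACGTN", "ACCT-", "ACCTA"])
        assert effective_length(a) == 4
        assert segregating_sites(a).count == 1
        assert nucleotide_diversity(a) == pytest.approx((2 / 3) / 4)


class TestOracleEquivalence:
    """Vectorized statistics agree with loop-based references exactly."""

    @pytest.mark.parametrize("missing_rate", [0.0, 0.08])
    def test_random_alignments(self, missing_rate):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(150):
            a = random_alignment(rng, missing_rate=missing_rate)
            seqs = [a.sequence(i) for i in range(a.n)]
            if len(ref.clean_columns(seqs)) == 0:
                continue
            seg = segregating_sites(a)
            assert seg.count == len(ref.seg_sites(seqs))
            K, vK, _ = pairwise_difference_moments(a)
            assert K == pytest.approx(ref.mean_k(seqs), abs=1e-9)
            assert vK == pytest.approx(ref.var_k(seqs), abs=1e-9)
            assert nucleotide_diversity(a) == pytest.approx(ref.pi(seqs), abs=1e-12)
            assert watterson_theta(a)[1] == pytest.approx(ref.watterson(seqs), abs=1e-9)
            if a.n >= 4 and seg.count >= 1:
                assert tajimas_D(a) == pytest.approx(ref.tajima_d(seqs), abs=1e-9)
                d_our = fu_li_Dstar_Fstar(a)
                d_ref = ref.fu_li(seqs)
                assert d_our == pytest.approx(d_ref, abs=1e-9)
            if seg.count >= 1:
                assert rarest_allele_moments(a) == pytest.approx(
                    ref.rarest(seqs), abs=1e-9
                )
            checked += 1
        assert checked >= 100

    def test_two_population_oracles(self):
        rng = np.random.default_rng(43)
        for _ in range(60):
            a = random_alignment(rng, n=int(rng.integers(4, 11)), length=30)
            half = a.n // 2
            a1, a2 = a.take(range(half)), a.take(range(half, a.n))
            s1 = [a1.sequence(i) for i in range(a1.n)]
            s2 = [a2.sequence(i) for i in range(a2.n)]
            f_ref = ref.hudson_fst(s1, s2)
            f_our = hudson_fst(a1, a2)
            if math.isnan(f_ref):
                assert math.isnan(f_our)
                continue
            assert f_our == pytest.approx(f_ref, abs=1e-9)
            Kxy, Dxy, Da = ref.divergence(s1, s2)
            d = divergence_stats(a1, a2)
            assert (d.Kxy, d.Dxy, d.Da) == pytest.approx((Kxy, Dxy, Da), abs=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_invariants_under_relabeling_and_pi_k_identity(seed):
    """Neutrality statistics ignore sequence order; pi*L == K throughout."""
    rng = np.random.default_rng(seed)
    a = random_alignment(rng, n=int(rng.integers(4, 10)), length=25)
    if segregating_sites(a).count == 0:
        return
    perm = rng.permutation(a.n)
    b = a.take(perm)
    assert tajimas_D(a) == pytest.approx(tajimas_D(b), abs=1e-12)
    assert fu_li_Dstar_Fstar(a) == pytest.approx(fu_li_Dstar_Fstar(b), abs=1e-12)
    K, _, _ = pairwise_difference_moments(a)
    assert nucleotide_diversity(a) * effective_length(a) == pytest.approx(K, abs=1e-9)


class TestSummaryVector:
    def _two_pop_dataset(self, rng):
        a = random_alignment(rng, n=8, length=40)
        pa = PopulationAssignment(
            {s: ("P1" if i < 4 else "P2") for i, s in enumerate(a.sample_ids)}
        )
        return a, pa

    def test_length_contract(self):
        rng = np.random.default_rng(3)
        a, pa = self._two_pop_dataset(rng)
        vec = summary_vector({"locus": a}, pa)
        assert len(vec) == 2 * 7 + 3
        assert len(vec.names) == len(vec.values) == len(vec.mask)

    def test_order_invariance_within_populations(self):
        rng = np.random.default_rng(4)
        a, pa = self._two_pop_dataset(rng)
        v1 = summary_vector({"locus": a}, pa)
        perm = np.concatenate([np.random.default_rng(0).permutation(4),
                               4 + np.random.default_rng(1).permutation(4)])
        v2 = summary_vector({"locus": a.take(perm)}, pa)
        assert np.allclose(v1.values, v2.values, atol=1e-12)

    def test_composition_matches_individual_statistics(self):
        rng = np.random.default_rng(5)
        a, pa = self._two_pop_dataset(rng)
        vec = summary_vector({"locus": a}, pa)
        names = list(vec.names)
        a1, a2 = a.take(range(4)), a.take(range(4, 8))
        d1 = diversity_stats(a1)
        assert vec.values[names.index("locus.P1.S")] == d1.S
        assert vec.values[names.index("locus.P1.K_mean")] == pytest.approx(d1.K)
        assert vec.values[names.index("locus.P1.tajima_D")] == pytest.approx(
            d1.tajima_D, nan_ok=True
        )
        dv = divergence_stats(a1, a2)
        assert vec.values[names.index("locus.P1|P2.Kxy")] == pytest.approx(dv.Kxy)
        assert vec.values[names.index("locus.P1|P2.S2")] == dv.S_joint
        f = vec.values[names.index("locus.P1|P2.fst")]
        if vec.mask[names.index("locus.P1|P2.fst")]:
            assert f == pytest.approx(dv.fst)

    def test_undefined_entries_masked_as_zero(self):
        a = Alignment.from_strings(["ACGT"] * 4 + ["ACGT"] * 4)
        pa = PopulationAssignment(
            {s: ("P1" if i < 4 else "P2") for i, s in enumerate(a.sample_ids)}
        )
        vec = summary_vector({"locus": a}, pa)
        names = list(vec.names)
        i = names.index("locus.P1.tajima_D")
        assert not vec.mask[i]
        assert vec.values[i] == 0.0
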