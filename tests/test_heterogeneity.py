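import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetpair.heterogeneity import (
    ComponentPair,
    fit_vaf_mixture,
    overlap_coefficient,
    recurrence_test,
    substitution_spectrum,
)
from hetpair.variants import ComponentCallset

from conftest import make_consensus


class TestOverlap:
    def test_identity_disjoint_partial(self):
        a = set(range(100))
        assert overlap_coefficient(a, a) == 1.0
        assert overlap_coefficient(a, set(range(100, 200))) == 0.0
        assert overlap_coefficient({1, 2, 3, 4, 5}, {1, 2, 3, 9}) == pytest.approx(0.75)

    def test_empty_sets_defined_as_zero(self):
        assert overlap_coefficient(set(), {1}) == 0.0
        assert overlap_coefficient(set(), set()) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
    )
    def test_symmetric_and_bounded(self, a, b):
        assert overlap_coefficient(a, b) == overlap_coefficient(b, a)
        assert 0.0 <= overlap_coefficient(a, b) <= 1.0


class TestPartition:
    def _callset(self, component, positions):
        return ComponentCallset(
            "T1", component, [make_consensus(pos=p) for p in positions]
        )

    def test_identical_callsets(self):
        pair = ComponentPair.from_callsets(
            self._callset("Neg", [10, 20, 30]), self._callset("Abr", [10, 20, 30])
        )
        assert not pair.private_neg and not pair.private_abr
        assert pair.overlap_snv == 1.0

    def test_empty_callset(self):
        pair = ComponentPair.from_callsets(
            self._callset("Neg", []), self._callset("Abr", [10])
        )
        assert pair.shared == set()
        assert pair.overlap_snv == 0.0

    def test_partition_is_disjoint_and_covering(self):
        pair = ComponentPair.from_callsets(
            self._callset("Neg", [10, 20, 30, 40]), self._callset("Abr", [30, 40, 50])
        )
        keys_neg = pair.callset_neg.keys()
        assert pair.shared | pair.private_neg == keys_neg
        assert pair.shared & pair.private_neg == set()
        assert len(pair.shared) == 2


class TestSpectrum:
    def test_strand_folding(self):
        snvs = [make_consensus(pos=10, ref="C", alt="T"),
                make_consensus(pos=20, ref="G", alt="A")]
        spectrum = substitution_spectrum(snvs)
        assert spectrum.as_dict()["C>T"] == 1.0

    def test_empty_flagged(self):
        spectrum = substitution_spectrum([])
        assert spectrum.empty and spectrum.fractions.sum() == 0

    def test_fractions_sum_to_one(self):
        snvs = [make_consensus(pos=i * 10, ref=r, alt=a)
                for i, (r, a) in enumerate([("C", "A"), ("C", "G"), ("T", "C"),
                                            ("G", "T"), ("A", "G")], start=1)]
        assert substitution_spectrum(snvs).fractions.sum() == pytest.approx(1.0)

    def test_invariant_under_reverse_complement_representation(self):
        pyr = [make_consensus(pos=10, ref="C", alt="A"),
               make_consensus(pos=20, ref="T", alt="G")]
        pur = [make_consensus(pos=10, ref="G", alt="T"),
               make_consensus(pos=20, ref="A", alt="C")]
        assert np.allclose(
            substitution_spectrum(pyr).fractions, substitution_spectrum(pur).fractions
        )


def _carrier_callset(component, genes, tumour_id):
    return ComponentCallset(
        tumour_id, component,
        [make_consensus(pos=100 + i, gene=g) for i, g in enumerate(genes)],
    )


class TestRecurrence:
    def _groups(self, carriers1, carriers2):
        g1 = [_carrier_callset("Neg", genes, f"A{i}") for i, genes in enumerate(carriers1)]
        g2 = [_carrier_callset("Neg", genes, f"B{i}") for i, genes in enumerate(carriers2)]
        return g1, g2

    def test_difference_threshold_and_p_value(self):
        # TP53 carried by 4/9 vs 1/9: difference 3, tested; p matches the
        # continuity-corrected proportion test (value frozen from R prop.test)
        g1, g2 = self._groups(
            [["TP53"]] * 4 + [[]] * 5, [["TP53"]] * 1 + [[]] * 8
        )
        table = recurrence_test(g1, g2)
        row = table[table.gene == "TP53"].iloc[0]
        assert row.difference == 3
        assert row.p_value == pytest.approx(0.2925841403, abs=1e-9)

    def test_small_difference_excluded_before_testing(self):
        g1, g2 = self._groups([["PIK3CA"]] * 2 + [[]] * 7, [["PIK3CA"]] * 1 + [[]] * 8)
        assert len(recurrence_test(g1, g2)) == 0

    def test_nongenic_variants_do_not_count(self):
        up = ComponentCallset("A0", "Neg", [make_consensus(gene="CDH1", func_class="upstream")])
        g2 = [_carrier_callset("Neg", [], f"B{i}") for i in range(3)]
        table = recurrence_test([up] * 3, g2)
        assert len(table) == 0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            recurrence_test([], [_carrier_callset("Neg", [], "B0")])


class TestVafMixture:
    def test_single_clone_recovery(self):
        rng = np.random.default_rng(1)
        depths = rng.poisson(80, 500)
        alts = rng.binomial(depths, 0.35)
        fit = fit_vaf_mixture(alts=alts, depths=depths, k_max=3)
        assert fit.k == 1
        assert fit.means[0] == pytest.approx(0.35, abs=0.02)

    def test_two_clone_recovery(self):
        rng = np.random.default_rng(2)
        d1, d2 = rng.poisson(80, 300), rng.poisson(80, 200)
        alts = np.concatenate([rng.binomial(d1, 0.40), rng.binomial(d2, 0.10)])
        depths = np.concatenate([d1, d2])
        fit = fit_vaf_mixture(alts=alts, depths=depths, k_max=3)
        assert fit.k == 2
        assert fit.means[0] == pytest.approx(0.10, abs=0.03)
        assert fit.means[1] == pytest.approx(0.40, abs=0.03)
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_too_few_variants_refused(self):
        with pytest.raises(ValueError, match="at least 20"):
            fit_vaf_mixture(alts=np.ones(10), depths=np.full(10, 50))

    def test_all_zero_alt_refused(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_vaf_mixture(alts=np.zeros(30), depths=np.full(30, 50))

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        depths = rng.poisson(60, 100)
        alts = rng.binomial(depths, 0.25)
        f1 = fit_vaf_mixture(alts=alts, depths=depths, k_max=3)
        f2 = fit_vaf_mixture(alts=alts, depths=depths, k_max=3)
        assert f1.k == f2.k
        assert np.array_equal(f1.means, f2.means)
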