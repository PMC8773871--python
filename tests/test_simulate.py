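import numpy as np
import pandas as pd
import pytest

from hetpair.filters import apply_post_hoc_filters
from hetpair.heterogeneity import overlap_coefficient
from hetpair.simulate import (
    CallerProfile,
    SimulationConfig,
    simulate_methylation,
    simulate_mutation_set,
    make_genes,
)
from hetpair.variants import build_consensus, normalize_variant


def perfect_callers():
    return {c: CallerProfile(sensitivity=1.0, false_positives=0)
            for c in ("callerA", "callerB", "callerC")}


def clean_config(**kw):
    """No annotation noise: every emitted variant passes the filter chain."""
    defaults = dict(
        seed=0, n_mutations_total=300, caller_profiles=perfect_callers(),
        multiallelic_fraction=0.0, common_variant_fraction=0.0,
        synonymous_fraction=0.0, normal_contamination_fraction=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def consensus_keys(pair, component):
    callsets = {
        caller: pair.calls[(component, caller)]
        for caller in ("callerA", "callerB", "callerC")
    }
    return {v.key for v in build_consensus(callsets)}


class TestConfigValidation:
    def test_bad_trunk_fraction(self):
        with pytest.raises(ValueError, match="trunk_fraction"):
            clean_config(trunk_fraction=1.5).validate()

    def test_bad_signature_weights(self):
        with pytest.raises(ValueError, match="sum"):
            clean_config(signature_mixture={"SBS1": 0.5, "SBS2": 0.4}).validate()

    def test_bad_purity(self):
        with pytest.raises(ValueError, match="purity"):
            clean_config(purity=0.0).validate()


class TestDeterminism:
    def test_same_seed_identical_output(self, reference, catalog):
        a = simulate_mutation_set(clean_config(seed=3), reference, catalog)
        b = simulate_mutation_set(clean_config(seed=3), reference, catalog)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for key in a.calls:
            assert a.calls[key] == b.calls[key]

    def test_different_seed_differs(self, reference, catalog):
        a = simulate_mutation_set(clean_config(seed=3), reference, catalog)
        b = simulate_mutation_set(clean_config(seed=4), reference, catalog)
        assert not a.truth.equals(b.truth)


class TestSharingRegimes:
    def test_full_sharing(self, reference, catalog):
        pair = simulate_mutation_set(
            clean_config(trunk_fraction=1.0), reference, catalog
        )
        neg, abr = consensus_keys(pair, "Neg"), consensus_keys(pair, "Abr")
        assert neg == abr
        assert overlap_coefficient(neg, abr) == 1.0

    def test_collision_regime(self, reference, catalog):
        pair = simulate_mutation_set(
            clean_config(trunk_fraction=0.0), reference, catalog
        )
        neg, abr = consensus_keys(pair, "Neg"), consensus_keys(pair, "Abr")
        assert overlap_coefficient(neg, abr) == 0.0


class TestTruthStructure:
    def test_truncal_mutations_in_both_components(self, reference, catalog):
        pair = simulate_mutation_set(clean_config(trunk_fraction=0.5), reference, catalog)
        truncal = pair.truth[pair.truth.label == "truncal"]
        assert len(truncal) == 150
        assert truncal.in_neg.all() and truncal.in_abr.all()
        private = pair.truth[pair.truth.label == "private_neg"]
        assert private.in_neg.all() and not private.in_abr.any()

    def test_truth_vaf_in_range(self, reference, catalog):
        pair = simulate_mutation_set(clean_config(), reference, catalog)
        assert pair.truth.vaf_neg.between(0, 1).all()
        assert pair.truth.vaf_abr.between(0, 1).all()

    def test_subclone_vaf_scales_with_cellular_fraction(self, reference, catalog):
        cfg = clean_config(subclones={"Neg": [(0.4, 50)], "Abr": []}, purity=0.8)
        pair = simulate_mutation_set(cfg, reference, catalog)
        sub = pair.truth[pair.truth.label == "subclone_neg_1"]
        assert len(sub) == 50
        assert np.allclose(sub.vaf_neg, 0.8 * 0.4 / 2)

    def test_emitted_indels_are_left_aligned(self, reference, catalog):
        cfg = clean_config(indel_fraction=1.0, n_mutations_total=60)
        pair = simulate_mutation_set(cfg, reference, catalog)
        for v in pair.calls[("Neg", "callerA")]:
            assert normalize_variant(v, reference).key == v.key


class TestVafLaw:
    def test_mean_observed_vaf_converges_to_half_purity(self, reference, catalog):
        """At depth 500 the mean observed VAF of truncal diploid-het
        mutations is purity/2 within 0.01."""
        cfg = clean_config(
            n_mutations_total=1000, trunk_fraction=1.0, purity=0.7,
            mean_depth_tumour=500, indel_fraction=0.0,
        )
        pair = simulate_mutation_set(cfg, reference, catalog)
        calls = pair.calls[("Neg", "callerA")]
        observed = np.array([c.tumour_alt / c.tumour_depth for c in calls])
        assert observed.mean() == pytest.approx(0.35, abs=0.01)


class TestCallerBehaviour:
    def test_sensitivity_thins_callsets(self, reference, catalog):
        cfg = clean_config(
            caller_profiles={
                "callerA": CallerProfile(sensitivity=0.5),
                "callerB": CallerProfile(sensitivity=1.0),
                "callerC": CallerProfile(sensitivity=1.0),
            },
            n_mutations_total=400, indel_fraction=0.0,
        )
        pair = simulate_mutation_set(cfg, reference, catalog)
        n_a = len(pair.calls[("Neg", "callerA")])
        n_b = len(pair.calls[("Neg", "callerB")])
        assert n_b == 400
        assert n_a == pytest.approx(200, abs=60)

    def test_false_positives_have_no_truth_support_and_are_filtered(
        self, reference, catalog
    ):
        cfg = clean_config(
            caller_profiles={
                "callerA": CallerProfile(false_positives=10),
                "callerB": CallerProfile(),
                "callerC": CallerProfile(),
            },
            n_mutations_total=100, indel_fraction=0.0,
        )
        pair = simulate_mutation_set(cfg, reference, catalog)
        fps = pair.truth[pair.truth.label == "false_positive"]
        assert len(fps) == 20  # 10 per component
        assert (fps.vaf_neg == 0).all() and (fps.vaf_abr == 0).all()
        # single-caller support: FPs never reach consensus
        assert consensus_keys(pair, "Neg") == pair.truth_keys("Neg")
        # and even if passed directly to the filters, low alt counts fail
        callsA = pair.calls[("Neg", "callerA")]
        cons = build_consensus({"callerA": callsA, "callerB": callsA})
        surv, _ = apply_post_hoc_filters(cons)
        surviving_fp = {v.key for v in surv} - pair.truth_keys("Neg")
        assert surviving_fp == set()


class TestMethylationSim:
    def test_no_discordance_when_fraction_zero(self, reference):
        cfg = clean_config(discordant_probe_fraction=0.0, n_probes=500)
        genes = make_genes(cfg, reference)
        probes, truth = simulate_methylation(cfg, genes, reference)
        assert len(truth) == 0
        assert len(probes) == 500

    def test_failed_probe_has_high_detection_p(self, reference):
        cfg = clean_config(n_probes=2000, probe_fail_fraction=0.05)
        genes = make_genes(cfg, reference)
        probes, _ = simulate_methylation(cfg, genes, reference)
        failing = probes[(probes.detp_Neg > 0.05) | (probes.detp_Abr > 0.05)]
        assert len(failing) > 0

    def test_planted_promoter_gene_is_hypermethylated(self, reference):
        cfg = clean_config(
            n_probes=3000, discordant_probe_fraction=0.0,
            planted_promoter_methylation=[{"gene": "CTNNA1", "component": "Neg"}],
        )
        genes = make_genes(cfg, reference)
        probes, truth = simulate_methylation(cfg, genes, reference)
        planted = probes[probes.probe_id.isin(truth.probe_id)]
        assert len(planted) > 0
        assert (planted.beta_Neg > 0.3).all()
        assert (planted.beta_Abr <= 0.3).all()
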