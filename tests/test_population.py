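"""Virtual-patient generation: genotypes, body size, binding, renal."""

import math

import numpy as np
import pytest

from irinosim.compounds import COMPOUND_NAMES
from irinosim.model import IrinotecanPBPK
from irinosim.parameters import ParameterDomainError
from irinosim.population import (
    GENOTYPE_LOCI,
    DistributionSpec,
    GenotypeProfile,
    PopulationModel,
    apply_genotype_effects,
    binding_fractions,
    body_surface_area,
    renal_clearance,
    sample_body_size,
    sample_genotypes,
    ugt1a1_reference_correction,
)


class TestGenotypeSampling:
    def test_zero_frequency_gives_all_wild(self, rng):
        freqs = {locus: 0.0 for locus in GENOTYPE_LOCI}
        profiles = sample_genotypes(freqs, 50, rng)
        assert all(p.states == ("wild",) * 6 for p in profiles)

    def test_unit_frequency_gives_all_hom(self, rng):
        freqs = {locus: 1.0 for locus in GENOTYPE_LOCI}
        profiles = sample_genotypes(freqs, 50, rng)
        assert all(p.states == ("hom",) * 6 for p in profiles)

    def test_hardy_weinberg_proportions_at_half(self, rng):
        """q = 0.5 gives hom fraction 0.25 within 3 binomial SE at n=10,000."""
        freqs = {locus: 0.5 for locus in GENOTYPE_LOCI}
        profiles = sample_genotypes(freqs, 10_000, rng)
        hom = np.mean([p["UGT1A1*28"] == "hom" for p in profiles])
        se = math.sqrt(0.25 * 0.75 / 10_000)
        assert abs(hom - 0.25) < 3 * se

    def test_hwe_chi_square_on_fixture_frequencies(self, tables, rng):
        """Sampled diplotype counts fit Hardy-Weinberg expectations."""
        from scipy.stats import chisquare

        n = 20_000
        for locus in GENOTYPE_LOCI:
            q = tables.genetics.loci[locus].allele_freq
            freqs = {x: tables.genetics.loci[x].allele_freq for x in GENOTYPE_LOCI}
            profiles = sample_genotypes(freqs, n, rng)
            counts = np.array(
                [sum(p[locus] == g for p in profiles) for g in ("wild", "het", "hom")]
            )
            expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
            keep = expected > 5
            stat, p = chisquare(counts[keep], expected[keep] * counts[keep].sum()
                                / expected[keep].sum())
            assert p > 0.001

    def test_invalid_frequency_rejected(self, rng):
        with pytest.raises(ParameterDomainError):
            sample_genotypes({locus: 1.5 for locus in GENOTYPE_LOCI}, 5, rng)


class TestGenotypeEffects:
    def test_all_wild_profile_leaves_parameters_unchanged(self, tables, base_params):
        scaled = apply_genotype_effects(
            base_params, GenotypeProfile.all_wild(), tables.genetics
        )
        for c in COMPOUND_NAMES:
            assert scaled.elementary[c].cl_bile == base_params.elementary[c].cl_bile
            assert scaled.elementary[c].cl_met_paths == base_params.elementary[c].cl_met_paths

    def test_full_contribution_scales_by_activity_ratio(self, tables, base_params):
        """UGT1A1 carries 100% of SN-38 glucuronidation, so a hom activity
        ratio multiplies the clearance directly."""
        profile = GenotypeProfile(("hom", "wild", "wild", "wild", "wild", "wild"))
        a_hom = tables.genetics.loci["UGT1A1*28"].activity["hom"]
        scaled = apply_genotype_effects(base_params, profile, tables.genetics)
        assert scaled.elementary["SN38"].cl_met_paths["SN38G"] == pytest.approx(
            a_hom * base_params.elementary["SN38"].cl_met_paths["SN38G"]
        )

    def test_partial_contribution_null_allele(self, tables, base_params):
        """A transporter carrying 33% of biliary flux, fully abolished,
        leaves 67% of the clearance: P * ((1-c) + c*a) with a=0."""
        import copy

        genetics = copy.deepcopy(tables.genetics)
        genetics.loci["ABCG2_421"].activity["hom"] = 0.0
        profile = GenotypeProfile(("wild", "wild", "wild", "hom", "wild", "wild"))
        scaled = apply_genotype_effects(base_params, profile, genetics)
        assert scaled.elementary["SN38"].cl_bile == pytest.approx(
            0.67 * base_params.elementary["SN38"].cl_bile
        )

    def test_transporter_contributions_to_one_parameter_sum_below_one(self, tables):
        from collections import defaultdict

        total = defaultdict(float)
        for locus in ("ABCG2_421", "ABCB1_3435", "ABCC2_-24"):
            for compound, param, c in tables.genetics.loci[locus].effects:
                total[(compound, param)] += c
        assert all(v <= 1.0 + 1e-9 for v in total.values())

    def test_ugt1a1_reference_correction(self, base_params):
        """The fitted glucuronidation clearance is a 50/50 *1/*1-*1/*28 mix
        mean; the corrected wild-type value restores that mix mean."""
        a_het = 0.7
        corrected = ugt1a1_reference_correction(base_params, a_het)
        cl_wild = corrected.elementary["SN38"].cl_met_paths["SN38G"]
        mix_mean = 0.5 * cl_wild + 0.5 * a_het * cl_wild
        assert mix_mean == pytest.approx(
            base_params.elementary["SN38"].cl_met_paths["SN38G"]
        )


class TestBodySize:
    def test_power_law_at_70_kg(self):
        # independent evaluation: 4.688 * 70000**(0.8168 - 0.0154*log10(70000))
        assert body_surface_area(70.0) == pytest.approx(1.853, abs=0.01)

    def test_deterministic_when_cvs_are_zero(self, rng):
        bw, bsa = sample_body_size(rng, mean_bw=78.8, cv_bw=0.0, cv_bsa=0.0)
        assert bw == 78.8
        assert bsa == pytest.approx(body_surface_area(78.8))

    def test_population_distribution_recovery(self):
        """BW ~ N(78.8, 11.7%) through the power law with 5.5% noise gives
        the reported BSA distribution: mean 1.97 m^2, CV 9.6%."""
        rng = np.random.default_rng(7)
        bsas = np.array([sample_body_size(rng)[1] for _ in range(100_000)])
        assert bsas.mean() == pytest.approx(1.97, rel=0.02)
        assert bsas.std() / bsas.mean() == pytest.approx(0.096, rel=0.05)


class TestBindingFractions:
    def test_no_binding_gives_unit_unbound_fraction(self):
        f_p, _ = binding_fractions(0.0, 0.5, 0.45, "irinotecan")
        assert f_p == 1.0

    def test_symmetric_binding_collapses_blood_to_plasma(self):
        f_p, f_b = binding_fractions(4.0, 0.2, 0.45, "irinotecan")
        assert f_p == pytest.approx(0.2)
        assert f_b == pytest.approx(f_p)  # f_p == f_r makes Hct cancel

    def test_sn38g_skips_blood_cells(self):
        f_p, f_b = binding_fractions(19.0, None, 0.45, "SN38G")
        assert f_p == pytest.approx(0.05)
        assert f_b == pytest.approx(0.05 / 0.55)

    def test_invalid_hematocrit_rejected(self):
        with pytest.raises(ParameterDomainError):
            binding_fractions(1.0, 0.5, 1.0, "irinotecan")


class TestRenalClearance:
    def test_zero_secretion_reduces_to_filtration(self):
        cl = renal_clearance(f_b=0.3, gfr=6.3, cl_int_sec=0.0, ff=0.2, hct=0.45)
        assert cl == pytest.approx(0.3 * 6.3, rel=1e-12)

    def test_flow_limited_ceiling(self):
        """Secretion saturates at the tubular blood flow Q_rtb."""
        gfr, ff, hct = 6.3, 0.2, 0.45
        q_rtb = gfr / ff / (1 - hct) - gfr
        cl = renal_clearance(0.3, gfr, 1e6, ff, hct)
        assert cl - 0.3 * gfr == pytest.approx(q_rtb, rel=1e-3)

    def test_linear_regime_matches_intrinsic_clearance(self):
        """For small f_b*CL_int/Q_rtb the dispersion model is linear:
        CL_sec ~ f_b * CL_int within 2% (series-expansion oracle)."""
        f_b, gfr, ff, hct = 0.05, 6.3, 0.2, 0.45
        cl_int = 0.5
        cl = renal_clearance(f_b, gfr, cl_int, ff, hct)
        assert cl - f_b * gfr == pytest.approx(f_b * cl_int, rel=0.02)

    def test_filtration_is_a_lower_bound(self, rng):
        for _ in range(50):
            f_b = rng.uniform(0.01, 1.0)
            cl_int = rng.uniform(0.0, 100.0)
            cl = renal_clearance(f_b, 6.3, cl_int, 0.2, 0.45)
            assert cl >= f_b * 6.3 - 1e-12

    def test_filtration_fraction_domain_enforced(self):
        with pytest.raises(ParameterDomainError):
            renal_clearance(0.3, 6.3, 1.0, ff=1.0, hct=0.45)
        with pytest.raises(ParameterDomainError):
            renal_clearance(0.3, 6.3, 1.0, ff=0.2, hct=1.2)


class TestDistributionSpec:
    def test_lognormal_mean_recovery(self, rng):
        spec = DistributionSpec(2.5, 0.4)
        draws = np.array([spec.sample(rng) for _ in range(10_000)])
        se = draws.std() / math.sqrt(len(draws))
        assert abs(draws.mean() - 2.5) < 3 * se

    def test_zero_cv_is_deterministic(self, rng):
        assert DistributionSpec(3.0, 0.0).sample(rng) == 3.0

    def test_invalid_shape_rejected(self):
        with pytest.raises(ParameterDomainError):
            DistributionSpec(1.0, 0.1, "uniform")


class TestPatientAssembly:
    def test_same_seed_reproduces_patient(self, population_model):
        p1 = population_model.sample_patient(np.random.default_rng(42))
        p2 = population_model.sample_patient(np.random.default_rng(42))
        assert p1.genotype.states == p2.genotype.states
        assert p1.body_weight == p2.body_weight
        assert (
            p1.params.elementary["SN38"].cl_met_paths
            == p2.params.elementary["SN38"].cl_met_paths
        )

    def test_different_seeds_differ_in_varying_parameters(self, population_model):
        p1 = population_model.sample_patient(np.random.default_rng(1))
        p2 = population_model.sample_patient(np.random.default_rng(2))
        assert p1.params.elementary["SN38"].v_central != p2.params.elementary[
            "SN38"
        ].v_central
        assert p1.body_weight != p2.body_weight

    def test_patients_are_simulate_ready(self, population_model, rng):
        for _ in range(3):
            pt = population_model.sample_patient(rng)
            exp = IrinotecanPBPK(pt.params).exposures()
            assert exp.mass_balance == pytest.approx(1.0, abs=1e-8)
            assert exp.auc_plasma["SN38"] > 0

    def test_binding_stays_physical(self, population_model, rng):
        for _ in range(20):
            pt = population_model.sample_patient(rng)
            for c in COMPOUND_NAMES:
                d = pt.params.disposition[c]
                assert 0 < d.f_p <= 1
                assert d.f_b > 0
                assert d.cl_r >= d.f_b * pt.params.physiology.gfr * pt.body_weight - 1e-9

    def test_population_mean_recovers_base_parameter(self, population_model):
        """Lognormal multiplicative noise has mean 1, so the sample mean of
        a perturbed clearance approaches the (corrected) base value."""
        rng = np.random.default_rng(5)
        base = population_model.base_params.elementary["irinotecan"].cl_bile
        genetics = population_model.genetics
        draws = []
        for _ in range(4000):
            pt = population_model.sample_patient(
                rng, genotype=GenotypeProfile.all_wild()
            )
            draws.append(pt.params.elementary["irinotecan"].cl_bile)
        draws = np.array(draws)
        se = draws.std() / math.sqrt(len(draws))
        assert abs(draws.mean() - base) < 3.5 * se
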