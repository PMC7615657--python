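"""Unit tests for the promoter-occupancy model and its oracle."""

import numpy as np
import pytest
from scipy.optimize import brentq

from ecdose import (
    DoseResponseProfile,
    PromoterArchitecture,
    ReceptorParams,
    SpongeSpec,
    brute_force_activity,
    chi,
    conditional_ligand_occupancy,
    effective_hill_coefficient,
    half_activation_dose,
    multi_ere_activity,
    normalized_activity,
    predicted_fluorescence,
    receptor_probabilities,
    response_features,
    sponge_activity,
)

DOSES = np.array([0.0, 20.0, 200.0, 2000.0])


class TestReceptorProbabilities:
    def test_no_ligand_splits_by_weights(self):
        p_act, p_rep = receptor_probabilities(0.0, ReceptorParams(1.0, 65.0))
        assert p_act == 0.0
        assert p_rep == pytest.approx(0.5)

    def test_saturation_limit(self):
        p_act, p_rep = receptor_probabilities(1e15, ReceptorParams(1.0, 65.0))
        assert p_act == pytest.approx(1.0, abs=1e-10)
        assert p_rep == pytest.approx(0.0, abs=1e-10)

    def test_half_activation_at_KE_times_one_plus_kR(self):
        # solving e/(1+kR+e) = 1/2 gives e = 1+kR
        for k_r in (0.3, 1.0, 4.0):
            rp = ReceptorParams(k_r, 65.0)
            p_act, _ = receptor_probabilities(65.0 * (1.0 + k_r), rp)
            assert p_act == pytest.approx(0.5, rel=1e-12)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            receptor_probabilities(-1.0, ReceptorParams())

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ReceptorParams(kappa_R_bar=-0.1)
        with pytest.raises(ValueError):
            ReceptorParams(K_E=0.0)


class TestChi:
    def test_neutral_receptor(self):
        # kappa_R_bar = 0 and E = 0: P_act = P_rep = 0, chi = 1
        assert chi(0.0, ReceptorParams(0.0, 65.0), 0.1, 10.0) == pytest.approx(1.0)

    def test_fully_activating_limit_equals_CEA(self):
        assert chi(1e16, ReceptorParams(1.0, 65.0), 0.1, 10.0) == pytest.approx(
            10.0, rel=1e-10
        )

    def test_hand_substitution_at_zero_ligand(self):
        # kR = 1, E = 0: P_rep = 0.5, P_act = 0 -> chi = 1 + (0.1-1)*0.5 = 0.55
        assert chi(0.0, ReceptorParams(1.0, 65.0), 0.1, 10.0) == pytest.approx(0.55)


class TestNormalizedActivity:
    def test_saturating_anchor(self, ere_arch, receptor):
        assert float(
            multi_ere_activity(1e15, ere_arch, receptor)
        ) == pytest.approx(1.0, rel=1e-9)

    def test_promoter_saturation_flattens_response(self, receptor):
        arch = PromoterArchitecture(
            n_ere=1, C_ER=0.1, C_EA=10.0, C_T=1e9, kappa_P=1.0
        )
        a = np.asarray(normalized_activity(DOSES, arch, receptor))
        assert np.allclose(a, 1.0, atol=1e-6)

    def test_matches_brute_force_on_dose_grid(self, ere_arch, receptor):
        closed = np.asarray(normalized_activity(DOSES, ere_arch, receptor))
        brute = np.asarray(brute_force_activity(DOSES, ere_arch, receptor))
        np.testing.assert_allclose(closed, brute, rtol=1e-12)

    def test_rejects_multi_site_architecture(self, receptor):
        arch = PromoterArchitecture(n_ere=2)
        with pytest.raises(ValueError, match="multi_ere_activity"):
            normalized_activity(20.0, arch, receptor)

    def test_low_affinity_limit_is_chi_over_CEA(self, receptor):
        arch = PromoterArchitecture(
            n_ere=1, C_ER=0.1, C_EA=10.0, C_T=1.0, kappa_P=1e-12
        )
        a = np.asarray(normalized_activity(DOSES, arch, receptor))
        expected = np.asarray(chi(DOSES, receptor, 0.1, 10.0)) / 10.0
        np.testing.assert_allclose(a, expected, rtol=1e-9)


class TestBruteForce:
    def test_two_independent_sites_equal_chi_squared_form(self, receptor):
        # omega = 1: the bound-state receptor factor factorizes as chi**n
        arch = PromoterArchitecture(n_ere=2, C_ER=0.1, C_EA=10.0, C_T=2.0, kappa_P=0.2)
        x = np.asarray(chi(DOSES, receptor, 0.1, 10.0))
        w = arch.kappa_P * arch.C_T * x**2
        w_inf = arch.kappa_P * arch.C_T * arch.C_EA**2
        expected = (w / (1 + w)) / (w_inf / (1 + w_inf))
        np.testing.assert_allclose(
            np.asarray(brute_force_activity(DOSES, arch, receptor)),
            expected,
            rtol=1e-12,
        )

    def test_no_ere_gives_constant_activity(self, receptor):
        arch = PromoterArchitecture(n_ere=0, C_T=2.0, kappa_P=0.1)
        a = np.asarray(brute_force_activity(DOSES, arch, receptor))
        assert np.allclose(a, a[0])

    def test_refuses_large_state_spaces(self, receptor):
        with pytest.raises(ValueError, match="enumeration refused"):
            brute_force_activity(20.0, PromoterArchitecture(n_ere=9), receptor)


class TestMultiEre:
    def test_omega_one_matches_brute_force_five_sites(self, receptor):
        arch = PromoterArchitecture(
            n_ere=5, C_ER=0.1, C_EA=10.0, C_T=1.0, kappa_P=0.1, omega=1.0
        )
        np.testing.assert_allclose(
            np.asarray(multi_ere_activity(DOSES, arch, receptor)),
            np.asarray(brute_force_activity(DOSES, arch, receptor)),
            rtol=1e-12,
        )

    def test_omega_zero_blocks_double_occupancy(self, receptor):
        # omega=0, n=2: TM-bound states allow at most one ligand-bound site,
        # so the occupancy weight is kP*(r^2 + 2*e*C_EA*r)/(1+kR+e)^2 with
        # r = 1 + kR*C_ER (hand enumeration of the 2*3^2 states).
        from ecdose import bound_probability

        arch = PromoterArchitecture(
            n_ere=2, C_ER=0.1, C_EA=10.0, C_T=1.0, kappa_P=0.1, omega=0.0
        )
        for E in (0.0, 20.0, 200.0, 2000.0):
            e = E / receptor.K_E
            r = 1.0 + receptor.kappa_R_bar * arch.C_ER
            w = (
                arch.kappa_P
                * (r**2 + 2 * e * arch.C_EA * r)
                / (1 + receptor.kappa_R_bar + e) ** 2
            )
            assert float(bound_probability(E, arch, receptor)) == pytest.approx(
                w / (1 + w), rel=1e-12
            )
            # occupancy never exceeds the independent-sites (omega=1) case
            indep = PromoterArchitecture(
                n_ere=2, C_ER=0.1, C_EA=10.0, C_T=1.0, kappa_P=0.1, omega=1.0
            )
            assert float(bound_probability(E, arch, receptor)) <= float(
                bound_probability(E, indep, receptor)
            )
        # the saturating normalization anchor vanishes and is refused
        with pytest.raises(ValueError, match="anchor vanishes"):
            multi_ere_activity(20.0, arch, receptor)

    def test_cooperativity_steepens_dose_response(self, receptor):
        base = dict(n_ere=5, C_ER=0.1, C_EA=10.0, C_T=1.0, kappa_P=0.1)
        h1 = effective_hill_coefficient(
            PromoterArchitecture(omega=1.0, **base), receptor
        )
        h3 = effective_hill_coefficient(
            PromoterArchitecture(omega=3.0, **base), receptor
        )
        assert h3 > h1


class TestPredictedFluorescence:
    def test_mutated_control_is_constant(self, receptor):
        arch = PromoterArchitecture(n_ere=0, C_T=2.0, kappa_P=0.05, k_T=131.0)
        i = np.asarray(predicted_fluorescence(DOSES, arch, receptor))
        const = 131.0 * 0.1 / 1.1
        np.testing.assert_allclose(i, const, rtol=1e-12)

    def test_saturated_control_reaches_kT(self, receptor):
        arch = PromoterArchitecture(n_ere=0, C_T=1e12, kappa_P=1.0, k_T=131.0)
        assert float(predicted_fluorescence(0.0, arch, receptor)) == pytest.approx(
            131.0, rel=1e-9
        )

    def test_enhancer_and_control_cross_exactly_once(self, receptor):
        # ERE+enhancer starts below its mutated-ERE control (repression by
        # unliganded receptor) and overtakes it at high hormone.
        ere = PromoterArchitecture(
            n_ere=1, C_ER=0.1, C_EA=13.0, C_T=2.0, kappa_P=0.03, k_T=131.0
        )
        ctrl = PromoterArchitecture(
            n_ere=0, C_ER=0.1, C_EA=13.0, C_T=2.0, kappa_P=0.03, k_T=131.0
        )

        def diff(E):
            return float(
                predicted_fluorescence(E, ere, receptor)
                - predicted_fluorescence(E, ctrl, receptor)
            )

        assert diff(0.0) < 0 and diff(2000.0) > 0
        root = brentq(diff, 0.0, 2000.0)
        # single crossing: difference is negative below, positive above
        grid = np.linspace(0.0, 2000.0, 500)
        signs = np.sign([diff(g) for g in grid])
        assert np.sum(np.abs(np.diff(signs)) > 0) == 1
        # the crossing is the derepression point chi(E) = 1
        assert root == pytest.approx(65.0 * 1.0 * 0.9 / 12.0, rel=1e-6)

    def test_baseline_increases_with_CT(self, receptor):
        baselines = [
            float(
                predicted_fluorescence(
                    0.0,
                    PromoterArchitecture(
                        n_ere=1, C_ER=0.1, C_EA=10.0, C_T=ct, kappa_P=0.1, k_T=100.0
                    ),
                    receptor,
                )
            )
            for ct in np.geomspace(0.05, 20.0, 12)
        ]
        assert np.all(np.diff(baselines) > 0)


class TestConditionalLigandOccupancy:
    def test_decoupling_limit_equals_free_receptor(self, receptor):
        arch = PromoterArchitecture(n_ere=1, C_ER=0.1, C_EA=10.0, kappa_P=1e-12)
        p_act, _ = receptor_probabilities(20.0, receptor)
        assert float(
            conditional_ligand_occupancy(20.0, arch, receptor)
        ) == pytest.approx(p_act, rel=1e-9)

    def test_zero_without_ligand(self, receptor):
        arch = PromoterArchitecture(n_ere=1, C_ER=0.1, C_EA=10.0, kappa_P=0.1)
        assert float(conditional_ligand_occupancy(0.0, arch, receptor)) == 0.0

    def test_enhancer_boosts_effective_ligand_affinity(self, receptor):
        occ = [
            float(
                conditional_ligand_occupancy(
                    20.0,
                    PromoterArchitecture(
                        n_ere=1, C_ER=0.1, C_EA=10.0, C_T=ct, kappa_P=0.1
                    ),
                    receptor,
                )
            )
            for ct in np.geomspace(0.05, 20.0, 10)
        ]
        assert np.all(np.diff(occ) > 0)


class TestSponge:
    def test_null_sponge_is_identity(self, ere_arch, receptor):
        base = np.asarray(multi_ere_activity(DOSES, ere_arch, receptor))
        sponged = np.asarray(
            sponge_activity(DOSES, ere_arch, receptor, SpongeSpec(0.0, "corepressor"))
        )
        np.testing.assert_array_equal(base, sponged)

    def test_infinite_sponge_derepresses_to_neutral_level(self, ere_arch, receptor):
        neutral = float(multi_ere_activity(0.0, ere_arch, ReceptorParams(0.0, 65.0)))
        huge = float(
            sponge_activity(0.0, ere_arch, receptor, SpongeSpec(1e9, "corepressor"))
        )
        assert huge == pytest.approx(neutral, rel=1e-6)

    def test_baseline_monotone_in_sponge_weight(self, ere_arch, receptor):
        weights = np.geomspace(1e-2, 1e4, 12)
        baselines = [
            float(sponge_activity(0.0, ere_arch, receptor, SpongeSpec(s, "corepressor")))
            for s in weights
        ]
        assert np.all(np.diff(baselines) > 0)

    def test_ligand_sponge_shifts_response_right(self, ere_arch, receptor):
        plain = float(multi_ere_activity(20.0, ere_arch, receptor))
        sponged = float(
            sponge_activity(20.0, ere_arch, receptor, SpongeSpec(5.0, "ligand"))
        )
        assert sponged < plain


class TestResponseFeatures:
    def test_arithmetic_example(self):
        f = response_features(
            DoseResponseProfile((0.0, 20.0, 200.0, 2000.0), (0.0, 1.0, 2.0, 3.0)),
            pseudocount=0.0,
        )
        assert f.delta_ratio == pytest.approx(2.0)
        assert f.fold_change == np.inf  # zero baseline with eps = 0

    def test_flat_gene(self):
        f = response_features(
            DoseResponseProfile((0.0, 20.0, 200.0, 2000.0), (1.0, 1.0, 1.0, 1.0))
        )
        assert f.delta_ratio == pytest.approx(0.0)
        assert f.fold_change == pytest.approx(1.0)

    def test_wrong_grid_rejected(self):
        with pytest.raises(ValueError, match="dose grid"):
            response_features(
                DoseResponseProfile((0.0, 10.0, 100.0, 1000.0), (0.0, 1.0, 2.0, 3.0))
            )

    def test_silencer_has_larger_fold_and_delta_than_enhancer(self, receptor):
        feats = {}
        for name, ct in (("silencer", 0.1), ("enhancer", 5.0)):
            arch = PromoterArchitecture(
                n_ere=1, C_ER=0.1, C_EA=10.0, C_T=ct, kappa_P=0.1
            )
            vals = tuple(np.asarray(multi_ere_activity(DOSES, arch, receptor)))
            feats[name] = response_features(
                DoseResponseProfile(tuple(DOSES), vals)
            )
        assert feats["silencer"].fold_change > feats["enhancer"].fold_change
        assert feats["silencer"].delta_ratio > feats["enhancer"].delta_ratio


class TestThreshold:
    def test_half_activation_dose_decreases_with_CT(self, receptor):
        doses = [
            half_activation_dose(
                PromoterArchitecture(n_ere=1, C_ER=0.1, C_EA=10.0, C_T=ct, kappa_P=0.1),
                receptor,
            )
            for ct in np.geomspace(0.05, 20.0, 10)
        ]
        assert np.all(np.diff(doses) < 0)
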