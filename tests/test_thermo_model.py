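"""Occupancy model: state enumeration, closed form, and response curves."""

import math

import numpy as np
import pytest

import promtune as pt
from conftest import brute_force_p_sigma, random_params

OFF = pt.InducerCondition({})


class TestActiveFraction:
    def test_activator_zero_ligand_is_inactive(self, activator):
        assert pt.active_fraction(activator, OFF) == 0.0

    def test_repressor_zero_ligand_is_fully_active(self, repressor):
        assert pt.active_fraction(repressor, OFF) == 1.0

    @pytest.mark.parametrize("n", [0.5, 1.0, 2.0, 4.0])
    def test_half_maximal_at_half_conc(self, n):
        reg = pt.RegulatorSpec("X", "activator", 10.0, 0.5, "lig", hill_n=n)
        half = pt.InducerCondition({"lig": 0.5})
        assert pt.active_fraction(reg, half) == pytest.approx(0.5)

    def test_negative_concentration_rejected(self):
        with pytest.raises(pt.ModelError):
            pt.InducerCondition({"lig": -1.0})


class TestEnumerateStates:
    def test_no_regulators_two_states(self):
        p = pt.ThermoParams(site_energies=pt.SiteEnergies(0, 0))
        states = pt.enumerate_states(p, OFF)
        assert len(states) == 2
        occ = {s.occupants for s in states}
        assert occ == {frozenset(), frozenset({"sigma"})}

    def test_one_activator_one_repressor_six_states(self, hybrid_params):
        states = pt.enumerate_states(hybrid_params, OFF)
        assert len(states) == 6

    def test_one_activator_two_repressors_ten_states(self, activator, repressor):
        p = pt.ThermoParams(
            site_energies=pt.SiteEnergies(0, 0),
            regulators=(activator, repressor,
                        pt.make_repressor(name="TetR", ligand="aTc",
                                          half_conc=10.0)),
        )
        assert len(pt.enumerate_states(p, OFF)) == 10

    def test_no_state_mixes_sigma_and_repressor(self, hybrid_params):
        for s in pt.enumerate_states(hybrid_params, OFF):
            assert not ({"sigma", "LacI"} <= s.occupants)

    def test_two_activators_unsupported(self, activator):
        with pytest.raises(pt.ModelError):
            pt.ThermoParams(
                site_energies=pt.SiteEnergies(0, 0),
                regulators=(activator, pt.make_activator(name="LasR",
                                                         ligand="3O-C12-HSL")),
            )

    def test_state_probabilities_normalize(self, hybrid_params, induced):
        states = pt.enumerate_states(hybrid_params, induced)
        total = sum(s.weight for s in states)
        assert sum(s.weight / total for s in states) == pytest.approx(1.0)


class TestPSigmaBound:
    def test_zero_keq_means_no_binding(self):
        # dG −10 huge makes K_eq numerically zero
        p = pt.ThermoParams(site_energies=pt.SiteEnergies(1e4, 0))
        assert pt.p_sigma_bound(p, OFF) == 0.0

    def test_no_regulators_unit_keq_gives_half(self):
        p = pt.ThermoParams(site_energies=pt.SiteEnergies(0, 0))
        assert pt.p_sigma_bound(p, OFF) == pytest.approx(0.5)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            params, cond = random_params(rng)
            closed = pt.p_sigma_bound(params, cond)
            assert abs(closed - brute_force_p_sigma(params, cond)) < 1e-12
            assert 0.0 <= closed <= 1.0


class TestTranscriptionRate:
    def test_zero_keq_zero_background_is_silent(self):
        p = pt.ThermoParams(site_energies=pt.SiteEnergies(1e4, 0), background=0.0)
        assert pt.transcription_rate(p, OFF) == 0.0

    def test_saturates_at_alpha_plus_background(self):
        p = pt.ThermoParams(site_energies=pt.SiteEnergies(-30, -30),
                            alpha=1e5, background=10.0)
        assert pt.transcription_rate(p, OFF) == pytest.approx(1e5 + 10.0)

    def test_rate_never_below_background(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            params, cond = random_params(rng)
            assert pt.transcription_rate(params, cond) >= params.background


class TestFoldChangeAndDynamicRange:
    def test_identical_conditions(self, activated_params, uninduced):
        assert pt.fold_change(activated_params, uninduced, uninduced) == 1.0
        assert pt.dynamic_range(activated_params, uninduced, uninduced) == 0.0

    def test_activation_gives_fold_change_above_one(
        self, activated_params, uninduced, induced
    ):
        assert pt.fold_change(activated_params, uninduced, induced) > 1.0

    def test_fold_change_approaches_one_at_saturating_keq(
        self, activated_params, uninduced, induced
    ):
        import dataclasses

        p = activated_params.with_ln_keq(30.0)
        assert pt.fold_change(p, uninduced, induced) == pytest.approx(1.0, abs=1e-6)

    def test_zero_rate_off_raises(self, uninduced, induced, activator):
        p = pt.ThermoParams(site_energies=pt.SiteEnergies(1e4, 0),
                            background=0.0, regulators=(activator,))
        with pytest.raises(pt.ModelError):
            pt.fold_change(p, uninduced, induced)

    def test_zero_keq_zero_dynamic_range(self, uninduced, induced, activator):
        p = pt.ThermoParams(site_energies=pt.SiteEnergies(1e4, 0),
                            regulators=(activator,))
        assert pt.dynamic_range(p, uninduced, induced) == 0.0


class TestMonotonicity:
    """Rate is monotone in K_eq, in activator activity, and against repression."""

    def test_rate_nondecreasing_in_keq(self, activated_params, induced):
        grid = np.linspace(-12, 12, 97)
        rates = [
            pt.transcription_rate(activated_params.with_ln_keq(x), induced)
            for x in grid
        ]
        assert np.all(np.diff(rates) >= -1e-12)

    def test_rate_nondecreasing_in_activator_ligand(self, activated_params):
        concs = np.linspace(0, 10, 50)
        rates = [
            pt.transcription_rate(
                activated_params, pt.InducerCondition({"arabinose": float(c)})
            )
            for c in concs
        ]
        assert np.all(np.diff(rates) >= -1e-12)

    def test_rate_nonincreasing_in_repressor_activity(self, hybrid_params):
        # lowering IPTG raises the repressor's active fraction
        iptg = np.linspace(0, 2.0, 40)
        rates = [
            pt.transcription_rate(
                hybrid_params,
                pt.InducerCondition({"arabinose": 5.0, "IPTG": float(c)}),
            )
            for c in iptg
        ]
        assert np.all(np.diff(rates) >= -1e-12)  # more IPTG, less repression

    def test_two_repressors_compound(self, activator):
        rep1 = pt.make_repressor()
        rep2 = pt.make_repressor(name="TetR", ligand="aTc", half_conc=10.0,
                                 binding_weight=500.0)
        both = pt.ThermoParams(site_energies=pt.SiteEnergies(1, 1),
                               regulators=(activator, rep1, rep2))
        only1 = pt.ThermoParams(site_energies=pt.SiteEnergies(1, 1),
                                regulators=(activator, rep1))
        only2 = pt.ThermoParams(site_energies=pt.SiteEnergies(1, 1),
                                regulators=(activator, rep2))
        cond = pt.InducerCondition({"arabinose": 5.0})
        r_both = pt.transcription_rate(both, cond)
        assert r_both <= pt.transcription_rate(only1, cond)
        assert r_both <= pt.transcription_rate(only2, cond)

    def test_regulator_relabeling_changes_nothing(self, activator):
        import dataclasses

        rep = pt.make_repressor()
        renamed = dataclasses.replace(rep, name="SomeOtherRepressor")
        cond = pt.InducerCondition({"arabinose": 1.0, "IPTG": 0.3})
        p1 = pt.ThermoParams(site_energies=pt.SiteEnergies(1, 2),
                             regulators=(activator, rep))
        p2 = pt.ThermoParams(site_energies=pt.SiteEnergies(1, 2),
                             regulators=(activator, renamed))
        assert pt.transcription_rate(p1, cond) == pt.transcription_rate(p2, cond)


class TestDoseResponse:
    def test_zero_point_equals_uninduced_rate(self, activated_params, uninduced):
        curve = pt.dose_response_curve(activated_params, "arabinose", [0.0])
        assert curve[0][1] == pt.transcription_rate(activated_params, uninduced)

    def test_monotone_for_activator_ligand(self, activated_params):
        concs = np.geomspace(1e-3, 50, 60)
        curve = pt.dose_response_curve(activated_params, "arabinose", concs)
        rates = [r for _, r in curve]
        assert np.all(np.diff(rates) >= -1e-12)

    def test_saturation_limit_matches_full_activity(self, activated_params):
        import dataclasses

        big = pt.dose_response_curve(activated_params, "arabinose", [1e9])[0][1]
        act = activated_params.activator
        # fully active activator: q_A = K_A exactly
        saturated = dataclasses.replace(
            act, half_conc=1e-30  # active_fraction -> 1 at any c > 0
        )
        p_sat = dataclasses.replace(activated_params, regulators=(saturated,))
        ref = pt.transcription_rate(p_sat, pt.InducerCondition({"arabinose": 1.0}))
        assert big == pytest.approx(ref, rel=1e-6)

    def test_unknown_ligand_rejected(self, activated_params):
        with pytest.raises(pt.ModelError):
            pt.dose_response_curve(activated_params, "xylose", [1.0])


class TestSweepKeq:
    def test_three_regime_picture(self, activated_params, uninduced, induced):
        grid = np.linspace(-25, 25, 241)
        df = pt.sweep_keq(activated_params, grid, uninduced, induced)
        assert list(df.columns) == ["ln_keq", "r_off", "r_on", "fold_change",
                                    "dynamic_range"]
        assert np.all(np.diff(df["r_off"]) >= -1e-9)
        assert np.all(np.diff(df["r_on"]) >= -1e-9)
        # single interior maximum of dynamic range
        dr = df["dynamic_range"].to_numpy()
        peak = int(np.argmax(dr))
        assert 0 < peak < len(dr) - 1
        assert np.all(np.diff(dr[: peak + 1]) >= -1e-9)
        assert np.all(np.diff(dr[peak:]) <= 1e-9)
        # fold change approaches 1 at both extremes (background > 0)
        assert df["fold_change"].iloc[0] == pytest.approx(1.0, abs=5e-2)
        assert df["fold_change"].iloc[-1] == pytest.approx(1.0, abs=5e-2)
        # low-K_eq promoters leak less than high-K_eq ones
        assert df["r_off"].iloc[0] < df["r_off"].iloc[-1]
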