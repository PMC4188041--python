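import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from oracle_utils import one_site_binding_complex
from rastriage.catalog import ValidationError
from rastriage.rascycle import (
    SPECIES,
    FoldChangeSet,
    SteadyStateResult,
    apply_fold_changes,
    build_reactions,
    compare_variants,
    format_reactions,
    load_params,
    simulate_variants,
    steady_state,
)
from rastriage.synth import gen_random_model_params

# Conservation vectors: each column of the stoichiometry matrix must leave
# the four totals unchanged.
_CONSERVED = {
    "ras": np.array([1, 1, 1, 1, 1, 0, 0, 0]),
    "gef": np.array([0, 0, 1, 0, 0, 1, 0, 0]),
    "gap": np.array([0, 0, 0, 1, 0, 0, 1, 0]),
    "eff": np.array([0, 0, 0, 0, 1, 0, 0, 1]),
}


def rel_diff(a: float, b: float) -> float:
    return abs(a - b) / max(abs(a), abs(b), 1.0)


class TestBuildReactions:
    def test_stoichiometry_shape_and_conservation(self, wt_params):
        system = build_reactions(wt_params)
        assert system.stoichiometry.shape == (8, 7)
        for name, vec in _CONSERVED.items():
            assert np.all(vec @ system.stoichiometry == 0), name

    def test_halving_volume_doubles_per_molecule_rates(self, wt_params):
        system = build_reactions(wt_params)
        halved = build_reactions(dataclasses.replace(wt_params, volume=wt_params.volume / 2))
        assert halved.kon_gef_pm == pytest.approx(2 * system.kon_gef_pm)
        assert halved.kon_gap_pm == pytest.approx(2 * system.kon_gap_pm)
        assert halved.kon_eff_pm == pytest.approx(2 * system.kon_eff_pm)

    def test_without_gef_the_exchange_channels_carry_no_flux(self, wt_params):
        system = build_reactions(dataclasses.replace(wt_params, gef_total=0.0))
        y0 = system.initial_state()
        fluxes = system.fluxes(y0)
        assert fluxes[0] == 0.0 and fluxes[1] == 0.0
        result = steady_state(system)
        assert result.abundances["RasD_GEF"] == pytest.approx(0.0, abs=1e-9)

    def test_negative_rate_rejected(self, wt_params):
        with pytest.raises(ValidationError):
            dataclasses.replace(wt_params, k_gap=-1.0)

    def test_reaction_export_lists_all_seven_channels(self, wt_params):
        text = format_reactions(build_reactions(wt_params))
        assert text.count("->") + text.count("<->") == 7 + 3  # '<->' also contains '->'


class TestSteadyState:
    def test_pure_binding_limit_matches_quadratic_closed_form(self, wt_params):
        """No deactivation and no GAP: all Ras ends GTP-loaded and the
        effector complex solves the one-site binding quadratic."""
        p = dataclasses.replace(
            wt_params, k_gap=0.0, k_gtp_hydr_intr=0.0, gap_total=0.0
        )
        system = build_reactions(p)
        result = steady_state(system)
        assert result.converged
        kd_molecules = p.koff_eff / system.kon_eff_pm
        expected = one_site_binding_complex(p.ras_total, p.eff_total, kd_molecules)
        assert rel_diff(result.ras_t_eff, expected) < 1e-6
        # all Ras is GTP-loaded (free, or in the effector complex)
        assert result.abundances["RasD"] == pytest.approx(0.0, abs=1e-6)

    def test_no_activation_path_gives_zero_complex(self, wt_params):
        p = dataclasses.replace(wt_params, gef_total=0.0, k_gdp_exch_intr=0.0)
        result = steady_state(build_reactions(p))
        assert result.converged
        assert result.ras_t_eff == pytest.approx(0.0, abs=1e-9)

    def test_conservation_at_steady_state_random_params(self, rng):
        for _ in range(10):
            p = gen_random_model_params(rng)
            system = build_reactions(p)
            result = steady_state(system)
            assert result.converged
            y = np.array([result.abundances[s] for s in SPECIES])
            for name, err in system.conservation_errors(y).items():
                total = getattr(p, f"{name}_total")
                assert err <= 1e-6 * max(total, 1.0), name

    def test_independent_of_initial_ras_partition(self, wt_params):
        system = build_reactions(wt_params)
        from_gdp = steady_state(system, system.initial_state(0.0))
        from_gtp = steady_state(system, system.initial_state(1.0))
        from_half = steady_state(system, system.initial_state(0.5))
        for other in (from_gtp, from_half):
            assert rel_diff(from_gdp.ras_t_eff, other.ras_t_eff) < 1e-6

    def test_polished_fixed_point_agrees_with_long_ode_integration(self, wt_params):
        system = build_reactions(wt_params)
        polished = steady_state(system)
        sol = solve_ivp(
            lambda _t, y: system.rhs(y),
            (0.0, 1e9),
            system.initial_state(),
            method="LSODA",
            rtol=1e-12,
            atol=1e-10,
        )
        ode_value = sol.y[4, -1]
        assert rel_diff(polished.ras_t_eff, ode_value) < 1e-6

    def test_monotone_in_gap_and_gef_catalysis(self, wt_params):
        readouts_gap = []
        for factor in (0.1, 1.0, 10.0):
            p = dataclasses.replace(wt_params, k_gap=wt_params.k_gap * factor)
            readouts_gap.append(steady_state(build_reactions(p)).ras_t_eff)
        assert readouts_gap[0] >= readouts_gap[1] >= readouts_gap[2]
        readouts_gef = []
        for factor in (0.1, 1.0, 10.0):
            p = dataclasses.replace(wt_params, k_gef=wt_params.k_gef * factor)
            readouts_gef.append(steady_state(build_reactions(p)).ras_t_eff)
        assert readouts_gef[0] <= readouts_gef[1] <= readouts_gef[2]


class TestFoldChanges:
    def test_all_ones_set_is_identity(self, wt_params):
        assert apply_fold_changes(wt_params, FoldChangeSet(name="WT")) == wt_params

    def test_gap_fold_change_scales_only_gap_catalysis(self, wt_params):
        mutant = apply_fold_changes(wt_params, FoldChangeSet(name="m", gap=0.1))
        assert mutant.k_gap == pytest.approx(0.1 * wt_params.k_gap)
        unchanged = {f.name for f in dataclasses.fields(wt_params)} - {"k_gap"}
        for name in unchanged:
            assert getattr(mutant, name) == getattr(wt_params, name)

    def test_kd_fold_change_acts_on_the_off_rate(self, wt_params):
        mutant = apply_fold_changes(wt_params, FoldChangeSet(name="m", kd_eff=2.0))
        assert mutant.koff_eff == pytest.approx(2.0 * wt_params.koff_eff)
        assert mutant.kon_eff == wt_params.kon_eff
        assert mutant.kd_eff == pytest.approx(2.0 * wt_params.kd_eff)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan")])
    def test_non_positive_fold_change_rejected(self, bad):
        with pytest.raises(ValidationError):
            FoldChangeSet(name="bad", gap=bad)


class TestCompareVariants:
    @staticmethod
    def result(value: float) -> SteadyStateResult:
        abundances = dict.fromkeys(SPECIES, 0.0)
        abundances["RasT_EFF"] = value
        return SteadyStateResult(abundances=abundances, converged=True, residual=0.0)

    def test_intermediate_outlier_and_boundary(self):
        report = compare_variants(
            self.result(100.0),
            self.result(500.0),
            {"mid": self.result(300.0), "out": self.result(600.0), "at_wt": self.result(100.0)},
        )
        assert bool(report.loc["mid", "intermediate"])
        assert not bool(report.loc["out", "intermediate"])
        assert bool(report.loc["at_wt", "intermediate"])  # closed interval
        assert int((~report["intermediate"]).sum()) == 1

    def test_unconverged_reference_rejected(self):
        bad = SteadyStateResult(dict.fromkeys(SPECIES, 0.0), converged=False, residual=1.0)
        with pytest.raises(ValidationError, match="converge"):
            compare_variants(self.result(1.0), bad, {})


class TestVariantSimulation:
    def test_default_config_variants_are_ordered(self, wt_params, default_variants):
        table = simulate_variants(wt_params, list(default_variants.values()))
        assert table["converged"].all()
        wt = table.loc["WT", "ras_t_eff"]
        comp = table.loc["compensatory", "ras_t_eff"]
        gap_loss = table.loc["gap_loss", "ras_t_eff"]
        onc = table.loc["oncogenic_reference", "ras_t_eff"]
        assert wt <= comp <= gap_loss <= onc
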