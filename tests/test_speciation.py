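import math

import numpy as np
import pytest

from phsolv.activity_ph import ActivityModel
from phsolv.errors import DomainError, InputError
from phsolv.model_registry import MediumRecipe
from phsolv.speciation import (
    ObservationFlag,
    SolubilityObservation,
    compute_pHmax,
    henderson_hasselbalch_logS,
    saturation_indices,
    select_solid_phases,
    simulate_logS_curve,
    solve_at_fixed_pcH,
    solve_equilibrium,
)

PKA = 9.52
PKSP_BHCL = 2.338
PS0 = 4.602


def bhcl_closed_form_S(c_b, c_cl, pcH):
    """Independent oracle: quadratic solution for the B/Cl toy system
    (no aggregates, activity off, BHCl the only solid)."""
    r = 1.0 + 10.0 ** (pcH - PKA)
    ksp = 10.0 ** (-PKSP_BHCL)
    d = c_cl - c_b
    bh = (-d + math.sqrt(d * d + 4 * r * ksp)) / (2 * r)
    return r * bh


class TestSolveAtFixedPcH:
    def test_half_ionization(self, model_no_agg, act_off):
        rec = MediumRecipe(c_b_total=1e-4, starting_material="free_base")
        st = solve_at_fixed_pcH(rec, model_no_agg, PKA, act_off)
        assert st.derived["B"] == pytest.approx(5e-5, rel=1e-8)
        assert st.derived["BH+"] == pytest.approx(5e-5, rel=1e-8)

    def test_two_decades_below_pka(self, model_no_agg, act_off):
        rec = MediumRecipe(c_b_total=1e-4, starting_material="free_base")
        st = solve_at_fixed_pcH(rec, model_no_agg, PKA - 2, act_off)
        assert st.derived["BH+"] / st.derived["B"] == pytest.approx(100.0, rel=1e-8)

    def test_set3_stock_trial_state_fully_dissolved(self, recipe_set3, model):
        # trial solve imposes no solids: total drug stays dissolved
        st = solve_at_fixed_pcH(recipe_set3, model, 5.0)
        assert st.solids == {}
        assert st.s_dissolved == pytest.approx(recipe_set3.c_b_total, rel=1e-9)

    def test_negative_total_rejected(self, model):
        with pytest.raises(InputError):
            rec = MediumRecipe(c_b_total=0.0, starting_material="free_base")
            solve_at_fixed_pcH(rec, model, 7.0)

    def test_mass_balances_reproduced(self, model, davies):
        rec = MediumRecipe.from_weighed_solid(0.057, 1.0, "salt_BHCl",
                                              background_NaH2PO4=0.14,
                                              c_strong_acid=0.049)
        for pcH in (3.0, 6.5, 10.0):
            st = solve_equilibrium(rec, model, pcH, davies)
            comp = {"B": ("B", 0), "P": ("P", 1), "Cl": ("Cl", 2)}
            from phsolv.model_registry import default_species, default_solids
            sp_by_name = {s.name: s for s in default_species(model)}
            so_by_name = {s.name: s for s in default_solids(model)}
            for key, total in st.totals.items():
                if total == 0:
                    continue
                attr = {"B": "n_b", "P": "n_p", "Cl": "n_cl"}[key]
                aq = sum(getattr(sp_by_name[n], attr) * c
                         for n, c in st.derived.items())
                solid = sum(getattr(so_by_name[n], attr) * x
                            for n, x in st.solids.items())
                assert abs(aq + solid - total) / total < 1e-10

    def test_charge_balance_with_slack(self, model, davies, recipe_set5):
        for pcH in (3.0, 7.0, 7.8):
            st = solve_equilibrium(recipe_set5, model, pcH, davies)
            c, z = st.ions()
            assert abs(st.charge_imbalance()) < 1e-10 * float(np.sum(c * np.abs(z)))


class TestSelectSolidPhases:
    def test_exact_saturation_boundary(self, model_no_agg, act_off):
        # choose totals so that [BH+][Cl-] == Ksp exactly at pcH 3
        c = 10.0 ** (-PKSP_BHCL / 2)
        frac = 1.0 + 10.0 ** (3.0 - PKA)  # tiny free-base correction
        rec = MediumRecipe(c_b_total=c * frac, c_cl_total=c, c_na_total=0.0,
                           starting_material="free_base")
        st = solve_at_fixed_pcH(rec, model_no_agg, 3.0, act_off)
        si = saturation_indices(st, model_no_agg)
        assert si["BHCl(s)"] == pytest.approx(0.0, abs=1e-6)
        out = select_solid_phases(st, model_no_agg)
        assert out.solids.get("BHCl(s)", 0.0) == pytest.approx(0.0, abs=1e-6)

    def test_undersaturated_returned_unchanged(self, model, act_off):
        rec = MediumRecipe(c_b_total=1e-6, c_cl_total=1e-6, c_na_total=0.0,
                           starting_material="free_base")
        st = solve_at_fixed_pcH(rec, model, 5.0, act_off)
        out = select_solid_phases(st, model)
        assert out.solids == {}
        assert all(v < 1e-6 for v in saturation_indices(out, model).values())

    def test_set5_like_selects_bhcl(self, recipe_set5, model_no_agg, act_off):
        st = solve_equilibrium(recipe_set5, model_no_agg, 3.0, act_off)
        assert st.solids_present == ("BHCl(s)",)
        S = bhcl_closed_form_S(recipe_set5.c_b_total, recipe_set5.c_cl_total, 3.0)
        assert st.s_dissolved == pytest.approx(S, rel=1e-8)

    def test_oracle_across_pch(self, model_no_agg, act_off):
        rec = MediumRecipe(c_b_total=0.05, c_cl_total=0.10, c_na_total=0.05,
                           starting_material="free_base")
        for pcH in (2.5, 3.5, 4.5, 5.5, 6.0):
            st = solve_equilibrium(rec, model_no_agg, pcH, act_off)
            assert st.solids_present == ("BHCl(s)",)
            S = bhcl_closed_form_S(rec.c_b_total, rec.c_cl_total, pcH)
            assert st.s_dissolved == pytest.approx(S, rel=1e-8)

    def test_present_solid_saturation_index_zero(self, recipe_set5, model, davies):
        st = solve_equilibrium(recipe_set5, model, 4.0, davies)
        si = saturation_indices(st, model)
        for name in st.solids_present:
            assert si[name] == pytest.approx(0.0, abs=1e-6)


class TestSimulateCurve:
    def test_set6_solid_switch_window(self, model, act_off):
        rec = MediumRecipe.from_weighed_solid(0.069, 1.0, "free_base",
                                              background_NaH2PO4=1.4,
                                              background_H3PO4=0.6)
        pts = simulate_logS_curve(rec, model, np.arange(2.5, 6.4, 0.05), act_off)
        controlling = [p.solids for p in pts]
        first = [s[0] for s in controlling if s]
        # dihydrogen phosphate controls first, then hydrogen phosphate
        assert first[0] == "BHH2PO4(s)"
        assert "BH2HPO4(s)" in {s for sol in controlling for s in sol}
        switch_pch = next(p.pcH for p in pts if "BH2HPO4(s)" in p.solids)
        assert 5.0 < switch_pch < 6.0
        # single switch: once the 2:1 salt appears the 1:1 salt never returns alone
        after = [p.solids for p in pts if p.pcH > switch_pch + 0.1]
        assert all("BHH2PO4(s)" not in s for s in after)

    def test_unreachable_ksp_all_subsaturated(self, model, act_off, recipe_set3):
        never = model.updated(pS0=-100.0, pKsp_BHCl=-100.0,
                              pKsp_BHH2PO4=-100.0, pKsp_BH2HPO4=-100.0)
        pts = simulate_logS_curve(recipe_set3, never, [3.0, 6.0, 9.0], act_off)
        assert all(p.subsaturated for p in pts)
        assert all(p.logS == pytest.approx(math.log10(recipe_set3.c_b_total))
                   for p in pts)

    def test_continuity_across_transition(self, model, act_off, recipe_set5):
        # fine grid through the salt -> base transition near pHmax
        pts = simulate_logS_curve(recipe_set5, model, np.arange(7.0, 8.0, 0.01),
                                  act_off)
        logS = np.array([p.logS for p in pts])
        diffs = np.abs(np.diff(logS))
        # steps stay bounded by the curve slope (|dlogS/dpH| ~ 1); no jump
        assert np.max(diffs) < 1.5 * 0.01
        # the step across the solid-solid switch is no outlier
        solids = [p.solids for p in pts]
        switch = next(i for i in range(1, len(solids))
                      if solids[i] != solids[i - 1] and "B(s)" in solids[i])
        assert diffs[switch - 1] <= np.max(diffs) + 1e-12
        assert ("BHCl(s)",) in set(solids) and ("B(s)",) in set(solids)

    def test_grid_must_ascend(self, model, recipe_set3):
        with pytest.raises(InputError):
            simulate_logS_curve(recipe_set3, model, [5.0, 4.0])

    def test_common_ion_monotonicity(self, model, act_off):
        s_prev = None
        for c_cl in (0.5, 1.0, 1.7, 2.5):
            rec = MediumRecipe(c_b_total=0.25, c_cl_total=c_cl, c_na_total=c_cl,
                               starting_material="free_base")
            st = solve_equilibrium(rec, model, 3.0, act_off)
            assert st.solids_present == ("BHCl(s)",)
            if s_prev is not None:
                assert st.s_dissolved <= s_prev + 1e-12
            s_prev = st.s_dissolved


class TestHendersonHasselbalch:
    def test_high_pch_limit(self):
        assert henderson_hasselbalch_logS(14.0, PS0, PKA) == pytest.approx(-4.602, abs=1e-4)

    def test_at_pka(self):
        assert henderson_hasselbalch_logS(PKA, PS0, PKA) == pytest.approx(
            -PS0 + math.log10(2), abs=1e-12)

    def test_two_below_pka(self):
        # -4.602 + log10(101)
        assert henderson_hasselbalch_logS(7.52, PS0, PKA) == pytest.approx(-2.598, abs=5e-4)

    def test_model_matches_hh_when_base_controls(self, model, act_off, recipe_set3):
        plain = model.without_aggregates()
        grid = np.arange(8.0, 12.0, 0.25)
        pts = simulate_logS_curve(recipe_set3, plain, grid, act_off)
        for p in pts:
            if p.solids == ("B(s)",):
                hh = henderson_hasselbalch_logS(p.pcH, PS0, PKA)
                assert abs(p.logS - hh) < 1e-9


class TestPHmax:
    def test_bhcl_base_closed_form_high_chloride(self, model):
        # pKa + log10(S0 * [Cl-] / Ksp) at [Cl-]=1.70
        got = compute_pHmax(model, "B(s)", "BHCl(s)", {"Cl-": 1.70})
        closed = PKA + math.log10(10 ** -PS0 * 1.70 / 10 ** -PKSP_BHCL)
        assert got == pytest.approx(closed, abs=1e-6)
        assert got == pytest.approx(7.49, abs=5e-3)
        assert got <= 7.5

    def test_common_ion_shift_one_decade(self, model):
        # ten-fold less chloride shifts pHmax one unit toward the acid side
        hi = compute_pHmax(model, "B(s)", "BHCl(s)", {"Cl-": 1.70})
        lo = compute_pHmax(model, "B(s)", "BHCl(s)", {"Cl-": 0.17})
        assert hi - lo == pytest.approx(1.0, abs=1e-6)
        closed = PKA + math.log10(10 ** -PS0 * 0.17 / 10 ** -PKSP_BHCL)
        assert lo == pytest.approx(closed, abs=1e-6)

    def test_order_invariant(self, model):
        a = compute_pHmax(model, "B(s)", "BHCl(s)", {"Cl-": 1.70})
        b = compute_pHmax(model, "BHCl(s)", "B(s)", {"Cl-": 1.70})
        assert a == pytest.approx(b, abs=1e-8)

    def test_identical_solids_rejected(self, model):
        with pytest.raises(DomainError):
            compute_pHmax(model, "BHCl(s)", "BHCl(s)", {"Cl-": 1.70})

    def test_phosphate_pair(self, model):
        got = compute_pHmax(model, "BHH2PO4(s)", "BH2HPO4(s)", {"H2PO4-": 1.7})
        assert 5.0 < got < 6.5


class TestObservation:
    def test_weight_flags(self):
        ok = SolubilityObservation(7.0, -3.0)
        assert ok.weight == 1.0
        for flag in (ObservationFlag.OUTLIER, ObservationFlag.DEGRADED,
                     ObservationFlag.SUBSATURATED):
            assert SolubilityObservation(7.0, -3.0, flag=flag).weight == 0.0

    def test_sigma_positive(self):
        with pytest.raises(InputError):
            SolubilityObservation(7.0, -3.0, sigma=0.0)
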