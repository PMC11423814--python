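"""Mechanotransduction steady states: mass conservation, closed-form vs
ODE-integration oracles, treatment directions and mutations."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from mechanoclock.mechano import (MechanoParams, TreatmentCondition,
                                  apply_mutation, factin_baseline,
                                  factin_cytochalasin, factin_jasplakinolide,
                                  factin_latrunculin, fak_contact_modulation,
                                  steady_state_network)
from mechanoclock.mechano import _actin_rates, _upstream

STIFFNESS_SWEEP = [0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 1e4, 1e7]


@pytest.fixture(scope="module")
def rates(mech):
    up = _upstream(mech, TreatmentCondition())
    return _actin_rates(mech, up["mdia"], up["cofilin"])


# ------------------------------------------------------------- actin variants

def test_baseline_mass_conservation(mech, rates):
    F = factin_baseline(mech, rates)
    G = mech.Actin_tot - F
    assert abs((F + G) - mech.Actin_tot) / mech.Actin_tot < 1e-10
    assert 0 < F < mech.Actin_tot


def test_baseline_matches_bisection_oracle(mech, rates):
    """Closed-form F equals the root of the polymerization balance."""
    k_a, k_d = rates

    def balance(F):
        return k_a * (mech.Actin_tot - F) - k_d * F

    F_root = bisect(balance, 0.0, mech.Actin_tot, xtol=1e-14)
    assert abs(factin_baseline(mech, rates) - F_root) < 1e-12


def test_baseline_zero_polymerization_limit(mech):
    F = factin_baseline(mech, rates=(1e-12, 1.0))
    assert F < 1e-10


def test_baseline_degenerate_rates_error(mech):
    with pytest.raises(ValueError, match="degenerate"):
        factin_baseline(mech, rates=(0.0, 0.0))


@pytest.mark.parametrize("drug,conc", [("cytochalasin", 0.5),
                                       ("latrunculin", 0.3),
                                       ("jasplakinolide", 1.0)])
def test_drug_steady_state_matches_ode_oracle(mech, rates, drug, conc):
    """Each closed form equals the long-time limit of the underlying ODEs."""
    k_a, k_d = rates
    A = mech.Actin_tot
    if drug == "cytochalasin":
        F_cl, G_cl = factin_cytochalasin(mech, conc, rates)

        def odes(t, y):
            F, G, CG2, FC = y
            dCG2 = mech.k_dimC * conc * G - mech.k_undim * CG2
            dFC = mech.k_capC * conc * F - mech.k_uncap * FC
            dF = k_a * G - k_d * F - dFC
            dG = -k_a * G + k_d * F - 2 * dCG2
            return [dF, dG, dCG2, dFC]

        y0 = [A * k_a / (k_a + k_d), A * k_d / (k_a + k_d), 0, 0]
        sol = solve_ivp(odes, (0, 5000), y0, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        assert abs(sol.y[0, -1] - F_cl) / max(F_cl, 1e-12) < 1e-4
        assert abs(sol.y[1, -1] - G_cl) / max(G_cl, 1e-12) < 1e-4
        total = sol.y[0, -1] + sol.y[1, -1] + 2 * sol.y[2, -1] + sol.y[3, -1]
        assert abs(total - A) / A < 1e-8
    elif drug == "latrunculin":
        F_cl, Gtot_cl = factin_latrunculin(mech, conc, rates)

        def odes(t, y):
            F, G, GL = y
            dGL = mech.k_onL * conc * G - mech.k_offL * GL
            dF = k_a * G - k_d * F
            dG = -dF - dGL
            return [dF, dG, dGL]

        sol = solve_ivp(odes, (0, 5000), [A * 0.5, A * 0.5, 0],
                        method="LSODA", rtol=1e-10, atol=1e-12)
        assert abs(sol.y[0, -1] - F_cl) / max(F_cl, 1e-12) < 1e-4
        assert abs(sol.y[1, -1] + sol.y[2, -1] - Gtot_cl) / Gtot_cl < 1e-4
    else:
        F_cl = factin_jasplakinolide(mech, conc, rates)
        s = conc / (mech.K2_jas + conc)
        ka2 = k_a * (1 + mech.e_jas_p * s)
        kd2 = k_d * (1 - mech.e_jas_d * s)

        def odes(t, y):
            return [ka2 * (A - y[0]) - kd2 * y[0]]

        sol = solve_ivp(odes, (0, 5000), [A * 0.5], method="LSODA",
                        rtol=1e-10, atol=1e-12)
        assert abs(sol.y[0, -1] - F_cl) / F_cl < 1e-4


def test_cytochalasin_zero_reduces_to_baseline(mech, rates):
    F0 = factin_baseline(mech, rates)
    F, G = factin_cytochalasin(mech, 0.0, rates)
    assert F == pytest.approx(F0, rel=1e-12)
    assert G == pytest.approx(mech.Actin_tot - F0, rel=1e-12)


def test_latrunculin_limits(mech, rates):
    F0 = factin_baseline(mech, rates)
    F, Gtot = factin_latrunculin(mech, 0.0, rates)
    assert F == pytest.approx(F0, rel=1e-12)
    assert Gtot == pytest.approx(mech.Actin_tot - F0, rel=1e-12)
    F_inf, Gtot_inf = factin_latrunculin(mech, 1e7, rates)
    assert F_inf < 1e-4
    assert Gtot_inf == pytest.approx(mech.Actin_tot, rel=1e-3)


def test_jasplakinolide_monotone(mech, rates):
    J = np.linspace(0, 10, 400)
    F = np.array([factin_jasplakinolide(mech, j, rates) for j in J])
    assert F[0] == pytest.approx(factin_baseline(mech, rates), rel=1e-12)
    assert np.all(np.diff(F) >= -1e-12)


# ------------------------------------------------------------- full network

def test_stiffness_monotonicity(mech):
    """F-actin, E_cyto, YAP/TAZ and MRTF N/C all non-decreasing in stiffness."""
    states = [steady_state_network(mech, TreatmentCondition(substrate_stiffness=E))
              for E in STIFFNESS_SWEEP]
    for attr in ("F_actin", "E_cyto", "yap_nc", "mrtf_nc"):
        v = np.array([getattr(s, attr) for s in states])
        assert np.all(np.diff(v) >= -1e-12), f"{attr} not monotone"


def test_network_steady_state_matches_time_integration(mech):
    """Algebraic cascade equals the long-time limit of the full ODE system."""
    cond = TreatmentCondition(substrate_stiffness=5.0)
    st = steady_state_network(mech, cond)
    p = mech
    up = _upstream(p, cond)
    k_a, k_d = _actin_rates(p, up["mdia"], up["cofilin"])
    area_scale = 1.0
    w = cond.substrate_stiffness**p.n_stiff_exp / (
        cond.substrate_stiffness**p.n_stiff_exp + p.C_E**p.n_stiff_exp)
    fak_act = (p.k_f0 + p.k_sf * w) * area_scale

    def odes(t, y):
        (fak, rhoa, rock, mdia, limk, cof, myo, F, lam, npc,
         yc, yp, yn, mc, mn) = y
        d = np.empty(15)
        d[0] = fak_act * (p.FAK_tot - fak) - p.k_df * fak
        a_rho = p.k_fkrho * (p.gamma_fak * fak) ** p.n_fak_exp
        d[1] = a_rho * (p.RhoA_tot - rhoa) - p.k_drho * rhoa
        d[2] = p.k_rrho * rhoa * (p.ROCK_tot - rock) - p.k_drock * rock
        d[3] = p.k_mrho * rhoa * (p.mDia_tot - mdia) - p.k_dmdia * mdia
        d[4] = p.k_lk * rock * (p.LIMK_tot - limk) - p.k_dlimk * limk
        d[5] = p.k_cof_on * (p.Cof_tot - cof) - p.k_lc * limk * cof
        d[6] = p.k_mr * rock * (p.Myo_tot - myo) - p.k_dmyo * myo
        ka_t = p.A_poly * (p.k_poly0 + p.k_mdia * mdia)
        kd_t = p.k_dep + p.k_sev * cof
        d[7] = ka_t * (p.Actin_tot - F) - kd_t * F
        E_cyto = p.E_c0 + p.E_cmax * F**p.n_EF_exp / (p.K_EF**p.n_EF_exp + F**p.n_EF_exp)
        r_deph = p.k_lam_deph * E_cyto**p.n_lam_exp / (
            p.K_lamE**p.n_lam_exp + E_cyto**p.n_lam_exp)
        d[8] = r_deph * (p.LamA_tot - lam) - p.k_lam_p * lam
        a_npc = p.k_npc_open * lam * F * myo
        d[9] = a_npc * (p.NPC_tot - npc) - p.k_npc_close * npc
        k_deph = p.k_ydeph0 + p.k_ydeph_F * F * myo
        k_in = p.k_yin0 + p.k_yin_npc * npc
        # transport rates act on concentrations; nuclear pool carries the
        # volume ratio so that total amount yc + yp + nu*yn is conserved
        d[10] = -p.k_yphos * yc + k_deph * yp - k_in * yc + p.k_yout * yn
        d[11] = p.k_yphos * yc - k_deph * yp
        d[12] = (k_in * yc - p.k_yout * yn) / p.nuc_vol_ratio
        G = p.Actin_tot - F
        b_on = (G / p.K_gm) ** p.n_gm_exp
        k_min = p.k_min0 + p.k_min_npc * npc
        # free cytosolic MRTF with G-actin binding at fast equilibrium
        # (bound pool = b_on * mc slaved to the free pool)
        d[13] = (-k_min * mc + p.k_mout * mn) / (1.0 + b_on)
        d[14] = (k_min * mc - p.k_mout * mn) / p.nuc_vol_ratio
        return d

    y0 = np.array([0.5, 0.3, 0.3, 0.3, 0.3, 0.5, 0.5, 0.4, 0.3, 0.3,
                   p.Y_tot / 3, p.Y_tot / 3, p.Y_tot / 3,
                   p.M_tot / 2, p.M_tot / 4])
    sol = solve_ivp(odes, (0, 20000), y0, method="LSODA", rtol=1e-11,
                    atol=1e-13)
    yss = sol.y[:, -1]
    expect = [st.fak_p, st.rhoa, st.rock, st.mdia, st.limk, st.cofilin,
              st.myosin, st.F_actin, st.lamin_a, st.npc]
    for val, ref in zip(yss[:10], expect):
        assert abs(val - ref) / max(abs(ref), 1e-9) < 1e-4
    # YAP and MRTF partitioning ratios
    yc, yp, yn = yss[10:13]
    assert abs(yn / yc - st.yap_nuc / st.yap_cyto) < 1e-4 * (st.yap_nuc / st.yap_cyto)
    mc, mn = yss[13], yss[14]
    assert abs(mn / mc - st.mrtf_nuc / st.mrtf_cyto_free) < \
        1e-4 * (st.mrtf_nuc / st.mrtf_cyto_free)


def test_identity_condition_defaults(mech):
    a = steady_state_network(mech, TreatmentCondition())
    b = steady_state_network(mech, TreatmentCondition(
        cytochalasin_d=0.0, latrunculin=0.0, jasplakinolide=0.0,
        y27632=0.0, blebbistatin=0.0, mutation="none", cell_density="low"))
    assert a == b


def test_cytochalasin_unique_opposite_mover(mech):
    """Cytochalasin D lowers nuclear YAP/TAZ but raises nuclear MRTF; every
    other packaged treatment moves both in the same (downward) direction."""
    ctrl = steady_state_network(mech, TreatmentCondition())
    treatments = {
        "cytochalasin_d": TreatmentCondition(cytochalasin_d=0.5),
        "latrunculin": TreatmentCondition(latrunculin=0.3),
        "y27632": TreatmentCondition(y27632=5.0),
        "blebbistatin": TreatmentCondition(blebbistatin=10.0),
        "density": TreatmentCondition(cell_density="high"),
        "area900": TreatmentCondition(contact_area=900.0),
        "area1600": TreatmentCondition(contact_area=1600.0),
    }
    opposite = []
    for name, cond in treatments.items():
        s = steady_state_network(mech, cond)
        dy = s.yap_nuc_total - ctrl.yap_nuc_total
        dm = s.mrtf_nuc - ctrl.mrtf_nuc
        assert dy < 0, f"{name} should lower nuclear YAP/TAZ"
        if dy * dm < 0:
            opposite.append(name)
        else:
            assert dm < 0, f"{name} should lower nuclear MRTF"
    assert opposite == ["cytochalasin_d"]


def test_cytochalasin_dose_response(mech):
    prev_F, prev_G = np.inf, np.inf
    ctrl = steady_state_network(mech, TreatmentCondition())
    for C in (0.25, 0.5, 1.0, 2.0):
        s = steady_state_network(mech, TreatmentCondition(cytochalasin_d=C))
        assert s.F_actin < prev_F and s.G_actin < prev_G
        prev_F, prev_G = s.F_actin, s.G_actin
        assert s.yap_nuc_total < ctrl.yap_nuc_total
        assert s.mrtf_nuc > ctrl.mrtf_nuc


def test_jasplakinolide_raises_both_nuclear_pools(mech):
    ctrl = steady_state_network(mech, TreatmentCondition())
    s = steady_state_network(mech, TreatmentCondition(jasplakinolide=1.0))
    assert s.F_actin > ctrl.F_actin
    assert s.yap_nuc_total > ctrl.yap_nuc_total
    assert s.mrtf_nuc > ctrl.mrtf_nuc


# -------------------------------------------------------------- contact area

def test_contact_area_identity_and_direction(mech):
    assert fak_contact_modulation(mech, mech.A_0) == pytest.approx(1.0)
    assert fak_contact_modulation(mech, 900.0) < fak_contact_modulation(mech, 1600.0) < 1.0
    s900 = steady_state_network(mech, TreatmentCondition(contact_area=900.0))
    s1600 = steady_state_network(mech, TreatmentCondition(contact_area=1600.0))
    assert s900.fak_p < s1600.fak_p


def test_contact_area_requires_a0(mech):
    p = dataclasses.replace(mech, A_0=None)
    with pytest.raises(ValueError, match="A_0"):
        fak_contact_modulation(p, 900.0)


# ----------------------------------------------------------------- mutations

def test_mutation_none_is_identity(mech):
    assert apply_mutation(mech, "none") == mech


def test_mutation_unknown_label(mech):
    with pytest.raises(ValueError, match="unknown mutation"):
        apply_mutation(mech, "YAP_4SA")


def test_yap5sa_raises_yap_only(mech):
    cond = TreatmentCondition(substrate_stiffness=30.0)
    wt = steady_state_network(mech, cond)
    mut = steady_state_network(mech, TreatmentCondition(
        substrate_stiffness=30.0, mutation="YAP_5SA"))
    assert mut.yap_nuc_total > 1.5 * wt.yap_nuc_total
    assert mut.mrtf_nuc == pytest.approx(wt.mrtf_nuc, rel=1e-12)
    p = apply_mutation(mech, "YAP_5SA")
    assert p.Y5SA_tot == mech.Y_tot  # twice the overall YAP/TAZ per cell


def test_lmna_raises_both(mech):
    cond = TreatmentCondition(substrate_stiffness=30.0)
    wt = steady_state_network(mech, cond)
    mut = steady_state_network(mech, TreatmentCondition(
        substrate_stiffness=30.0, mutation="LMNA"))
    assert mut.yap_nuc_total > wt.yap_nuc_total
    assert mut.mrtf_nuc > wt.mrtf_nuc
    p = apply_mutation(mech, "LMNA")
    assert p.k_lam_p == 0.0
    assert p.k_npc_open == pytest.approx(2 * mech.k_npc_open)


# ----------------------------------------------------------------- validation

def test_condition_validation_errors():
    with pytest.raises(ValueError):
        TreatmentCondition(substrate_stiffness=-1.0).validate()
    with pytest.raises(ValueError):
        TreatmentCondition(cytochalasin_d=-0.1).validate()
    with pytest.raises(ValueError, match="one actin-targeting drug"):
        TreatmentCondition(cytochalasin_d=0.5, jasplakinolide=0.5).validate()
    with pytest.raises(ValueError, match="density"):
        TreatmentCondition(cell_density="medium").validate()
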