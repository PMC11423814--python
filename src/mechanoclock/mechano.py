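"""Steady-state YAP/TAZ-MRTF mechanotransduction network.

The network maps a mechanical/pharmacological condition (substrate stiffness,
contact area, cell density, cytoskeletal inhibitors, mutations) to
steady-state concentrations of every species, in particular nuclear YAP/TAZ
and nuclear MRTF, which drive the circadian clock.

Signal flow (each stage at steady state, solved as an explicit cascade):

    stiffness --> FAK phosphorylation --> RhoA-GTP --> {ROCK, mDia}
    ROCK --> LIMK --| cofilin (F-actin severing), ROCK --> myosin
    mDia --> actin polymerization;  F-actin <-> G-actin (mass conserved)
    F-actin --> cytosolic stiffness E_cyto --> lamin A dephosphorylation
    lamin A + cytoskeletal tension --> NPC opening --> nuclear import
    F-actin * myosin --| YAP/TAZ phosphorylation --> nuclear YAP/TAZ
    G-actin --| free MRTF --> nuclear MRTF

Because the cascade has no feedback, the steady state is unique and is
computed algebraically stage by stage; drug treatments replace the actin
balance with the corresponding closed form (capping/dimerization for
cytochalasin D, G-actin sequestration for latrunculin, enhanced assembly for
jasplakinolide).  Concentrations are in normalized model units (protein
totals are 1 except where noted); stiffnesses in kPa, areas in um^2,
inhibitor concentrations in uM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

__all__ = [
    "MechanoParams",
    "TreatmentCondition",
    "MechanoState",
    "MUTATIONS",
    "steady_state_network",
    "factin_baseline",
    "factin_cytochalasin",
    "factin_latrunculin",
    "factin_jasplakinolide",
    "fak_contact_modulation",
    "apply_mutation",
]

MUTATIONS = ("none", "YAP_5SA", "LMNA")

GLASS_STIFFNESS_KPA = 1.0e7  # glass encoded as 10 GPa


@dataclass
class MechanoParams:
    """Rate constants and totals of the mechanotransduction network.

    All rates must be non-negative; exponent fields (names ending in ``_exp``)
    are held constant during population sampling.
    """

    # FAK module
    FAK_tot: float = 1.0
    k_f0: float = 0.015        # stiffness-independent FAK phosphorylation (1/h)
    k_sf: float = 0.25         # stiffness-dependent FAK phosphorylation (1/h)
    C_E: float = 10.0          # stiffness half-activation (kPa)
    n_stiff_exp: float = 0.5   # sub-linear stiffness sensing (exponent, constant)
    k_df: float = 0.12        # FAK dephosphorylation (1/h)
    A_0: float | None = 3000.0  # control cell-substrate contact area (um^2); assumption
    K_A: float = 1800.0        # contact-area half-saturation (um^2)
    density_fak_factor: float = 0.55   # FAK activation scale at high cell density
    density_lats_factor: float = 2.5   # LATS-driven YAP/TAZ phosphorylation multiplier
    # RhoA
    RhoA_tot: float = 1.0
    k_fkrho: float = 1.0
    gamma_fak: float = 1.8     # FAK->RhoA gain
    n_fak_exp: float = 4.0     # FAK->RhoA cooperativity (exponent, constant)
    k_drho: float = 2.0
    # ROCK / mDia
    ROCK_tot: float = 1.0
    k_rrho: float = 2.2
    k_drock: float = 1.5
    mDia_tot: float = 1.0
    k_mrho: float = 2.5
    k_dmdia: float = 1.5
    # LIMK / cofilin
    LIMK_tot: float = 1.0
    k_lk: float = 2.0
    k_dlimk: float = 0.8
    Cof_tot: float = 1.0
    k_cof_on: float = 0.2      # cofilin reactivation
    k_lc: float = 1.0          # LIMK-driven cofilin inactivation
    # myosin
    Myo_tot: float = 1.5
    k_mr: float = 2.0
    k_dmyo: float = 1.0
    # actin (Actin_tot = concentration of monomer units)
    Actin_tot: float = 1.0
    A_poly: float = 1.0        # overall polymerization timescale (arbitrary)
    k_poly0: float = 0.05      # mDia-independent polymerization
    k_mdia: float = 1.6        # mDia-driven polymerization
    k_dep: float = 0.3         # basal depolymerization
    k_sev: float = 2.5         # cofilin-mediated severing
    # drug-specific constants
    k_capC: float = 4.0        # cytochalasin D capping of F-actin (1/(uM h))
    k_uncap: float = 1.0
    k_dimC: float = 4.0        # cytochalasin D G-actin dimerization (1/(uM h))
    k_undim: float = 1.0
    k_onL: float = 10.0        # latrunculin G-actin sequestration (1/(uM h))
    k_offL: float = 1.0
    e_jas_p: float = 6.0       # max fold-increase of polymerization by jasplakinolide
    e_jas_d: float = 0.75      # max fractional decrease of depolymerization
    K2_jas: float = 1.0        # shared jasplakinolide sensitivity (uM)
    K_y27: float = 1.0         # Y-27632 half-inhibition of ROCK (uM)
    n_y27_exp: float = 2.0
    K_bleb: float = 2.0        # blebbistatin half-inhibition of stress fibers (uM)
    n_bleb_exp: float = 2.0
    # cytosolic stiffness law E_cyto(F)
    E_c0: float = 0.1          # soft background (kPa)
    E_cmax: float = 7.0        # saturating F-actin contribution (kPa)
    K_EF: float = 0.6          # F-actin half-saturation
    n_EF_exp: float = 2.0
    # lamin A and NPC
    LamA_tot: float = 1.0
    k_lam_deph: float = 1.0
    K_lamE: float = 2.0        # E_cyto half-max for lamin A dephosphorylation (kPa)
    n_lam_exp: float = 2.0
    k_lam_p: float = 0.5       # lamin A phosphorylation (zeroed by LMNA mutation)
    NPC_tot: float = 1.0
    k_npc_open: float = 8.0    # opening driven by lamin A * F-actin * myosin
    k_npc_close: float = 1.0
    # YAP/TAZ
    Y_tot: float = 2.0         # total YAP/TAZ (per cytosolic volume)
    Y5SA_tot: float = 0.0      # mutant pool (set by YAP_5SA mutation)
    k_yphos: float = 2.608       # basal (LATS-dependent) phosphorylation
    k_ydeph0: float = 0.2
    k_ydeph_F: float = 20.16     # stress-fiber (F*myosin)-driven dephosphorylation
    k_yin0: float = 0.1261       # NPC-independent nuclear import
    k_yin_npc: float = 0.3082     # NPC-dependent import
    k_yout: float = 0.8        # nuclear export
    # MRTF
    M_tot: float = 2.0
    K_gm: float = 0.45         # G-actin sequestration constant
    n_gm_exp: float = 2.0
    k_min0: float = 0.8
    k_min_npc: float = 0.8
    k_mout: float = 0.8
    # geometry
    nuc_vol_ratio: float = 0.4  # nuclear / cytosolic volume

    def validate(self) -> None:
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if v is None:
                continue
            if v < 0:
                raise ValueError(f"mechano parameter {f_.name} must be >= 0, got {v}")
        if not self.Actin_tot > 0:
            raise ValueError("Actin_tot must be > 0")

    def with_(self, **kw) -> "MechanoParams":
        return replace(self, **kw)


@dataclass
class TreatmentCondition:
    """A mechanical/pharmacological condition.

    ``substrate_stiffness`` in kPa (glass = 1e7); ``contact_area`` in um^2
    (None = control area A_0); ``cell_density`` in {"low", "high"}; inhibitor
    concentrations in uM; ``mutation`` in {"none", "YAP_5SA", "LMNA"}.
    At most one actin-targeting drug (cytochalasin D / latrunculin /
    jasplakinolide) may be nonzero at a time.
    """

    substrate_stiffness: float = GLASS_STIFFNESS_KPA
    contact_area: float | None = None
    cell_density: str = "low"
    cytochalasin_d: float = 0.0
    latrunculin: float = 0.0     # latrunculin A or B (same mechanism)
    jasplakinolide: float = 0.0
    y27632: float = 0.0
    blebbistatin: float = 0.0
    mutation: str = "none"
    label: str = ""

    def validate(self) -> None:
        if not self.substrate_stiffness > 0:
            raise ValueError("substrate stiffness must be > 0")
        if self.contact_area is not None and not self.contact_area > 0:
            raise ValueError("contact area must be > 0")
        if self.cell_density not in ("low", "high"):
            raise ValueError(f"unknown cell density level {self.cell_density!r}")
        for name in ("cytochalasin_d", "latrunculin", "jasplakinolide",
                     "y27632", "blebbistatin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} concentration must be >= 0")
        if self.mutation not in MUTATIONS:
            raise ValueError(f"unknown mutation {self.mutation!r}; "
                             f"expected one of {MUTATIONS}")
        n_actin = sum(getattr(self, n) > 0 for n in
                      ("cytochalasin_d", "latrunculin", "jasplakinolide"))
        if n_actin > 1:
            raise ValueError("at most one actin-targeting drug per condition")


@dataclass
class MechanoState:
    """Steady-state concentrations of the network (model units)."""

    fak_p: float
    rhoa: float
    rock: float
    mdia: float
    limk: float
    cofilin: float
    myosin: float
    F_actin: float
    G_actin: float          # free G-actin
    G_seq_pool: float       # MRTF-sequestering G-actin pool for the condition
    E_cyto: float
    lamin_a: float          # dephosphorylated (lamina-incorporated) lamin A
    npc: float              # open NPC fraction
    yap_cyto: float
    yap_phos: float
    yap_nuc: float
    yap_nc: float           # nuclear / total-cytosolic ratio
    yap5sa_nuc: float
    mrtf_cyto_free: float
    mrtf_bound: float
    mrtf_nuc: float
    mrtf_nc: float

    @property
    def yap_nuc_total(self) -> float:
        """Nuclear YAP/TAZ including any mutant pool (the clock input)."""
        return self.yap_nuc + self.yap5sa_nuc

    def nuclear_inputs(self) -> tuple[float, float]:
        return self.yap_nuc_total, self.mrtf_nuc

    def as_dict(self) -> dict:
        d = {f_.name: getattr(self, f_.name) for f_ in fields(self)}
        d["yap_nuc_total"] = self.yap_nuc_total
        return d


# ----------------------------------------------------------------- mutations

def apply_mutation(params: MechanoParams, mutation: str) -> MechanoParams:
    """Return parameters modified for a mutation.

    ``YAP_5SA``: adds a second, phosphorylation-dead YAP species whose total
    equals the wild-type YAP/TAZ total (doubling overall YAP/TAZ per cell).
    ``LMNA``: lamin A phosphorylation rate set to zero and NPC opening rate
    doubled.  ``none`` returns the parameters unchanged.
    """
    if mutation not in MUTATIONS:
        raise ValueError(f"unknown mutation {mutation!r}; expected one of {MUTATIONS}")
    if mutation == "none":
        return params
    if mutation == "YAP_5SA":
        return params.with_(Y5SA_tot=params.Y_tot)
    return params.with_(k_lam_p=0.0, k_npc_open=2.0 * params.k_npc_open)


# ------------------------------------------------------------ cascade stages

def fak_contact_modulation(params: MechanoParams, area: float) -> float:
    """Scaling of FAK phosphorylation with cell-substrate contact area.

    Saturating in area and normalized to 1 at the control area ``A_0``;
    smaller micropatterned areas give proportionally less FAK activation.
    """
    if params.A_0 is None or not params.A_0 > 0:
        raise ValueError(
            "control contact area A_0 is not configured; set MechanoParams.A_0 "
            "(um^2) before using contact-area conditions"
        )
    if not area > 0:
        raise ValueError("contact area must be > 0")
    sat = area / (area + params.K_A)
    sat0 = params.A_0 / (params.A_0 + params.K_A)
    return sat / sat0


def _fak_steady(params: MechanoParams, stiffness: float, area_scale: float,
                density_scale: float) -> float:
    w = stiffness**params.n_stiff_exp / (
        stiffness**params.n_stiff_exp + params.C_E**params.n_stiff_exp)
    act = (params.k_f0 + params.k_sf * w) * area_scale * density_scale
    return params.FAK_tot * act / (act + params.k_df)


def _sat(a: float, k: float) -> float:
    return a / (a + k)


def _upstream(params: MechanoParams, condition: TreatmentCondition) -> dict:
    """FAK -> ... -> myosin stages (everything upstream of the actin balance)."""
    area = condition.contact_area if condition.contact_area is not None else params.A_0
    area_scale = fak_contact_modulation(params, area)
    dens_fak = params.density_fak_factor if condition.cell_density == "high" else 1.0
    lats = params.density_lats_factor if condition.cell_density == "high" else 1.0
    fak = _fak_steady(params, condition.substrate_stiffness, area_scale, dens_fak)
    a_rho = params.k_fkrho * (params.gamma_fak * fak) ** params.n_fak_exp
    rhoa = params.RhoA_tot * _sat(a_rho, params.k_drho)
    inh_y27 = 1.0 / (1.0 + (condition.y27632 / params.K_y27) ** params.n_y27_exp)
    rock = params.ROCK_tot * _sat(params.k_rrho * rhoa, params.k_drock) * inh_y27
    mdia = params.mDia_tot * _sat(params.k_mrho * rhoa, params.k_dmdia)
    limk = params.LIMK_tot * _sat(params.k_lk * rock, params.k_dlimk)
    cof = params.Cof_tot * params.k_cof_on / (params.k_cof_on + params.k_lc * limk)
    inh_bleb = 1.0 / (1.0 + (condition.blebbistatin / params.K_bleb) ** params.n_bleb_exp)
    myo = params.Myo_tot * _sat(params.k_mr * rock, params.k_dmyo) * inh_bleb
    return dict(fak_p=fak, rhoa=rhoa, rock=rock, mdia=mdia, limk=limk,
                cofilin=cof, myosin=myo, lats=lats)


def _actin_rates(params: MechanoParams, mdia: float, cofilin: float) -> tuple:
    """Polymerization and depolymerization rate coefficients (k_a, k_d)."""
    k_a = params.A_poly * (params.k_poly0 + params.k_mdia * mdia)
    k_d = params.k_dep + params.k_sev * cofilin
    return k_a, k_d


def _default_rates(params: MechanoParams) -> tuple:
    up = _upstream(params, TreatmentCondition())
    return _actin_rates(params, up["mdia"], up["cofilin"])


def _check_physical(F: float, params: MechanoParams, context: str) -> None:
    if not (0.0 <= F <= params.Actin_tot * (1 + 1e-12)):
        raise RuntimeError(
            f"non-physical F-actin steady state {F:g} (must lie in "
            f"[0, Actin_tot={params.Actin_tot:g}]) under {context}"
        )


def factin_baseline(params: MechanoParams, rates: tuple | None = None) -> float:
    """Untreated steady-state F-actin from the polymerization balance.

    dF/dt = k_a [G] - k_d [F] with [F] + [G] = Actin_tot gives
    [F] = Actin_tot k_a / (k_a + k_d).
    """
    k_a, k_d = rates if rates is not None else _default_rates(params)
    if k_a + k_d <= 0:
        raise ValueError("degenerate actin rate constants: k_a + k_d must be > 0")
    F = params.Actin_tot * k_a / (k_a + k_d)
    _check_physical(F, params, "baseline")
    return F


def factin_cytochalasin(params: MechanoParams, C: float,
                        rates: tuple | None = None) -> tuple:
    """Steady-state (F, free G) under cytochalasin D at concentration C (uM).

    Cytochalasin D caps F-actin (F + C <-> FC) and dimerizes G-actin with rate
    proportional to [C][G] (2 G + C -> CG2, reversible); the drug is in
    excess so C is constant.  Mass conservation
    [F] + [G] + 2[CG2] + [FC] = Actin_tot closes the system.  Dimerized
    G-actin no longer sequesters MRTF, so the MRTF-relevant pool is free [G].
    """
    if C < 0:
        raise ValueError("cytochalasin D concentration must be >= 0")
    k_a, k_d = rates if rates is not None else _default_rates(params)
    if k_a + k_d <= 0:
        raise ValueError("degenerate actin rate constants")
    r = k_a / k_d
    phi_dim = params.k_dimC / params.k_undim
    phi_cap = params.k_capC / params.k_uncap
    G = params.Actin_tot / (1.0 + r + 2.0 * phi_dim * C + phi_cap * C * r)
    F = r * G
    _check_physical(F, params, "cytochalasin D")
    return F, G


def factin_latrunculin(params: MechanoParams, L: float,
                       rates: tuple | None = None) -> tuple:
    """Steady-state (F, total G) under latrunculin at concentration L (uM).

    Latrunculin sequesters G-actin (G + L <-> GL) with the drug in excess;
    conservation [G] + [GL] + [F] = Actin_tot.  The sequestering pool for
    MRTF is the total G-actin [G_tot] = [G] + [GL].
    """
    if L < 0:
        raise ValueError("latrunculin concentration must be >= 0")
    k_a, k_d = rates if rates is not None else _default_rates(params)
    if k_a + k_d <= 0:
        raise ValueError("degenerate actin rate constants")
    r = k_a / k_d
    phi = params.k_onL / params.k_offL
    G = params.Actin_tot / (1.0 + phi * L + r)
    F = r * G
    G_tot = G * (1.0 + phi * L)
    _check_physical(F, params, "latrunculin")
    return F, G_tot


def factin_jasplakinolide(params: MechanoParams, J: float,
                          rates: tuple | None = None) -> float:
    """Steady-state F-actin under jasplakinolide at concentration J (uM).

    Polymerization increases and depolymerization decreases with J through
    saturating laws sharing the sensitivity K2_jas; F(J) is monotone
    non-decreasing.
    """
    if J < 0:
        raise ValueError("jasplakinolide concentration must be >= 0")
    k_a, k_d = rates if rates is not None else _default_rates(params)
    s = J / (params.K2_jas + J)
    k_a2 = k_a * (1.0 + params.e_jas_p * s)
    k_d2 = k_d * (1.0 - params.e_jas_d * s)
    if k_a2 + k_d2 <= 0:
        raise ValueError("degenerate actin rate constants under jasplakinolide")
    F = params.Actin_tot * k_a2 / (k_a2 + k_d2)
    _check_physical(F, params, "jasplakinolide")
    return F


# ------------------------------------------------------------- full network

def steady_state_network(params: MechanoParams,
                         condition: TreatmentCondition) -> MechanoState:
    """Unique steady state of the mechanotransduction network.

    Applies the condition's mutation to the parameters, resolves the
    FAK->...->myosin cascade, the actin balance for the active treatment
    variant, the E_cyto/lamin-A/NPC nuclear-transport stages, and the
    YAP/TAZ and MRTF partitioning.  Deterministic; raises if any stage
    produces a non-physical (negative) concentration.
    """
    params.validate()
    condition.validate()
    p = apply_mutation(params, condition.mutation)
    up = _upstream(p, condition)
    rates = _actin_rates(p, up["mdia"], up["cofilin"])

    if condition.cytochalasin_d > 0:
        F, G_free = factin_cytochalasin(p, condition.cytochalasin_d, rates)
        G_seq = G_free
    elif condition.latrunculin > 0:
        F, G_tot = factin_latrunculin(p, condition.latrunculin, rates)
        G_free = G_tot / (1.0 + p.k_onL / p.k_offL * condition.latrunculin)
        G_seq = G_tot
    elif condition.jasplakinolide > 0:
        F = factin_jasplakinolide(p, condition.jasplakinolide, rates)
        G_free = p.Actin_tot - F
        G_seq = G_free
    else:
        F = factin_baseline(p, rates)
        G_free = p.Actin_tot - F
        G_seq = G_free

    E_cyto = p.E_c0 + p.E_cmax * F**p.n_EF_exp / (p.K_EF**p.n_EF_exp + F**p.n_EF_exp)
    r_deph = p.k_lam_deph * E_cyto**p.n_lam_exp / (
        p.K_lamE**p.n_lam_exp + E_cyto**p.n_lam_exp)
    lam = p.LamA_tot * r_deph / (r_deph + p.k_lam_p) if (r_deph + p.k_lam_p) > 0 \
        else p.LamA_tot
    a_npc = p.k_npc_open * lam * F * up["myosin"]
    npc = p.NPC_tot * _sat(a_npc, p.k_npc_close)

    # YAP/TAZ partitioning (phospho-cytosolic / cytosolic / nuclear)
    k_phos = p.k_yphos * up["lats"]
    k_deph = p.k_ydeph0 + p.k_ydeph_F * F * up["myosin"]
    k_in = p.k_yin0 + p.k_yin_npc * npc
    nc_transport = k_in / p.k_yout
    nu = p.nuc_vol_ratio

    def yap_partition(total: float, kp: float) -> tuple:
        ratio_p = kp / k_deph
        yc = total / (1.0 + ratio_p + nu * nc_transport)
        return yc, ratio_p * yc, nc_transport * yc

    y_c, y_p, y_n = yap_partition(p.Y_tot, k_phos)
    if p.Y5SA_tot > 0:
        _c5, _p5, y5_n = yap_partition(p.Y5SA_tot, 0.0)
    else:
        y5_n = 0.0
    yap_nc = y_n / (y_c + y_p)

    # MRTF partitioning (G-actin-bound / free cytosolic / nuclear)
    b = (G_seq / p.K_gm) ** p.n_gm_exp
    k_min = p.k_min0 + p.k_min_npc * npc
    m_transport = k_min / p.k_mout
    m_c = p.M_tot / (1.0 + b + nu * m_transport)
    m_b = b * m_c
    m_n = m_transport * m_c
    mrtf_nc = m_n / (m_c + m_b)

    state = MechanoState(
        fak_p=up["fak_p"], rhoa=up["rhoa"], rock=up["rock"], mdia=up["mdia"],
        limk=up["limk"], cofilin=up["cofilin"], myosin=up["myosin"],
        F_actin=F, G_actin=G_free, G_seq_pool=G_seq, E_cyto=E_cyto,
        lamin_a=lam, npc=npc,
        yap_cyto=y_c, yap_phos=y_p, yap_nuc=y_n, yap_nc=yap_nc,
        yap5sa_nuc=y5_n,
        mrtf_cyto_free=m_c, mrtf_bound=m_b, mrtf_nuc=m_n, mrtf_nc=mrtf_nc,
    )
    for f_ in fields(state):
        v = getattr(state, f_.name)
        if not math.isfinite(v) or v < 0:
            raise RuntimeError(f"steady state failed: species {f_.name} = {v}")
    return state
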