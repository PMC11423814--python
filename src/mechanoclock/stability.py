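"""Linear stability analysis of the clock DDEs: characteristic roots and the
Hopf bifurcation locus over the nuclear YAP/TAZ-MRTF plane.

Linearizing the delay system about its fixed point gives the characteristic
equation

    det( lambda*I - A0 - A_B e^{-lambda tau_B} - A_P e^{-lambda tau_P}
                       - A_R e^{-lambda tau_R} ) = 0,

with A0 the instantaneous Jacobian (pure decay, -K_d on the diagonal) and
A_j the Jacobians with respect to each delayed argument.  The fixed point is
unstable — i.e. a stable circadian limit cycle exists (supercritical Hopf) —
when the rightmost root pair has positive real part; increasing nuclear
YAP/TAZ/MRTF input pushes the pair into the left half-plane, where
oscillations decay.  The Hopf locus is the zero level set of max Re(lambda).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clock import (CircadianParams, CouplingInput, coupling_rates,
                    fixed_point, HILL_EXPONENT)

__all__ = [
    "CharacteristicProblem",
    "linearize",
    "characteristic",
    "rightmost_roots",
    "hopf_locus",
    "max_real_part",
]


@dataclass
class CharacteristicProblem:
    """Fixed point, Jacobian blocks and delays of a linearized DDE."""

    fixed_point: tuple
    A0: np.ndarray                    # instantaneous Jacobian
    delayed: list                     # [(tau, A_tau), ...]

    def __post_init__(self):
        if not np.all(np.isfinite(self.A0)):
            raise ValueError("non-finite Jacobian")
        for tau, A in self.delayed:
            if tau <= 0:
                raise ValueError("delays must be > 0")
            if not np.all(np.isfinite(A)):
                raise ValueError("non-finite delayed Jacobian")


def linearize(params: CircadianParams, coupling: CouplingInput) -> CharacteristicProblem:
    """Analytic Jacobians of the clock DDEs at the fixed point."""
    B, P, R = fixed_point(params, coupling)
    n = HILL_EXPONENT
    A0 = np.diag([-params.K_dB, -params.K_dP, -params.K_dR])

    # d(K_eB1)/dR at R*, entering through the tau_B-delayed argument
    u = (R / params.K_IR) ** n
    dKeB_dR = -params.K_eB0 * n * u / R / (1.0 + u) ** 2 if R > 0 else 0.0
    A_B = np.zeros((3, 3))
    A_B[0, 2] = dKeB_dR

    # d g / d(B, P) at the fixed point (g = BMAL1-activated, PER/CRY-repressed
    # E-box expression)
    act = (B / params.K_aB) ** n
    rep = 1.0 + (P / params.K_IP) ** n
    dg_dB = (params.K_eP0 * (n * act / B) / (1.0 + act) ** 2 / rep) if B > 0 else 0.0
    gP = params.K_eP0 * act / (1.0 + act)
    dg_dP = -gP * (n * (P / params.K_IP) ** n / P) / rep**2 if P > 0 else 0.0
    A_P = np.zeros((3, 3))
    A_P[1, 0] = dg_dB
    A_P[1, 1] = dg_dP
    A_R = np.zeros((3, 3))
    A_R[2, 0] = params.zeta * dg_dB
    A_R[2, 1] = params.zeta * dg_dP

    return CharacteristicProblem(
        fixed_point=(B, P, R), A0=A0,
        delayed=[(params.tau_B, A_B), (params.tau_P, A_P), (params.tau_R, A_R)],
    )


def characteristic(problem: CharacteristicProblem, lam: complex) -> complex:
    """det(lambda I - A0 - sum_j A_j exp(-lambda tau_j))."""
    if not np.isfinite(lam.real) or not np.isfinite(lam.imag):
        return complex(np.inf)
    dim = problem.A0.shape[0]
    M = lam * np.eye(dim, dtype=complex) - problem.A0.astype(complex)
    for tau, A in problem.delayed:
        z = -lam * tau
        if z.real > 80:  # exp overflow guard: such roots are far left, irrelevant
            return complex(np.inf)
        M -= A * np.exp(z)
    return complex(np.linalg.det(M))


def _newton_root(problem, lam0, tol=1e-13, maxit=60):
    lam = complex(lam0)
    h = 1e-7
    for _ in range(maxit):
        f = characteristic(problem, lam)
        df = (characteristic(problem, lam + h) - characteristic(problem, lam - h)) / (2 * h)
        if df == 0:
            return None
        step = f / df
        lam -= step
        if abs(step) < tol:
            return lam
    return None


def rightmost_roots(problem: CharacteristicProblem, n_roots: int = 6,
                    re_range=(-1.0, 0.6), im_range=(0.0, 1.6),
                    grid=(12, 14)) -> np.ndarray:
    """Characteristic roots with the largest real parts.

    Newton iterations from a grid of complex starting points (delay systems
    have infinitely many roots; only the rightmost matter for stability),
    deduplicated and completed with complex conjugates, sorted by descending
    real part.  Residuals are verified; failure to locate any root raises.
    """
    roots = []
    res = np.linspace(re_range[0], re_range[1], grid[0])
    ims = np.linspace(im_range[0], im_range[1], grid[1])
    for a in res:
        for b in ims:
            lam = _newton_root(problem, a + 1j * b)
            if lam is None:
                continue
            scale = max(1.0, abs(lam)) ** problem.A0.shape[0]
            if abs(characteristic(problem, lam)) > 1e-9 * scale:
                continue
            if lam.real < re_range[0] - 1.0:
                continue
            lam = complex(lam.real, abs(lam.imag))
            if not any(abs(lam - r) < 1e-6 for r in roots):
                roots.append(lam)
    if not roots:
        raise RuntimeError(
            "characteristic root search failed to converge from every start; "
            "widen re_range/im_range or refine the grid"
        )
    roots.sort(key=lambda z: -z.real)
    out = []
    for r in roots[:n_roots]:
        out.append(r)
        if r.imag > 1e-12:
            out.append(r.conjugate())
    return np.array(out[:2 * n_roots])


def max_real_part(params: CircadianParams, coupling: CouplingInput) -> float:
    """Real part of the rightmost characteristic root."""
    prob = linearize(params, coupling)
    return float(rightmost_roots(prob, n_roots=3)[0].real)


def hopf_locus(params: CircadianParams, yap_grid: np.ndarray,
               mrtf_grid: np.ndarray, tol: float = 1e-6) -> dict:
    """Hopf bifurcation curve and period map over the YAP/TAZ-MRTF plane.

    For each MRTF value, the critical nuclear YAP/TAZ level where
    max Re(lambda) crosses zero is located by bisection along the YAP axis
    (robust against the locus's curvature at desk scale).  Points with
    max Re > 0 (below/left of the locus) sustain oscillations whose period
    is estimated as 2*pi / Im(lambda) of the rightmost pair.

    Returns dict with "mrtf", "yap_critical" (NaN where no crossing),
    "period_map" (len(yap_grid) x len(mrtf_grid), NaN in the damped region)
    and "stable_mask".
    """
    yap_grid = np.asarray(yap_grid, dtype=float)
    mrtf_grid = np.asarray(mrtf_grid, dtype=float)

    def re_im(y, m):
        prob = linearize(params, coupling_rates(y, m, params))
        lam = rightmost_roots(prob, n_roots=3)[0]
        return lam.real, lam.imag

    yap_crit = np.full(len(mrtf_grid), np.nan)
    period_map = np.full((len(yap_grid), len(mrtf_grid)), np.nan)
    stable = np.zeros((len(yap_grid), len(mrtf_grid)), dtype=bool)
    for j, m in enumerate(mrtf_grid):
        vals = []
        for i, y in enumerate(yap_grid):
            re, im = re_im(y, m)
            vals.append(re)
            if re > 0 and im > 0:
                period_map[i, j] = 2 * np.pi / im
            stable[i, j] = re <= 0
        vals = np.asarray(vals)
        sign_change = np.nonzero(np.diff(np.signbit(vals)))[0]
        if len(sign_change) == 0:
            continue
        k = sign_change[0]
        lo, hi = yap_grid[k], yap_grid[k + 1]
        flo = vals[k]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            fm, _ = re_im(mid, m)
            if (fm > 0) == (flo > 0):
                lo, flo = mid, fm
            else:
                hi = mid
            if hi - lo < tol * max(1.0, yap_grid[-1]):
                break
        yap_crit[j] = 0.5 * (lo + hi)
    return {"mrtf": mrtf_grid, "yap_critical": yap_crit,
            "period_map": period_map, "stable_mask": stable,
            "yap_grid": yap_grid}
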