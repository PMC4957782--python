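"""Single-nephron tubuloglomerular-feedback (TGF) model.

Six state variables per nephron: proximal tubular pressure P_t (kPa), the
normalized afferent-arteriolar radius r and its rate v_r, and a three-stage
linear chain X1..X3 that approximates the transport delay T of the loop of
Henle. The algebraic closure evaluated at every right-hand side includes a
cubic equation for the efferent plasma protein concentration C_e, the
glomerular pressure/flow block, the sigmoidal TGF activation Psi, and the
active/elastic equilibrium pressure of the arteriolar wall.

The feed pressure P_a is a control parameter for an isolated nephron and
becomes the arteriole-origin node pressure when the nephron is embedded in
a vascular network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "NephronParams",
    "NephronRegimeError",
    "EXAMPLE_STATE",
    "henle_flow",
    "afferent_resistance",
    "cubic_coefficients",
    "solve_Ce",
    "glomerular_block",
    "tgf_activation",
    "equilibrium_pressure",
    "nephron_rhs",
    "nephron_derivatives",
    "integrate_single",
    "autoregulation_sweep",
]

#: published example starting point (P_t, r, v_r, X1, X2, X3); a convenient
#: near-attractor state, not asserted to lie on the limit cycle
EXAMPLE_STATE = np.array([1.7923, 1.0221, -0.0149, 0.9177, 0.8903, 0.8695])

#: peak-to-peak P_t below this is classified as non-oscillatory (kPa)
OSCILLATION_THRESHOLD = 0.01


@dataclass(frozen=True)
class NephronParams:
    """Model constants; defaults are the published table values.

    Resistances kPa*s/nL, pressures kPa, flows nL/s, concentrations g/L.
    """

    c_tub: float = 3.0      # proximal tubule compliance, nL/kPa
    h_a: float = 0.5        # arterial hematocrit
    p_v: float = 1.3        # efferent (venous-side) pressure, kPa
    p_d: float = 0.6        # distal tubular pressure, kPa
    f_hen0: float = 0.2     # Henle equilibrium flow, nL/s
    f_reab: float = 0.3     # proximal reabsorption, nL/s
    r_hen: float = 5.3      # Henle flow resistance
    r_a0: float = 2.4       # afferent arteriolar equilibrium resistance
    r_e: float = 1.9        # efferent arteriolar resistance
    omega: float = 20.0     # wall mass/compliance coefficient, kPa*s^2
    k_damp: float = 0.04    # radius damping, 1/s
    beta: float = 0.67      # non-variable fraction of afferent resistance
    psi_min: float = 0.20
    psi_max: float = 0.44
    psi_eq: float = 0.38
    c_a: float = 54.0       # afferent plasma protein concentration
    a_prot: float = 21.7e-3  # linear protein-pressure coefficient, kPa*L/g
    b_prot: float = 0.39e-3  # quadratic protein-pressure coefficient, kPa*L^2/g^2
    delay: float = 13.5     # TGF transport delay T, s
    alpha: float = 20.0     # TGF amplification

    def __post_init__(self):
        if not (self.psi_min < self.psi_eq < self.psi_max):
            raise ValueError("need psi_min < psi_eq < psi_max")
        if not (0.0 < self.beta < 1.0):
            raise ValueError("beta must lie in (0, 1)")
        if min(self.r_a0, self.r_e, self.r_hen, self.c_tub, self.delay) <= 0:
            raise ValueError("resistances, compliances and delay must be > 0")


class NephronRegimeError(RuntimeError):
    """The protein cubic has no positive root: the state is outside the
    filtration regime (e.g. feed pressure below tubular pressure)."""

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


# ---------------------------------------------------------------------------
# algebraic closure

def henle_flow(p_t, params: NephronParams):
    """Flow into the loop of Henle (nL/s), linear in the pressure drop."""
    return (np.asarray(p_t, float) - params.p_d) / params.r_hen


def afferent_resistance(r, params: NephronParams):
    """(R_a, R): active afferent resistance and its ratio to R_a0.

    R_a = R_a0*(beta + (1-beta)/r^4): a beta fraction of the resistance does
    not respond to radius; the rest follows Poiseuille's r^-4.
    """
    r = np.asarray(r, float)
    if np.any(r <= 0):
        raise ValueError("radius must be > 0")
    r_a = params.r_a0 * (params.beta + (1.0 - params.beta) / r ** 4)
    return r_a, params.r_a0 / r_a


def cubic_coefficients(p_t, p_a, big_r, params: NephronParams):
    """Coefficients (A, B, C, D) of the protein cubic A*Ce^3+...+D = 0."""
    pm = params
    one_m_h = 1.0 - pm.h_a
    a = pm.b_prot + big_r * pm.b_prot * pm.h_a
    b = pm.a_prot + big_r * pm.b_prot * pm.c_a * one_m_h + big_r * pm.a_prot * pm.h_a
    c = (p_t - pm.p_v + big_r * pm.a_prot * pm.c_a * one_m_h
         + big_r * (p_t - p_a) * pm.h_a)
    d = (p_t - p_a) * big_r * pm.c_a * one_m_h
    return a, b, c, d


def _cubic_roots_vec(a, b, c, d):
    """All real roots of a*x^3+b*x^2+c*x+d per element (vectorized Cardano).

    Returns an (n, 3) array with NaN padding. Inputs must be equal-shape
    1-D float arrays.
    """
    p = (3 * a * c - b ** 2) / (3 * a ** 2)
    q = (2 * b ** 3 - 9 * a * b * c + 27 * a ** 2 * d) / (27 * a ** 3)
    shift = b / (3 * a)
    disc = (q / 2) ** 2 + (p / 3) ** 3
    roots = np.full(a.shape + (3,), np.nan)
    one = disc > 0
    if np.any(one):
        s = np.sqrt(disc[one])
        t = np.cbrt(-q[one] / 2 + s) + np.cbrt(-q[one] / 2 - s)
        roots[one, 0] = t - shift[one]
    tri = ~one
    if np.any(tri):
        pp = np.minimum(p[tri], -1e-300)
        m = 2 * np.sqrt(-pp / 3)
        arg = np.clip(3 * q[tri] / (pp * m), -1.0, 1.0)
        theta = np.arccos(arg) / 3
        for k in range(3):
            roots[tri, k] = m * np.cos(theta - 2 * np.pi * k / 3) - shift[tri]
    return roots


def _polish(x, a, b, c, d, iters=3):
    """Newton refinement of a (batch of) cubic root estimates."""
    for _ in range(iters):
        f = ((a * x + b) * x + c) * x + d
        df = (3.0 * a * x + 2.0 * b) * x + c
        df = np.where(df == 0.0, 1.0, df)
        x = x - f / df
    return x


def solve_Ce_vec(p_t, p_a, big_r, params: NephronParams):
    """Vectorized positive-root solve; returns (Ce, ok mask).

    Where the filtration regime holds the cubic has exactly one positive
    root; out of regime (ok=False) the result is NaN.
    """
    a, b, c, d = cubic_coefficients(np.atleast_1d(np.asarray(p_t, float)),
                                    np.atleast_1d(np.asarray(p_a, float)),
                                    np.atleast_1d(np.asarray(big_r, float)),
                                    params)
    a, b, c, d = np.broadcast_arrays(np.atleast_1d(a), np.atleast_1d(b),
                                     np.atleast_1d(c), np.atleast_1d(d))
    if np.all(a != 0.0):
        roots = _cubic_roots_vec(a, b, c, d)
    else:
        # degenerate configurations (e.g. zero quadratic protein-pressure
        # coefficient) reduce the closure to a quadratic or linear equation
        roots = np.full(a.shape + (3,), np.nan)
        cub = a != 0.0
        if np.any(cub):
            roots[cub] = _cubic_roots_vec(a[cub], b[cub], c[cub], d[cub])
        quad = ~cub & (b != 0.0)
        disc = c[quad] ** 2 - 4.0 * b[quad] * d[quad]
        ok_q = disc >= 0
        sq = np.sqrt(np.where(ok_q, disc, 0.0))
        r1 = np.where(ok_q, (-c[quad] + sq) / (2 * b[quad]), np.nan)
        r2 = np.where(ok_q, (-c[quad] - sq) / (2 * b[quad]), np.nan)
        roots[quad, 0], roots[quad, 1] = r1, r2
        lin = ~cub & (b == 0.0) & (c != 0.0)
        roots[lin, 0] = -d[lin] / c[lin]
    neg = ~(roots > 0)  # True for NaN padding as well
    roots[neg] = -np.inf
    best = roots.max(axis=-1)
    ok = np.isfinite(best)
    ce = np.where(ok, best, 1.0)
    ce = _polish(ce, a, b, c, d)
    # residual audit relative to the dominant term scale
    scale = (np.abs(a) * ce * ce * ce + np.abs(b) * ce * ce
             + np.abs(c) * ce + np.abs(d))
    res = ((a * ce + b) * ce + c) * ce + d
    bad = ok & (np.abs(res) > 1e-10 * np.where(scale > 0, scale, 1.0))
    if np.any(bad):  # pragma: no cover - Newton-polished Cardano is exact
        for i in np.flatnonzero(bad):
            ce[i] = _bracket_root(a[i], b[i], c[i], d[i])
    return np.where(ok, ce, np.nan), ok


def _bracket_root(a, b, c, d):
    """Safeguarded bisection fallback for the positive cubic root."""
    from scipy.optimize import brentq
    poly = lambda x: ((a * x + b) * x + c) * x + d
    lo, hi = 1e-12, 1.0
    while poly(lo) * poly(hi) > 0 and hi < 1e9:
        hi *= 2
    return brentq(poly, lo, hi, xtol=1e-14)


def solve_Ce(p_t, p_a, big_r, params: NephronParams) -> float:
    """Efferent plasma protein concentration C_e (g/L): the unique positive
    root of the closure cubic. Raises :class:`NephronRegimeError` when no
    positive root exists."""
    ce, ok = solve_Ce_vec(p_t, p_a, big_r, params)
    if not ok.all():
        raise NephronRegimeError(
            "protein cubic has no positive root (feed pressure below the "
            "filtration regime)", state={"p_t": p_t, "p_a": p_a, "R": big_r})
    return float(ce[0]) if np.size(ce) == 1 else ce


def glomerular_block(c_e, p_t, p_a, r_a, params: NephronParams):
    """(P_g, P_av, F_filt, F_eff) from the protein concentration."""
    pm = params
    c_e = np.asarray(c_e, float)
    p_g = pm.b_prot * c_e ** 2 + pm.a_prot * c_e + p_t
    p_av = 0.5 * (p_a - (p_a - p_g) * pm.beta * pm.r_a0 / r_a + p_g)
    f_filt = (1.0 - pm.h_a) * (1.0 - pm.c_a / c_e) * (p_a - p_g) / r_a
    f_eff = (p_g - pm.p_v) / pm.r_e
    return p_g, p_av, f_filt, f_eff


def tgf_activation(x3, params: NephronParams):
    """Sigmoidal TGF activation Psi as a function of the delayed Henle flow
    proxy 3*X3/T; equals psi_eq when that flow matches F_Hen0."""
    pm = params
    x = 3.0 * np.asarray(x3, float) / (pm.delay * pm.f_hen0) - 1.0
    gain = (pm.psi_eq - pm.psi_min) / (pm.psi_max - pm.psi_eq)
    return pm.psi_max - (pm.psi_max - pm.psi_min) / (1.0 + gain * np.exp(pm.alpha * x))


def equilibrium_pressure(r, psi, params: NephronParams):
    """(P_el, P_act, P_eq): passive elastic, active muscular and total
    equilibrium pressure of the arteriolar wall at radius r."""
    r = np.asarray(r, float)
    p_el = 1.6 * (r - 1.0) + 2.4 * np.exp(10.0 * (r - 1.4))
    p_act = 4.7 / (1.0 + np.exp(13.0 * (0.4 - r))) + 7.2 * r + 6.3
    return p_el, p_act, p_el + np.asarray(psi, float) * p_act


# ---------------------------------------------------------------------------
# right-hand side

def nephron_rhs(states, p_a, params: NephronParams, psi_effective=None):
    """Vectorized right-hand side for n nephrons.

    ``states`` is (n, 6); ``psi_effective``, if given, replaces each
    nephron's own activation in the wall equilibrium (this is how
    electrotonic coupling enters). Returns (derivs (n, 6), aux dict).

    Out-of-regime nephrons (no positive protein root) fall back to the
    no-filtration closure C_e = C_a, F_filt = 0, which lets the tubule
    drain and reproduces the negative tubular pressures seen at
    insufficient feed pressure; they are flagged in ``aux['ok']``.
    """
    pm = params
    st = np.atleast_2d(np.asarray(states, float))
    p_t, r, v_r, x1, x2, x3 = st.T
    p_a = np.broadcast_to(np.asarray(p_a, float), p_t.shape)
    f_hen = henle_flow(p_t, pm)
    r_safe = np.maximum(r, 1e-6)
    r_a, _ = afferent_resistance(r_safe, pm)
    # the protein cubic's resistance ratio is R_e/R_a: that is the unique
    # choice for which the root satisfies blood-flow conservation
    # F_in = F_filt + F_eff along with protein conservation
    ce, ok = solve_Ce_vec(p_t, p_a, pm.r_e / r_a, pm)
    ce = np.where(ok, ce, pm.c_a)
    p_g, p_av, f_filt, f_eff = glomerular_block(ce, p_t, p_a, r_a, pm)
    f_filt = np.where(ok, f_filt, 0.0)
    psi = tgf_activation(x3, pm)
    psi_eff = psi if psi_effective is None else np.asarray(psi_effective, float)
    _, _, p_eq = equilibrium_pressure(r_safe, psi_eff, pm)
    d = np.empty_like(st)
    d[:, 0] = (f_filt - pm.f_reab - f_hen) / pm.c_tub
    d[:, 1] = v_r
    d[:, 2] = (p_av - p_eq) / pm.omega - pm.k_damp * v_r
    d[:, 3] = f_hen - (3.0 / pm.delay) * x1
    d[:, 4] = (3.0 / pm.delay) * (x1 - x2)
    d[:, 5] = (3.0 / pm.delay) * (x2 - x3)
    aux = {"f_hen": f_hen, "r_a": r_a, "ce": ce, "p_g": p_g, "p_av": p_av,
           "f_filt": f_filt, "f_eff": f_eff, "psi": psi, "ok": ok,
           "f_neph": (p_a - p_g) / r_a}
    return d, aux


def nephron_derivatives(state, p_a, params: NephronParams, psi_effective=None):
    """Single-nephron time derivatives (length-6 array)."""
    d, _ = nephron_rhs(np.asarray(state, float)[None, :], p_a, params,
                       None if psi_effective is None else [psi_effective])
    return d[0]


# ---------------------------------------------------------------------------
# integration and sweeps

def integrate_single(p_a, params: NephronParams = NephronParams(),
                     t_end=600.0, y0=None, t_eval_step=0.25,
                     rtol=1e-6, atol=1e-8):
    """Integrate one isolated nephron; returns (t, states (len(t), 6))."""
    y0 = EXAMPLE_STATE.copy() if y0 is None else np.asarray(y0, float)
    rhs = lambda t, y: nephron_rhs(y[None, :], p_a, params)[0][0]
    t_eval = np.arange(0.0, t_end + 1e-9, t_eval_step)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.t, sol.y.T


def autoregulation_sweep(p_a_values, params: NephronParams = NephronParams(),
                         t_transient=300.0, t_measure=300.0):
    """Time-averaged response of an isolated nephron across feed pressures.

    Integrates to stationarity at each P_a, discards the transient and
    reports mean radius, efferent flow and filtration rate plus the
    peak-to-peak amplitude of the tubular pressure. Grid points where the
    model leaves the filtration regime or the solver fails are reported
    with ``active=False``.
    """
    import pandas as pd

    rows = []
    for p_a in np.asarray(p_a_values, float):
        try:
            t, y = integrate_single(p_a, params, t_end=t_transient + t_measure)
        except RuntimeError:
            rows.append({"p_a": p_a, "r_mean": np.nan, "f_eff_mean": np.nan,
                         "f_filt_mean": np.nan, "p_t_mean": np.nan,
                         "p_t_amplitude": np.nan, "active": False})
            continue
        sel = t >= t_transient
        _, aux = nephron_rhs(y[sel], p_a, params)
        p_t = y[sel, 0]
        amp = float(p_t.max() - p_t.min())
        active = bool(amp >= OSCILLATION_THRESHOLD and p_t.mean() > 0
                      and aux["ok"].all())
        rows.append({"p_a": float(p_a), "r_mean": float(y[sel, 1].mean()),
                     "f_eff_mean": float(aux["f_eff"].mean()),
                     "f_filt_mean": float(aux["f_filt"].mean()),
                     "p_t_mean": float(p_t.mean()),
                     "p_t_amplitude": amp, "active": active})
    return pd.DataFrame(rows)
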