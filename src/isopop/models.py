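"""Testbed dose-response models.

Two kinds of objective are provided:

* A malaria-like combination-therapy PK/PD model: each drug follows a
  two-compartment linear-elimination model with first-order absorption; the
  parasite population grows exponentially and is killed at a
  concentration-dependent rate combining both drugs' sigmoidal Emax effects
  by a Bliss-independence rule modified for unequal maximal effects. An
  individual is cured when parasitemia falls below the limit of
  quantification (10 parasites/ml) at day 28 after a single dose of each
  drug.

* Analytic surface fixtures (additive, Bliss, probit-additive and a
  non-monotone bump family) with closed-form isoboles, used as exact oracles
  for the grid-refinement and aggregation algorithms.

The default malaria parameterization is hypothetical: it is chosen so that
single-drug cures are reachable within a 0-800 mg dosing range and the
population success-rate surface is monotone in each dose. It does not
describe any specific compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import norm

from .geometry import Polyline

__all__ = [
    "DrugParams",
    "MalariaModel",
    "combined_kill_rate",
    "hill_effect",
    "simulate_malaria_individual",
    "AnalyticSurface",
    "analytic_surface",
    "MALARIA_PARAMETER_NAMES",
]


def hill_effect(c, emax, ec50, hill):
    """Sigmoidal Emax effect e = Emax * c^h / (EC50^h + c^h)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative concentration")
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / ec50) ** hill, 0.0)
    return emax * ratio / (1.0 + ratio)


def combined_kill_rate(c1, c2, pd_params: Mapping[str, float]):
    """Combined kill rate of two drugs under modified Bliss independence.

    Per-drug effects e_i = Emax_i c_i^h_i / (EC50_i^h_i + c_i^h_i) are
    combined as ``e1 + e2 - e1*e2 / max(Emax_1, Emax_2)``: the classical
    Bliss product term is normalized by the larger maximal effect so that
    the combination of two saturating drugs caps at max(Emax) rather than
    exceeding either drug's achievable kill rate, while reducing exactly to
    the single-drug effect when the partner concentration is zero.

    ``pd_params`` needs keys emax1, ec50_1, h1, emax2, ec50_2, h2.
    """
    e1 = hill_effect(c1, pd_params["emax1"], pd_params["ec50_1"], pd_params["h1"])
    e2 = hill_effect(c2, pd_params["emax2"], pd_params["ec50_2"], pd_params["h2"])
    emax_ref = max(pd_params["emax1"], pd_params["emax2"])
    return e1 + e2 - e1 * e2 / emax_ref


@dataclass(frozen=True)
class DrugParams:
    """Two-compartment oral PK + sigmoidal PD parameters for one drug.

    Units: days, litres, mg; concentrations in mg/L; kill rates in 1/day.
    """

    ka: float     # first-order absorption rate [1/day]
    cl: float     # clearance [L/day]
    vc: float     # central volume [L]
    q: float      # inter-compartmental clearance [L/day]
    vp: float     # peripheral volume [L]
    emax: float   # maximal kill rate [1/day]
    ec50: float   # concentration of half-maximal kill [mg/L]
    hill: float   # Hill coefficient

    def __post_init__(self):
        for name in ("ka", "cl", "vc", "q", "vp", "hill"):
            if getattr(self, name) <= 0:
                raise ValueError(f"drug parameter {name} must be > 0")


def _two_compartment_concentration(t, dose, ka, cl, vc, q, vp):
    """Closed-form central concentration after a single oral dose at t=0.

    Standard bi-exponential disposition with first-order absorption:
    C(t) = (D ka / Vc) * [A e^-at + B e^-bt + K e^-ka t] with macro
    constants from the micro rates k10 = CL/Vc, k12 = Q/Vc, k21 = Q/Vp.
    Broadcasts over subjects and time.
    """
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    ca = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    cb = (k21 - beta) / ((ka - beta) * (alpha - beta))
    ck = (k21 - ka) / ((alpha - ka) * (beta - ka))
    pref = dose * ka / vc
    conc = pref * (
        ca * np.exp(-alpha * t) + cb * np.exp(-beta * t) + ck * np.exp(-ka * t)
    )
    return np.maximum(conc, 0.0)


@lru_cache(maxsize=8)
def _quadrature_nodes(horizon: float) -> tuple[np.ndarray, np.ndarray]:
    # composite 5-point Gauss-Legendre: quarter-day panels over the
    # absorption transient (first 2 days), half-day panels afterwards
    edges = np.concatenate(
        [np.arange(0.0, min(2.0, horizon), 0.25), np.arange(2.0, horizon, 0.5), [horizon]]
    )
    edges = np.unique(edges)
    gx, gw = np.polynomial.legendre.leggauss(5)
    a, b = edges[:-1], edges[1:]
    half = (b - a) / 2.0
    nodes = ((a + b) / 2.0)[:, None] + half[:, None] * gx[None, :]
    weights = half[:, None] * gw[None, :]
    return nodes.ravel(), weights.ravel()


#: flat parameter names understood by MalariaModel.with_params / success()
MALARIA_PARAMETER_NAMES = (
    "ka1", "cl1", "vc1", "q1", "vp1", "emax1", "ec50_1", "h1",
    "ka2", "cl2", "vc2", "q2", "vp2", "emax2", "ec50_2", "h2",
    "kgrow",
)


@dataclass(frozen=True)
class MalariaModel:
    """Malaria-like single-dose combination-therapy testbed.

    The per-subject endpoint is cure: parasitemia below ``loq`` at
    ``horizon`` days after simultaneous single doses of both drugs. Because
    the parasite equation is linear in log-parasitemia,

        d log P / dt = k_grow - k_kill(C1(t), C2(t)),

    the endpoint has the exact form
    log P(T) = log P0 + k_grow*T - int_0^T k_kill dt, which the model
    evaluates by composite Gauss-Legendre quadrature over the closed-form
    concentration profiles (no ODE solver needed). ``simulate_individual``
    integrates the full ODE system as an independent cross-check and for
    trajectory output.
    """

    drug1: DrugParams = DrugParams(
        ka=8.0, cl=6.0, vc=50.0, q=10.0, vp=100.0, emax=3.5, ec50=0.8, hill=3.0
    )
    drug2: DrugParams = DrugParams(
        ka=6.0, cl=9.0, vc=70.0, q=12.0, vp=140.0, emax=4.0, ec50=1.0, hill=2.5
    )
    growth_rate: float = 1.15          # parasite net growth [1/day]
    baseline: float = 1e8              # initial parasitemia [parasites/ml]
    loq: float = 10.0                  # limit of quantification [parasites/ml]
    horizon: float = 28.0              # endpoint evaluation time [days]

    def param_dict(self) -> dict[str, float]:
        """Flat name -> value mapping of all structural parameters."""
        d1, d2 = self.drug1, self.drug2
        return {
            "ka1": d1.ka, "cl1": d1.cl, "vc1": d1.vc, "q1": d1.q, "vp1": d1.vp,
            "emax1": d1.emax, "ec50_1": d1.ec50, "h1": d1.hill,
            "ka2": d2.ka, "cl2": d2.cl, "vc2": d2.vc, "q2": d2.q, "vp2": d2.vp,
            "emax2": d2.emax, "ec50_2": d2.ec50, "h2": d2.hill,
            "kgrow": self.growth_rate,
        }

    def with_params(self, overrides: Mapping[str, float]) -> "MalariaModel":
        """Return a copy with flat-named parameters replaced."""
        base = self.param_dict()
        unknown = set(overrides) - set(base)
        if unknown:
            raise KeyError(f"unknown malaria parameters: {sorted(unknown)}")
        base.update(overrides)
        d1 = DrugParams(base["ka1"], base["cl1"], base["vc1"], base["q1"],
                        base["vp1"], base["emax1"], base["ec50_1"], base["h1"])
        d2 = DrugParams(base["ka2"], base["cl2"], base["vc2"], base["q2"],
                        base["vp2"], base["emax2"], base["ec50_2"], base["h2"])
        return replace(self, drug1=d1, drug2=d2, growth_rate=base["kgrow"])

    # ---- vectorized endpoint over subjects -------------------------------

    def log10_parasitemia(self, params: Mapping[str, np.ndarray],
                          dose1: float, dose2: float) -> np.ndarray:
        """log10 parasitemia at the horizon for an array of subjects.

        ``params`` maps flat parameter names to (n_subj,) arrays; names not
        present fall back to the model defaults. Doses are in mg.
        """
        if dose1 < 0 or dose2 < 0:
            raise ValueError("doses must be >= 0")
        defaults = self.param_dict()
        p = {k: np.atleast_1d(np.asarray(params.get(k, defaults[k]), dtype=float))
             for k in defaults}
        n = max(v.size for v in p.values())
        t, w = _quadrature_nodes(self.horizon)

        def col(v):
            return np.broadcast_to(v, (n,))[:, None]

        kill = np.zeros((n, t.size))
        if dose1 > 0:
            c1 = _two_compartment_concentration(
                t[None, :], dose1, col(p["ka1"]), col(p["cl1"]),
                col(p["vc1"]), col(p["q1"]), col(p["vp1"]))
        else:
            c1 = np.zeros((n, t.size))
        if dose2 > 0:
            c2 = _two_compartment_concentration(
                t[None, :], dose2, col(p["ka2"]), col(p["cl2"]),
                col(p["vc2"]), col(p["q2"]), col(p["vp2"]))
        else:
            c2 = np.zeros((n, t.size))
        e1 = _hill_cols(c1, col(p["emax1"]), col(p["ec50_1"]), col(p["h1"]))
        e2 = _hill_cols(c2, col(p["emax2"]), col(p["ec50_2"]), col(p["h2"]))
        emax_ref = np.maximum(col(p["emax1"]), col(p["emax2"]))
        kill = e1 + e2 - e1 * e2 / emax_ref
        integral = kill @ w
        kgrow = np.broadcast_to(p["kgrow"], (n,))
        ln_p = np.log(self.baseline) + kgrow * self.horizon - integral
        return ln_p / np.log(10.0)

    def success(self, params: Mapping[str, np.ndarray],
                dose1: float, dose2: float) -> np.ndarray:
        """Boolean cure indicator per subject: P(horizon) < loq."""
        return self.log10_parasitemia(params, dose1, dose2) < np.log10(self.loq)

    # ---- single-subject ODE path -----------------------------------------

    def simulate_individual(self, params: Mapping[str, float],
                            doses: tuple[float, float],
                            horizon: float | None = None,
                            n_times: int = 281):
        """Integrate the full PK/PD ODE system for one subject.

        States: gut and central/peripheral amounts for each drug plus
        log-parasitemia (which keeps the parasite count positive by
        construction). Returns ``(success, trajectory)`` where trajectory is
        a dict with keys t, c1, c2, parasites.
        """
        m = self.with_params(dict(params)) if params else self
        horizon = self.horizon if horizon is None else horizon
        d1, d2 = m.drug1, m.drug2
        dose1, dose2 = doses
        if dose1 < 0 or dose2 < 0:
            raise ValueError("doses must be >= 0")
        pd = {"emax1": d1.emax, "ec50_1": d1.ec50, "h1": d1.hill,
              "emax2": d2.emax, "ec50_2": d2.ec50, "h2": d2.hill}

        def rhs(t, y):
            g1, a1, b1, g2, a2, b2, lp = y
            c1 = max(a1, 0.0) / d1.vc
            c2 = max(a2, 0.0) / d2.vc
            kk = combined_kill_rate(c1, c2, pd)
            return [
                -d1.ka * g1,
                d1.ka * g1 - (d1.cl + d1.q) / d1.vc * a1 + d1.q / d1.vp * b1,
                d1.q / d1.vc * a1 - d1.q / d1.vp * b1,
                -d2.ka * g2,
                d2.ka * g2 - (d2.cl + d2.q) / d2.vc * a2 + d2.q / d2.vp * b2,
                d2.q / d2.vc * a2 - d2.q / d2.vp * b2,
                m.growth_rate - kk,
            ]

        y0 = [dose1, 0.0, 0.0, dose2, 0.0, 0.0, np.log(m.baseline)]
        t_eval = np.linspace(0.0, horizon, n_times)
        sol = solve_ivp(rhs, (0.0, horizon), y0, t_eval=t_eval,
                        method="LSODA", rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed for doses {doses}: {sol.message}; "
                f"parameters: {dict(params) if params else 'defaults'}"
            )
        parasites = np.exp(sol.y[6])
        success = bool(parasites[-1] < m.loq)
        traj = {"t": sol.t, "c1": sol.y[1] / d1.vc, "c2": sol.y[4] / d2.vc,
                "parasites": parasites}
        return success, traj


def _hill_cols(c, emax, ec50, hill):
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / ec50) ** hill, 0.0)
    return emax * ratio / (1.0 + ratio)


def simulate_malaria_individual(params, doses, horizon=None,
                                model: MalariaModel | None = None):
    """Convenience wrapper: simulate one subject on the malaria testbed."""
    return (model or MalariaModel()).simulate_individual(params, doses, horizon)


# ---------------------------------------------------------------------------
# analytic fixtures with closed-form isoboles
# ---------------------------------------------------------------------------

_FAMILIES = ("additive", "bliss", "probit-additive", "nonmonotone-bump")


@dataclass(frozen=True)
class AnalyticSurface:
    """Closed-form dose-response surface with an exact isobole oracle."""

    family: str
    bounds: tuple[float, float] = (1.0, 1.0)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {_FAMILIES}")

    def value(self, d1, d2):
        """Surface value at dose coordinates (vectorized)."""
        x = np.asarray(d1, float) / self.bounds[0]
        y = np.asarray(d2, float) / self.bounds[1]
        p = self.params
        if self.family == "additive":
            w1, w2 = p.get("w1", 0.5), p.get("w2", 0.5)
            return w1 * x + w2 * y
        if self.family == "bliss":
            y1 = hill_effect(x, 1.0, p.get("ec50_1", 0.4), p.get("h1", 2.0))
            y2 = hill_effect(y, 1.0, p.get("ec50_2", 0.4), p.get("h2", 2.0))
            return 1.0 - (1.0 - y1) * (1.0 - y2)
        if self.family == "probit-additive":
            b0 = p.get("b0", -2.0)
            b1, b2 = p.get("b1", 3.0), p.get("b2", 3.0)
            return norm.cdf(b0 + b1 * x + b2 * y)
        # nonmonotone-bump: additive base plus a localized Gaussian bump,
        # producing a region where the surface decreases as dose increases
        amp = p.get("amp", 0.3)
        cx, cy = p.get("center", (0.5, 0.5))
        s = p.get("width", 0.12)
        base = 0.5 * x + 0.5 * y
        return base + amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * s * s))

    @property
    def objective(self):
        """Scalar objective f(amt1, amt2) for the isobole finder."""
        return lambda a1, a2: float(self.value(a1, a2))

    def exact_isobole(self, level: float, n: int = 513) -> Polyline:
        """The true level set in dose units, as a dense polyline.

        Raises for the nonmonotone-bump family, whose level sets are not
        single curves.
        """
        b1, b2 = self.bounds
        p = self.params
        if self.family == "additive":
            w1, w2 = p.get("w1", 0.5), p.get("w2", 0.5)
            # w1*x + w2*y = level clipped to the unit box
            x_hi = min(level / w1, 1.0)
            x_lo = max(0.0, (level - w2) / w1)
            x = np.linspace(x_lo, x_hi, n)
            y = (level - w1 * x) / w2
            return Polyline(np.column_stack([x * b1, y * b2]))
        if self.family == "probit-additive":
            c = norm.ppf(level) - p.get("b0", -2.0)
            w1, w2 = p.get("b1", 3.0), p.get("b2", 3.0)
            x_hi = min(c / w1, 1.0)
            x_lo = max(0.0, (c - w2) / w1)
            x = np.linspace(x_lo, x_hi, n)
            y = (c - w1 * x) / w2
            return Polyline(np.column_stack([x * b1, y * b2]))
        if self.family == "bliss":
            ec1, h1 = p.get("ec50_1", 0.4), p.get("h1", 2.0)
            ec2, h2 = p.get("ec50_2", 0.4), p.get("h2", 2.0)

            def inv_hill(yv, ec50, h):
                yv = np.clip(yv, 0.0, 1.0 - 1e-15)
                return ec50 * (yv / (1.0 - yv)) ** (1.0 / h)

            # x-range where drug 1 alone is below the level
            x_star = min(inv_hill(level, ec1, h1), 1.0)
            x = np.linspace(0.0, x_star, n)
            y1 = hill_effect(x, 1.0, ec1, h1)
            y2_req = 1.0 - (1.0 - level) / (1.0 - y1)
            y = inv_hill(y2_req, ec2, h2)
            pts = np.column_stack([x * b1, np.minimum(y, 1.0) * b2])
            return Polyline(pts)
        raise ValueError("nonmonotone-bump has no single-curve isobole")


def analytic_surface(family: str, bounds=(1.0, 1.0), **params) -> AnalyticSurface:
    """Build an analytic fixture surface; see :class:`AnalyticSurface`."""
    return AnalyticSurface(family=family, bounds=tuple(bounds), params=params)
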