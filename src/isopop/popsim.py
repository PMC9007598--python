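"""Hierarchical two-level Monte-Carlo population simulation.

Populations are drawn from the parameter-uncertainty distribution (the
asymptotic sampling distribution of the population-parameter estimates,
multivariate normal on the log scale for positive-constrained parameters);
each population then carries its own sample of individual subjects drawn
log-normally around the population values with inter-individual-variability
(IIV) variances. The module also houses the one-dimensional machinery:
bisection for the effective dose of a monotone dose-response curve, and the
empirical-CDF construction of confidence levels from an ensemble of
effective doses.

Randomness discipline: a single master seed; the population-level draw uses
one dedicated stream, and each population's subject draw uses a stream keyed
by (seed, population_id), so ensembles are bit-reproducible regardless of
the order in which populations are later evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "UncertaintyDistribution",
    "IIVSpec",
    "PopulationParameters",
    "PopulationEnsemble",
    "EfficacyTarget",
    "sample_ensemble",
    "success_rate",
    "effective_dose_bisection",
    "confidence_from_effective_doses",
    "check_monotonicity",
    "rank_parameter_influence",
    "BracketError",
    "MonotonicityReport",
]

_SYM_TOL = 1e-10
_PSD_TOL = -1e-10


class BracketError(ValueError):
    """Bisection bracket invalid; .classification says which way."""

    def __init__(self, message: str, classification: str):
        super().__init__(message)
        self.classification = classification


@dataclass(frozen=True)
class UncertaintyDistribution:
    """Multivariate-normal parameter-uncertainty distribution.

    ``mean`` holds point estimates on the sampling scale: log-transformed
    values for positive-constrained parameters (the default), raw values
    where ``log_scale`` is False. ``covariance`` is the asymptotic MLE
    covariance on that same scale.
    """

    parameter_names: tuple[str, ...]
    mean: np.ndarray
    covariance: np.ndarray
    log_scale: tuple[bool, ...] = ()

    def __post_init__(self):
        names = tuple(self.parameter_names)
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        k = len(names)
        if mean.shape != (k,) or cov.shape != (k, k):
            raise ValueError("mean/covariance dimensions inconsistent with names")
        if np.max(np.abs(cov - cov.T), initial=0.0) > _SYM_TOL:
            raise ValueError("covariance not symmetric")
        log_scale = tuple(self.log_scale) if self.log_scale else (True,) * k
        if len(log_scale) != k:
            raise ValueError("log_scale length inconsistent with names")
        object.__setattr__(self, "parameter_names", names)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(self, "log_scale", log_scale)

    def validate_psd(self) -> None:
        eig = np.linalg.eigvalsh(self.covariance)
        if eig.min() < _PSD_TOL:
            raise ValueError(
                f"covariance is not positive semi-definite: smallest "
                f"eigenvalue {eig.min():.3e}"
            )

    @classmethod
    def from_estimates(cls, estimates: Mapping[str, float],
                       se: Mapping[str, float] | float = 0.0,
                       correlation: np.ndarray | None = None):
        """Build from natural-scale point estimates and log-scale SEs."""
        names = tuple(estimates)
        mean = np.log(np.array([estimates[n] for n in names], dtype=float))
        if isinstance(se, Mapping):
            s = np.array([se.get(n, 0.0) for n in names], dtype=float)
        else:
            s = np.full(len(names), float(se))
        corr = np.eye(len(names)) if correlation is None else np.asarray(correlation)
        cov = corr * np.outer(s, s)
        return cls(names, mean, cov)


@dataclass(frozen=True)
class IIVSpec:
    """Log-normal inter-individual variability specification.

    ``variances``: parameter name -> omega^2 (variance of the log-scale
    random effect). Parameters without an entry do not vary across subjects.
    An optional correlation matrix (ordered like ``variances``) induces
    correlated random effects.
    """

    variances: dict[str, float] = field(default_factory=dict)
    correlation: np.ndarray | None = None

    def __post_init__(self):
        for name, v in self.variances.items():
            if v < 0:
                raise ValueError(f"IIV variance for {name} must be >= 0")


@dataclass
class PopulationParameters:
    """One realization of population parameters plus its subject draws."""

    population_id: int
    values: dict[str, float]
    individuals: pd.DataFrame  # one row per subject, columns = parameters

    @property
    def n_subj(self) -> int:
        return len(self.individuals)


@dataclass
class PopulationEnsemble:
    """The two-level hierarchical sample: populations x subjects."""

    populations: list[PopulationParameters]
    seed: int
    n_subj: int

    @property
    def n_pop(self) -> int:
        return len(self.populations)

    def parameter_table(self) -> pd.DataFrame:
        """Population-level parameters, one row per population."""
        rows = [dict(p.values, population_id=p.population_id)
                for p in self.populations]
        return pd.DataFrame(rows).set_index("population_id")

    def subject_table(self) -> pd.DataFrame:
        """Long-format table of all subject draws with ids."""
        frames = []
        for p in self.populations:
            df = p.individuals.copy()
            df.insert(0, "subject_id", np.arange(len(df)))
            df.insert(0, "population_id", p.population_id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class EfficacyTarget:
    """Prespecified success-rate threshold plus the per-subject predicate."""

    target_rate: float
    predicate: str = "cure_at_horizon"
    predicate_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.target_rate < 1.0:
            raise ValueError("target_rate must lie strictly in (0, 1)")


def sample_ensemble(u: UncertaintyDistribution, iiv_spec: IIVSpec,
                    n_pop: int, n_subj: int, seed: int,
                    n_subj_overrides: Mapping[int, int] | None = None
                    ) -> PopulationEnsemble:
    """Draw the hierarchical population ensemble.

    Population parameters are drawn multivariate-normal on the sampling
    scale and back-transformed (exp for log-scale entries); each subject's
    parameters are the population values multiplied by log-normal random
    effects with the IIV variances. If an IIV variance name appears among
    the uncertainty parameters, the *drawn* population value of that
    parameter is used as the subject-level variance (uncertainty about the
    IIV magnitude itself propagates to the subjects).
    """
    if n_pop < 1 or n_subj < 1:
        raise ValueError("n_pop and n_subj must be >= 1")
    u.validate_psd()
    rng_pop = np.random.default_rng([int(seed), 1])
    draws = rng_pop.multivariate_normal(u.mean, u.covariance, size=n_pop,
                                        method="svd")
    log_mask = np.array(u.log_scale)
    draws[:, log_mask] = np.exp(draws[:, log_mask])

    iiv_names = list(iiv_spec.variances)
    corr = iiv_spec.correlation
    chol = None
    if corr is not None:
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (len(iiv_names),) * 2:
            raise ValueError("IIV correlation shape inconsistent with variances")
        chol = np.linalg.cholesky(corr)

    populations = []
    for pid in range(n_pop):
        values = dict(zip(u.parameter_names, draws[pid]))
        ns = n_subj if not n_subj_overrides else n_subj_overrides.get(pid, n_subj)
        rng_ind = np.random.default_rng([int(seed), 2, pid])
        z = rng_ind.standard_normal((ns, len(iiv_names)))
        if chol is not None:
            z = z @ chol.T
        cols = {}
        for j, name in enumerate(iiv_names):
            omega2 = iiv_spec.variances[name]
            if isinstance(omega2, str):
                omega2 = values[omega2]
            base = values.get(name)
            if base is None:
                raise KeyError(f"IIV parameter {name!r} not among population "
                               f"parameters")
            if base <= 0:
                raise ValueError(f"log-normal IIV requires {name} > 0")
            cols[name] = base * np.exp(np.sqrt(omega2) * z[:, j])
        # parameters without IIV are constant across subjects
        for name in u.parameter_names:
            if name not in cols:
                cols[name] = np.full(ns, values[name])
        individuals = pd.DataFrame(cols, columns=list(u.parameter_names))
        populations.append(PopulationParameters(pid, values, individuals))
    return PopulationEnsemble(populations, seed=int(seed), n_subj=n_subj)


def success_rate(model, pop: PopulationParameters, dose_pair,
                 target: EfficacyTarget) -> float:
    """Fraction of the population's subjects whose endpoint is a success.

    The subject sample is frozen inside ``pop``, so for a given ensemble
    the success-rate surface over doses is deterministic (common random
    numbers across all dose combinations).
    """
    d1, d2 = dose_pair
    if d1 < 0 or d2 < 0:
        raise ValueError("doses must be >= 0")
    params = {c: pop.individuals[c].to_numpy() for c in pop.individuals.columns}
    ok = model.success(params, float(d1), float(d2))
    return float(np.mean(ok))


def effective_dose_bisection(objective: Callable[[float], float],
                             target_rate: float, lo: float, hi: float,
                             n_iter: int) -> float:
    """Find the effective dose of a monotone 1D dose-response by bisection.

    Two evaluations validate the bracket, then ``n_iter`` halvings narrow
    it; the midpoint of the final bracket is returned, so the total number
    of objective evaluations is always ``n_iter + 2`` and the final bracket
    width is (hi - lo) / 2**n_iter.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    y_lo = objective(lo)
    y_hi = objective(hi)
    if y_lo >= target_rate:
        raise BracketError(
            "objective already meets the target at the lower bound "
            "(always efficacious within bounds)", "always_efficacious")
    if y_hi < target_rate:
        raise BracketError(
            "objective below the target at the upper bound "
            "(never efficacious within bounds)", "never_efficacious")
    for _ in range(n_iter):
        mid = (lo + hi) / 2.0
        if objective(mid) >= target_rate:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2.0


def confidence_from_effective_doses(eds: Sequence[float], query_doses) -> np.ndarray:
    """Confidence level at each query dose: fraction of effective doses <= d.

    The right-continuous empirical CDF of the effective-dose ensemble; a
    population contributes success at dose d iff its effective dose does
    not exceed d.
    """
    eds = np.asarray(eds, dtype=float)
    if eds.size == 0:
        raise ValueError("need at least one effective dose")
    eds = np.sort(eds)
    q = np.atleast_1d(np.asarray(query_doses, dtype=float))
    return np.searchsorted(eds, q, side="right") / eds.size


@dataclass
class MonotonicityReport:
    """Result of the brute-force monotonicity pre-check."""

    violations: list[tuple[tuple[float, float], tuple[float, float], float]]
    probe_values: np.ndarray
    tolerance: float

    @property
    def ok(self) -> bool:
        return not self.violations


def check_monotonicity(objective, axis1, axis2, tol: float = 1e-9
                       ) -> MonotonicityReport:
    """Probe a 2D objective on a small lattice for monotonicity violations.

    The isobole-refinement algorithm assumes one contour per level, which a
    surface non-decreasing in each dose guarantees. Every adjacent lattice
    pair where the value drops by more than ``tol`` as one dose increases is
    reported; run this on a few populations before committing to a large
    ensemble run.
    """
    ax1 = np.asarray(axis1, dtype=float)
    ax2 = np.asarray(axis2, dtype=float)
    if len(ax1) < 3 or len(ax2) < 3:
        raise ValueError("probe lattice must be at least 3x3")
    vals = np.array([[float(objective(a, b)) for b in ax2] for a in ax1])
    violations = []
    for i in range(len(ax1)):
        for j in range(len(ax2)):
            if i + 1 < len(ax1) and vals[i + 1, j] < vals[i, j] - tol:
                violations.append(((ax1[i], ax2[j]), (ax1[i + 1], ax2[j]),
                                   float(vals[i, j] - vals[i + 1, j])))
            if j + 1 < len(ax2) and vals[i, j + 1] < vals[i, j] - tol:
                violations.append(((ax1[i], ax2[j]), (ax1[i], ax2[j + 1]),
                                   float(vals[i, j] - vals[i, j + 1])))
    return MonotonicityReport(violations, vals, tol)


def rank_parameter_influence(ensemble: PopulationEnsemble,
                             failure_areas: Sequence[float]) -> pd.DataFrame:
    """Rank population parameters by influence on isobole location.

    ``failure_areas`` is one scalar isobole-location summary per population
    (the area of the failure polygon in normalized dose space; see
    ``aggregate.isobole_to_polygon``). For each population parameter, the
    Spearman rank correlation between the parameter draws and the summary
    is computed; the table is sorted by decreasing absolute correlation.
    Parameters that push the isobole outward (larger failure region) get
    positive correlations.
    """
    if ensemble.n_pop < 3:
        raise ValueError("parameter influence needs at least 3 populations")
    areas = np.asarray(failure_areas, dtype=float)
    if areas.size != ensemble.n_pop:
        raise ValueError("one isobole summary per population required")
    table = ensemble.parameter_table()
    rows = []
    for name in table.columns:
        x = table[name].to_numpy()
        if np.allclose(x, x[0]) or np.allclose(areas, areas[0]):
            rho = 0.0
        else:
            rho = float(spearmanr(x, areas).statistic)
        rows.append({"parameter": name, "spearman_rho": rho})
    df = pd.DataFrame(rows)
    return df.reindex(df.spearman_rho.abs().sort_values(ascending=False).index
                      ).reset_index(drop=True)
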