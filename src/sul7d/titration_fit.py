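"""Weighted nonlinear least-squares fitting of reverse quenching titrations.

Each model evaluation solves the implicit lattice-binding equation by
bisection for every titration point, then the outer damped least-squares
optimisation adjusts (K, n, Q_max) to minimise the weighted sum of squared
deviations between observed and predicted quenching.  Because K and n are
strongly correlated, the fit is repeated from a grid of starting values and
the best final residual wins (ties broken towards the smaller site size).

Parameters are optimised as (log K, log n, log Q_max), which keeps every
step inside the model's domain; bounds enforce n >= 1 and Q_max <= 1.
Standard errors come from the linearised covariance at the optimum scaled
by the residual variance, propagated to the (K_D, n, Q_max) scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .binding_model import (
    BindingModelError,
    BindingParameters,
    SolverError,
    TitrationExperiment,
    quenching_curve,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "InsufficientDataError",
    "NonIdentifiableError",
    "weighted_rss",
    "fit_titration",
]


class InsufficientDataError(ValueError):
    """Too few titration points to constrain (K, n, Q_max)."""


class NonIdentifiableError(RuntimeError):
    """No quenching signal or no start converged: the fit would be garbage."""


#: multistart grid: site sizes (nucleotides) x dissociation constants (M)
DEFAULT_N_STARTS = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
DEFAULT_KD_STARTS = (1e-6, 1e-5, 1e-4)


@dataclass
class FitOptions:
    """Tunables of the titration fit.

    ``weights`` is 'uniform', an explicit per-point array, or 'inverse_q'
    (1/max(Q_obs, floor), a crude variance model for quenching data).
    ``inner_tol`` is the relative bisection tolerance on P_b inside each
    model evaluation.
    """

    weights: str | Sequence[float] = "uniform"
    n_starts: Sequence[float] = DEFAULT_N_STARTS
    kd_starts: Sequence[float] = DEFAULT_KD_STARTS
    extra_starts: Sequence[BindingParameters] = field(default_factory=tuple)
    inner_tol: float = 1e-12
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-10
    max_nfev: int = 2000
    min_signal: float = 1e-3
    min_points: int = 5

    # bounds in natural-log space for (K [M^-1], n, Q_max)
    log_k_bounds: tuple[float, float] = (0.0, math.log(1e12))
    log_n_bounds: tuple[float, float] = (0.0, math.log(100.0))
    log_q_bounds: tuple[float, float] = (math.log(1e-4), 0.0)


@dataclass
class FitResult:
    """Point estimates, uncertainties and diagnostics of one titration fit."""

    params: BindingParameters
    kd_M: float
    se: dict[str, float]  # keys: kd_uM, n, q_max
    covariance: np.ndarray  # 3x3, (K_D [M], n, Q_max) scale
    rss: float
    n_points: int
    converged: bool
    n_starts_tried: int
    residuals: np.ndarray

    @property
    def kd_uM(self) -> float:
        return self.kd_M * 1e6

    def to_dict(self) -> dict:
        return {
            "kd_uM": self.kd_uM,
            "kd_se_uM": self.se["kd_uM"],
            "n_bases": self.params.n,
            "n_se": self.se["n"],
            "q_max": self.params.q_max,
            "q_max_se": self.se["q_max"],
            "rss": self.rss,
            "n_points": self.n_points,
            "converged": self.converged,
            "n_starts_tried": self.n_starts_tried,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def table_row(self, name: str = "") -> str:
        """One TSV row at the study's reporting precision (K_D integer uM, n one decimal)."""
        return (
            f"{name}\t{self.kd_uM:.0f} ± {self.se['kd_uM']:.0f}\t"
            f"{self.params.n:.1f} ± {self.se['n']:.1f}\t{self.params.q_max:.2f}"
        )


def _resolve_weights(options: FitOptions, q_obs: np.ndarray) -> np.ndarray:
    if isinstance(options.weights, str):
        if options.weights == "uniform":
            return np.ones_like(q_obs)
        if options.weights == "inverse_q":
            return 1.0 / np.maximum(q_obs, 0.05)
        raise ValueError(f"unknown weights scheme {options.weights!r}")
    w = np.asarray(options.weights, dtype=float)
    if w.shape != q_obs.shape:
        raise ValueError(
            f"weights length {w.size} does not match {q_obs.size} titration points"
        )
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative with at least one positive")
    return w


def weighted_rss(
    params: BindingParameters,
    experiment: TitrationExperiment,
    weights: Sequence[float] | None = None,
    inner_tol: float = 1e-12,
) -> float:
    """Weighted sum of squared quenching deviations for given parameters."""
    q_obs = experiment.quenching()
    if weights is None:
        w = np.ones_like(q_obs)
    else:
        w = _resolve_weights(FitOptions(weights=weights), q_obs)
    q_model = quenching_curve(params, experiment.p_total, experiment.d_totals, tol=inner_tol)
    return float(np.sum(w * (q_obs - q_model) ** 2))


def fit_titration(
    experiment: TitrationExperiment, options: FitOptions | None = None
) -> FitResult:
    """Estimate (K, n, Q_max) from a reverse titration.

    Multistart bounded least squares in log-parameter space with the
    bisection solve nested in every model evaluation.  Raises
    :class:`InsufficientDataError` below ``options.min_points`` points and
    :class:`NonIdentifiableError` when there is no quenching signal or no
    start produces a finite optimum.
    """
    opts = options or FitOptions()
    if len(experiment) < opts.min_points:
        raise InsufficientDataError(
            f"{len(experiment)} points < required minimum {opts.min_points}"
        )
    q_obs = experiment.quenching()
    d = experiment.d_totals
    p_t = experiment.p_total
    if np.nanmax(q_obs) < opts.min_signal:
        raise NonIdentifiableError(
            f"max observed quenching {np.nanmax(q_obs):.2g} below "
            f"{opts.min_signal}: no binding signal to fit"
        )
    w = _resolve_weights(opts, q_obs)
    sw = np.sqrt(w)

    lb = np.array([opts.log_k_bounds[0], opts.log_n_bounds[0], opts.log_q_bounds[0]])
    ub = np.array([opts.log_k_bounds[1], opts.log_n_bounds[1], opts.log_q_bounds[1]])

    def resid(x: np.ndarray) -> np.ndarray:
        params = BindingParameters(K=math.exp(x[0]), n=math.exp(x[1]), q_max=math.exp(x[2]))
        return sw * (q_obs - quenching_curve(params, p_t, d, tol=opts.inner_tol))

    q0 = float(np.clip(np.max(q_obs), 0.05, 1.0))
    starts = [
        np.array([math.log(1.0 / kd0), math.log(n0), math.log(q0)])
        for n0 in opts.n_starts
        for kd0 in opts.kd_starts
    ]
    starts += [
        np.array([math.log(p.K), math.log(p.n), math.log(p.q_max)])
        for p in opts.extra_starts
    ]

    candidates = []
    for x0 in starts:
        x0c = np.clip(x0, lb + 1e-12, ub - 1e-12)
        try:
            res = least_squares(
                resid,
                x0c,
                bounds=(lb, ub),
                method="trf",
                x_scale="jac",
                ftol=opts.ftol,
                xtol=opts.xtol,
                gtol=opts.gtol,
                max_nfev=opts.max_nfev,
            )
        except (SolverError, BindingModelError, FloatingPointError):
            continue
        if np.isfinite(res.cost):
            candidates.append(res)
    if not candidates:
        raise NonIdentifiableError("all multistart fits failed")

    best_rss = min(2.0 * r.cost for r in candidates)
    # ties on RSS (flat K-n ridge) resolved towards the smaller site size
    tied = [r for r in candidates if 2.0 * r.cost <= best_rss * (1 + 1e-9) + 1e-300]
    res = min(tied, key=lambda r: r.x[1])

    k, n, q_max = (math.exp(v) for v in res.x)
    params = BindingParameters(K=k, n=n, q_max=q_max)
    rss = 2.0 * res.cost
    n_pts = q_obs.size
    dof = max(n_pts - 3, 1)
    s2 = rss / dof
    jtj = res.jac.T @ res.jac
    cov_log = s2 * np.linalg.pinv(jtj)
    # delta method to (K_D, n, Q_max): K_D = exp(-x0), n = exp(x1), Q = exp(x2)
    grad = np.diag([-params.kd, n, q_max])
    cov = grad @ cov_log @ grad.T
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    se = {"kd_uM": sd[0] * 1e6, "n": sd[1], "q_max": sd[2]}

    return FitResult(
        params=params,
        kd_M=params.kd,
        se=se,
        covariance=cov,
        rss=rss,
        n_points=n_pts,
        converged=bool(res.status > 0),
        n_starts_tried=len(starts),
        residuals=res.fun / np.where(sw > 0, sw, 1.0),
    )
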