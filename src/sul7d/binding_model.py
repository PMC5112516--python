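"""Non-cooperative lattice-binding isotherm for Sul7d-type proteins on dsDNA.

Sul7d chromatin proteins bind double-stranded DNA without sequence
specificity, each bound protein occluding ``n`` contiguous nucleotides of the
DNA lattice.  The McGhee-von Hippel treatment of such binding relates the
binding density nu (bound proteins per nucleotide) and the free protein
concentration P_f through

    nu / P_f = K * (1 - n*nu) * [ (1 - n*nu) / (1 - (n-1)*nu) ]**(n-1)

where ``K`` is the intrinsic association constant (M^-1, on the
per-nucleotide lattice scale) and the bracketed factor accounts for the
overlap exclusion of potential binding sites.  In a reverse titration the
protein concentration P_t is fixed, DNA is added stepwise, and the occupancy
is read out as tryptophan fluorescence quenching

    Q_obs = (F_i - F_obs) / F_i,          Q = Q_max * P_b / P_t

with P_b the bound-protein concentration and Q_max the quenching at
saturation.  Given (K, n, Q_max) and a total nucleotide concentration D_t,
the bound concentration P_b is defined implicitly; this module solves that
implicit equation by bisection, the procedure used throughout the fitting
layer.

All DNA concentrations are molarity of *nucleotides* (ct-DNA quantified at
260 nm with epsilon = 6600 M^-1 cm^-1 per nucleotide), so the fitted site
size ``n`` is in nucleotides ("bases").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DNA_EXTINCTION_260",
    "PROTEIN_EXTINCTION_280",
    "BindingParameters",
    "LatticeBindingState",
    "TitrationPoint",
    "TitrationExperiment",
    "BindingModelError",
    "SolverError",
    "fractional_quenching",
    "mvh_residual",
    "solve_bound_protein",
    "solve_bound_curve",
    "closed_form_n1",
    "predict_quenching",
    "quenching_curve",
]

#: molar extinction coefficient of ct-DNA at 260 nm, per nucleotide (M^-1 cm^-1)
DNA_EXTINCTION_260 = 6600.0
#: molar extinction coefficient of the Sul7d constructs at 280 nm (M^-1 cm^-1)
PROTEIN_EXTINCTION_280 = 8250.0


class BindingModelError(ValueError):
    """Invalid parameters or inputs for the binding model."""


class SolverError(RuntimeError):
    """The bisection solve failed to bracket or converge; carries diagnostics."""


@dataclass(frozen=True)
class BindingParameters:
    """Parameters of the non-cooperative lattice isotherm.

    Attributes
    ----------
    K : float
        Association constant, M^-1, on the nucleotide-lattice scale.
    n : float
        Site size: nucleotides covered per bound protein.  Continuous,
        ``n >= 1`` (fits report values such as 6.4).
    q_max : float
        Maximum fractional fluorescence quenching at saturation of the
        protein, ``0 < q_max <= 1``.
    """

    K: float
    n: float
    q_max: float = 1.0

    def __post_init__(self) -> None:
        if not (self.K > 0 and np.isfinite(self.K)):
            raise BindingModelError(f"association constant K must be > 0, got {self.K}")
        if not (self.n >= 1 and np.isfinite(self.n)):
            raise BindingModelError(f"site size n must be >= 1, got {self.n}")
        if not (0 < self.q_max <= 1):
            raise BindingModelError(f"q_max must be in (0, 1], got {self.q_max}")

    @property
    def kd(self) -> float:
        """Dissociation constant K_D = 1/K, in M."""
        return 1.0 / self.K

    @property
    def kd_uM(self) -> float:
        """Dissociation constant in micromolar."""
        return 1e6 / self.K

    @classmethod
    def from_kd(cls, kd_M: float, n: float, q_max: float = 1.0) -> "BindingParameters":
        """Construct from a dissociation constant in M."""
        if not kd_M > 0:
            raise BindingModelError(f"K_D must be > 0, got {kd_M}")
        return cls(K=1.0 / kd_M, n=n, q_max=q_max)


@dataclass(frozen=True)
class LatticeBindingState:
    """Partition of protein between free solution and the DNA lattice.

    ``nu`` is the binding density (bound proteins per nucleotide); it is 0
    when no DNA is present.
    """

    p_bound: float
    p_free: float
    nu: float


@dataclass(frozen=True)
class TitrationPoint:
    """One addition step: total DNA (M nucleotides) and the measured signal."""

    d_total: float
    f_obs: float | None = None
    q_obs: float | None = None

    def __post_init__(self) -> None:
        if self.d_total < 0:
            raise BindingModelError(f"d_total must be >= 0, got {self.d_total}")
        if self.f_obs is None and self.q_obs is None:
            raise BindingModelError("a titration point needs f_obs or q_obs")


@dataclass
class TitrationExperiment:
    """A reverse titration: fixed protein, stepwise DNA additions.

    Attributes
    ----------
    p_total : float
        Total protein concentration, M (the study works at 5-6 uM).
    f_init : float
        Fluorescence at zero DNA, arbitrary units.
    points : list of TitrationPoint
        Ordered by strictly increasing ``d_total``.
    """

    p_total: float
    f_init: float
    points: list[TitrationPoint]
    buffer: str = "PBS"
    temperature_c: float = 25.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.p_total > 0:
            raise BindingModelError(f"p_total must be > 0, got {self.p_total}")
        if not self.f_init > 0:
            raise BindingModelError(f"f_init must be > 0, got {self.f_init}")
        d = np.asarray([p.d_total for p in self.points], dtype=float)
        if d.size and np.any(np.diff(d) <= 0):
            bad = np.nonzero(np.diff(d) <= 0)[0]
            raise BindingModelError(
                f"d_total must be strictly increasing; violated after rows {bad.tolist()}"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def d_totals(self) -> np.ndarray:
        return np.asarray([p.d_total for p in self.points], dtype=float)

    def quenching(self) -> np.ndarray:
        """Observed fractional quenching per point (Q_obs, computed from F if needed)."""
        out = np.empty(len(self.points))
        for i, p in enumerate(self.points):
            out[i] = (
                p.q_obs
                if p.q_obs is not None
                else fractional_quenching(self.f_init, p.f_obs)
            )
        return out


def fractional_quenching(f_init, f_obs):
    """Fractional fluorescence quenching Q_obs = (F_i - F_obs) / F_i.

    Small negative quenching values (F_obs marginally above F_i, instrument
    noise at the start of a titration) are clamped to 0 with a warning.
    Negative fluorescence is rejected.  Accepts scalars or arrays.
    """
    f_init = np.asarray(f_init, dtype=float)
    f_obs_arr = np.asarray(f_obs, dtype=float)
    if np.any(f_init <= 0):
        raise BindingModelError("f_init must be > 0")
    if np.any(f_obs_arr < 0):
        raise BindingModelError("negative fluorescence is not physical")
    q = (f_init - f_obs_arr) / f_init
    if np.any(q < 0):
        warnings.warn(
            "F_obs above F_i: negative quenching clamped to 0", stacklevel=2
        )
        q = np.maximum(q, 0.0)
    return float(q) if q.ndim == 0 else q


def _residual_arr(p_b, K, n, p_t, d_t):
    """Isotherm residual g(P_b), vectorised, no domain checks."""
    nu = p_b / d_t
    p_f = p_t - p_b
    one_m_n_nu = 1.0 - n * nu
    denom = 1.0 - (n - 1.0) * nu
    return nu / p_f - K * one_m_n_nu * (one_m_n_nu / denom) ** (n - 1.0)


def mvh_residual(p_b: float, params: BindingParameters, p_t: float, d_t: float) -> float:
    """Residual of the implicit lattice-binding equation at bound protein ``p_b``.

        g(P_b) = nu/P_f - K (1 - n nu) [(1 - n nu)/(1 - (n-1) nu)]^(n-1)

    with nu = P_b/D_t and P_f = P_t - P_b.  The physically meaningful root
    lies in the open bracket (0, min(P_t, D_t/n)), where g is continuous,
    negative as P_b -> 0+ (limit -K) and -> +inf at the upper end.
    """
    if d_t <= 0:
        raise BindingModelError("mvh_residual requires d_t > 0")
    ub = min(p_t, d_t / params.n)
    if not (0 < p_b < ub):
        raise BindingModelError(
            f"p_b={p_b} outside the open bracket (0, {ub}) for this lattice"
        )
    return float(_residual_arr(p_b, params.K, params.n, p_t, d_t))


def closed_form_n1(K: float, p_t: float, d_t: float) -> float:
    """Bound protein for site size n = 1 (independent nucleotide sites).

    With n = 1 the lattice equation reduces to simple 1:1 binding to D_t
    independent sites, whose bound concentration is the smaller root of

        P_b^2 - (P_t + D_t + 1/K) P_b + P_t D_t = 0.

    Evaluated in the numerically stable form 2c / (b + sqrt(b^2 - 4c)).
    Serves as the analytic oracle for the bisection solver.
    """
    if not (K > 0 and p_t > 0 and d_t >= 0):
        raise BindingModelError("closed_form_n1 requires K > 0, p_t > 0, d_t >= 0")
    if d_t == 0:
        return 0.0
    b = p_t + d_t + 1.0 / K
    c = p_t * d_t
    return 2.0 * c / (b + np.sqrt(b * b - 4.0 * c))


def solve_bound_curve(
    params: BindingParameters,
    p_t: float,
    d_t: Sequence[float] | np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> np.ndarray:
    """Bound-protein concentrations for an array of total-DNA values.

    Vectorised bisection on the implicit isotherm equation, one root per
    D_t value; D_t = 0 entries yield P_b = 0.  ``tol`` is relative on P_b.
    """
    d = np.asarray(d_t, dtype=float)
    if not p_t > 0:
        raise BindingModelError(f"p_t must be > 0, got {p_t}")
    if np.any(d < 0):
        raise BindingModelError("d_t must be >= 0")
    out = np.zeros_like(d)
    pos = d > 0
    if not np.any(pos):
        return out
    dp = d[pos]
    ub = np.minimum(p_t, dp / params.n)
    eps = 1e-15
    lo = ub * eps
    hi = ub * (1.0 - eps)
    g_lo = _residual_arr(lo, params.K, params.n, p_t, dp)
    g_hi = _residual_arr(hi, params.K, params.n, p_t, dp)
    if np.any(g_lo >= 0) or np.any(g_hi <= 0):
        raise SolverError(
            "failed to bracket the isotherm root: "
            f"g(lo) range [{g_lo.min():.3g}, {g_lo.max():.3g}], "
            f"g(hi) range [{g_hi.min():.3g}, {g_hi.max():.3g}], "
            f"bracket upper bounds [{ub.min():.3g}, {ub.max():.3g}] M"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        neg = _residual_arr(mid, params.K, params.n, p_t, dp) < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
        if np.all(hi - lo <= tol * hi):
            break
    out[pos] = 0.5 * (lo + hi)
    return out


def solve_bound_protein(
    params: BindingParameters,
    p_t: float,
    d_t: float,
    tol: float = 1e-12,
) -> LatticeBindingState:
    """Solve the implicit isotherm for bound protein at one DNA concentration.

    Returns the unique root of :func:`mvh_residual` in
    (0, min(P_t, D_t/n)) by bisection, to relative tolerance ``tol`` on
    P_b.  ``d_t = 0`` returns the empty-lattice state (P_b = 0, nu = 0).
    """
    if d_t == 0:
        return LatticeBindingState(p_bound=0.0, p_free=p_t, nu=0.0)
    p_b = float(solve_bound_curve(params, p_t, np.array([d_t]), tol=tol)[0])
    return LatticeBindingState(p_bound=p_b, p_free=p_t - p_b, nu=p_b / d_t)


def quenching_curve(
    params: BindingParameters,
    p_t: float,
    d_t: Sequence[float] | np.ndarray,
    tol: float = 1e-12,
) -> np.ndarray:
    """Model quenching Q = Q_max * P_b / P_t for an array of D_t values."""
    return params.q_max * solve_bound_curve(params, p_t, d_t, tol=tol) / p_t


def predict_quenching(
    params: BindingParameters, p_t: float, d_t: float, tol: float = 1e-12
) -> float:
    """Model quenching at one DNA concentration; in [0, Q_max], monotone in D_t and K."""
    state = solve_bound_protein(params, p_t, d_t, tol=tol)
    return params.q_max * state.p_bound / p_t
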