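"""Three-body binding equilibrium for heterobifunctional degraders.

A PROTAC (P) engages an E3 ligase (L) through one ligand and a target
protein (T) through the other, so the solution equilibrium involves three
free species and three complexes (LP, TP and the ternary complex LPT).
The ternary complex is governed by three mass-action laws::

    [LP]  = [L][P] / K_LP
    [TP]  = [T][P] / K_TP
    [LPT] = alpha * [L][T][P] / (K_LP * K_TP)

where ``alpha = K_LP / K_LPT`` is the cooperativity: alpha > 1 means the
target's presence strengthens PROTAC-ligase engagement through favourable
protein-protein contacts.  The coupled system has no closed form, but the
total-PROTAC conservation residual is strictly monotone in free [P], so the
exact state is recovered by scalar root-finding.

All concentrations are in nM throughout; convert at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EquilibriumParams",
    "SpeciesState",
    "cooperativity",
    "beta_factor",
    "spr_occupancy",
    "max_ternary_fraction",
    "binary_complex_conc",
    "solve_ternary_equilibrium",
    "hook_curve",
]

#: Target excess over K_TP used to hold the binary complex together in the
#: SPR flow cell; enters the beta factor denominator.
DEFAULT_TARGET_EXCESS = 25.0


class EquilibriumError(ValueError):
    """Raised for invalid binding parameters or concentrations."""


class ConvergenceError(RuntimeError):
    """Raised when the equilibrium root-find fails to converge."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise EquilibriumError(f"{name} must be finite and > 0, got {value!r}")


def _require_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0 or not math.isfinite(value):
            raise EquilibriumError(f"{name} must be finite and >= 0, got {value!r}")


def cooperativity(k_lp: float, k_lpt: float) -> float:
    """Cooperativity alpha = K_LP / K_LPT.

    The ratio of the binary ligase-PROTAC dissociation constant to the
    ternary one.  Values above 1 indicate that target engagement
    stabilises PROTAC binding to the ligase.
    """
    _require_positive(k_lp=k_lp, k_lpt=k_lpt)
    return k_lp / k_lpt


def beta_factor(k_lp: float, k_tp: float, target_excess: float = DEFAULT_TARGET_EXCESS) -> float:
    """Binary-affinity factor beta = (sqrt(K_LP/K_TP) + 1)^2 / target_excess.

    Summarises how the two binary affinities limit the maximal ternary
    fraction achievable on an SPR surface when the target is held at
    ``target_excess``-fold over K_TP (default 25).
    """
    _require_positive(k_lp=k_lp, k_tp=k_tp, target_excess=target_excess)
    return (math.sqrt(k_lp / k_tp) + 1.0) ** 2 / target_excess


def spr_occupancy(p_total: float, k_lpt: float) -> float:
    """Fraction of surface ligase in ternary complex at PROTAC dose ``p_total``.

    With excess preformed target-PROTAC binary complex flowed over an
    immobilised ligase, the surface behaves as a one-site isotherm:
    [LPT]/[L]_t = [P]_t / ([P]_t + K_LPT).  Half-saturation at
    [P]_t = K_LPT defines the ternary dissociation constant.
    """
    _require_positive(k_lpt=k_lpt)
    _require_nonnegative(p_total=p_total)
    return p_total / (p_total + k_lpt)


def max_ternary_fraction(alpha: float, beta: float) -> float:
    """Maximal ternary fraction [LPT]_max/[L]_t ≈ alpha / (alpha + beta).

    The peak of the bell-shaped ternary-complex response over PROTAC dose,
    under the SPR surface constraint.  Increasing cooperativity drives the
    fraction toward 1; larger beta (weak relative binary affinity) demands
    more cooperativity to reach the same fraction.
    """
    _require_positive(alpha=alpha, beta=beta)
    return alpha / (alpha + beta)


def binary_complex_conc(p_total: float, t_total: float, k_tp: float) -> float:
    """Exact binary complex [TP] from the tight-binding quadratic.

    [TP] = ((P+T+K) - sqrt((P+T+K)^2 - 4 P T)) / 2, evaluated in a
    cancellation-safe factored form so the weak- and tight-binding limits
    are both accurate.
    """
    _require_positive(k_tp=k_tp)
    _require_nonnegative(p_total=p_total, t_total=t_total)
    s = p_total + t_total + k_tp
    # (s^2 - 4PT) stays positive; sqrt via stable rearrangement
    disc = (p_total - t_total) ** 2 + k_tp * k_tp + 2.0 * k_tp * (p_total + t_total)
    root = math.sqrt(disc)
    # (s - root) = 4PT / (s + root): avoids catastrophic cancellation
    return 2.0 * p_total * t_total / (s + root)


@dataclass(frozen=True)
class EquilibriumParams:
    """Binding parameters for one ligase/PROTAC/target system (nM).

    Either ``k_lpt`` or ``alpha`` may be given; the other is derived.
    ``beta`` is always derived from the binary constants.
    """

    k_lp: float
    k_tp: float
    k_lpt: float | None = None
    alpha: float | None = None
    target_excess: float = DEFAULT_TARGET_EXCESS
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        _require_positive(k_lp=self.k_lp, k_tp=self.k_tp)
        if self.k_lpt is None and self.alpha is None:
            raise EquilibriumError("provide k_lpt or alpha")
        if self.k_lpt is None:
            _require_positive(alpha=self.alpha)
            object.__setattr__(self, "k_lpt", self.k_lp / self.alpha)
        elif self.alpha is None:
            _require_positive(k_lpt=self.k_lpt)
            object.__setattr__(self, "alpha", self.k_lp / self.k_lpt)
        else:
            _require_positive(k_lpt=self.k_lpt, alpha=self.alpha)
            if not math.isclose(self.alpha, self.k_lp / self.k_lpt, rel_tol=1e-9):
                raise EquilibriumError(
                    f"inconsistent parameters: alpha={self.alpha} but "
                    f"K_LP/K_LPT={self.k_lp / self.k_lpt}"
                )
        object.__setattr__(
            self, "beta", beta_factor(self.k_lp, self.k_tp, self.target_excess)
        )

    def max_ternary_fraction(self) -> float:
        return max_ternary_fraction(self.alpha, self.beta)


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations (nM) of every species at equilibrium."""

    l_total: float
    t_total: float
    p_total: float
    l_free: float
    t_free: float
    p_free: float
    lp: float
    tp: float
    lpt: float

    def check_conservation(self, rtol: float = 1e-8) -> None:
        """Raise if mass conservation is violated beyond ``rtol``."""
        checks = (
            ("L", self.l_free + self.lp + self.lpt, self.l_total),
            ("T", self.t_free + self.tp + self.lpt, self.t_total),
            ("P", self.p_free + self.lp + self.tp + self.lpt, self.p_total),
        )
        for name, got, want in checks:
            if abs(got - want) > rtol * max(want, 1e-300):
                raise EquilibriumError(
                    f"{name} conservation violated: {got} != {want}"
                )


def _free_lt_given_p(
    p_free: float, l_total: float, t_total: float, params: EquilibriumParams
) -> tuple[float, float]:
    """Free [L], [T] at fixed free [P], from the 2x2 mass-action system.

    Substituting L = L_t/(a1 + c T) into the T-conservation law gives a
    quadratic in free T with exactly one positive root.
    """
    a1 = 1.0 + p_free / params.k_lp
    a2 = 1.0 + p_free / params.k_tp
    c = params.alpha * p_free / (params.k_lp * params.k_tp)
    if c == 0.0:
        return l_total / a1, t_total / a2
    # a2*c*T^2 + (a1*a2 + c*(L_t - T_t))*T - a1*T_t = 0
    qa = a2 * c
    qb = a1 * a2 + c * (l_total - t_total)
    qc = -a1 * t_total
    # stable positive root
    disc = math.sqrt(qb * qb - 4.0 * qa * qc)
    if qb >= 0.0:
        t_free = 2.0 * (-qc) / (qb + disc)
    else:
        t_free = (-qb + disc) / (2.0 * qa)
    l_free = l_total / (a1 + c * t_free)
    return l_free, t_free


def _state_at_p(
    p_free: float, l_total: float, t_total: float, p_total: float,
    params: EquilibriumParams,
) -> SpeciesState:
    l_free, t_free = _free_lt_given_p(p_free, l_total, t_total, params)
    lp = l_free * p_free / params.k_lp
    tp = t_free * p_free / params.k_tp
    lpt = params.alpha * l_free * t_free * p_free / (params.k_lp * params.k_tp)
    return SpeciesState(
        l_total=l_total, t_total=t_total, p_total=p_total,
        l_free=l_free, t_free=t_free, p_free=p_free, lp=lp, tp=tp, lpt=lpt,
    )


def solve_ternary_equilibrium(
    l_total: float,
    t_total: float,
    p_total: float,
    params: EquilibriumParams,
    *,
    rtol: float = 1e-13,
    maxiter: int = 200,
) -> SpeciesState:
    """Exact numerical solution of the three-body binding equilibrium.

    The PROTAC conservation residual
    ``g(P) = P + [LP] + [TP] + [LPT] - P_t`` is strictly increasing in
    free P on [0, P_t] (every bound term grows with free P), so bracketed
    root-finding gives the unique physical state.

    Degenerate totals (any total zero) short-circuit to the closed-form
    binary or empty solution.
    """
    _require_nonnegative(l_total=l_total, t_total=t_total, p_total=p_total)
    if p_total == 0.0:
        return SpeciesState(l_total, t_total, 0.0, l_total, t_total,
                            0.0, 0.0, 0.0, 0.0)
    if l_total == 0.0 and t_total == 0.0:
        return SpeciesState(0.0, 0.0, p_total, 0.0, 0.0, p_total, 0.0, 0.0, 0.0)
    if l_total == 0.0:
        tp = binary_complex_conc(p_total, t_total, params.k_tp)
        return SpeciesState(0.0, t_total, p_total, 0.0, t_total - tp,
                            p_total - tp, 0.0, tp, 0.0)
    if t_total == 0.0:
        lp = binary_complex_conc(p_total, l_total, params.k_lp)
        return SpeciesState(l_total, 0.0, p_total, l_total - lp, 0.0,
                            p_total - lp, lp, 0.0, 0.0)

    def residual(p_free: float) -> float:
        st = _state_at_p(p_free, l_total, t_total, p_total, params)
        return st.p_free + st.lp + st.tp + st.lpt - p_total

    lo, hi = 0.0, p_total
    try:
        p_free = brentq(residual, lo, hi, xtol=rtol * p_total,
                        rtol=4 * np.finfo(float).eps, maxiter=maxiter)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
        raise ConvergenceError(
            f"equilibrium root-find failed for totals "
            f"(L={l_total}, T={t_total}, P={p_total}): {exc}"
        ) from exc
    # In tight-binding regimes the root sits orders of magnitude below
    # P_t, where the absolute bracketing tolerance under-resolves the
    # very steep residual; polish to relative precision with secant steps.
    if p_free > 0.0:
        x0, x1 = p_free, p_free * (1.0 + 1e-7)
        f0, f1 = residual(x0), residual(x1)
        for _ in range(60):
            if f1 == f0:
                break
            x2 = x1 - f1 * (x1 - x0) / (f1 - f0)
            if not (0.0 < x2 <= p_total) or not math.isfinite(x2):
                break
            x0, f0, x1 = x1, f1, x2
            f1 = residual(x1)
            if abs(x1 - x0) <= 4 * np.finfo(float).eps * x1:
                break
        if abs(f1) < abs(residual(p_free)):
            p_free = x1
    state = _state_at_p(p_free, l_total, t_total, p_total, params)
    state.check_conservation(rtol=1e-8)
    return state


def hook_curve(
    l_total: float,
    t_total: float,
    p_grid: Sequence[float],
    params: EquilibriumParams,
) -> np.ndarray:
    """Ternary complex [LPT] across a PROTAC titration.

    Reproduces the bell-shaped ("hook effect") dose dependence: the
    ternary complex rises with dose and then collapses when excess PROTAC
    saturates both proteins as separate binary complexes.
    """
    grid = np.asarray(p_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise EquilibriumError("p_grid must be a non-empty 1-D sequence")
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise EquilibriumError("p_grid must be non-negative and strictly increasing")
    return np.array([
        solve_ternary_equilibrium(l_total, t_total, p, params).lpt for p in grid
    ])
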