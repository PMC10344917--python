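"""Initial-rate model for PROTAC-induced target ubiquitination.

Under rapid-equilibrium assumptions the initial ubiquitination rate is set
by the fraction of ligase engaged in ternary complex, giving

    v = V_max / [ (1 - K_LPT/K_LP) + (1 + [P]_t/K_LP) * 2 K_LPT / D ]

with D = ([P]_t + [T]_t + K_TP) - sqrt(([P]_t + [T]_t + K_TP)^2 - 4 [P]_t [T]_t),
and V_max the product of the ternary-complex breakdown rate constant and
total ligase concentration.  Substituting alpha = K_LP/K_LPT yields the
equivalent normalized form

    v/V_max = alpha / ( alpha + 2 (K_LP + [P]_t) / D - 1 )

whose two characteristic regimes are a linear rise at low dose,
v/V_max ≈ [P]_t / (2 K_LPT), and a cooperativity-controlled plateau/decay
at saturating dose, v/V_max ≈ alpha [T]_t / (2 [P]_t).

Note on the saturation formula: the printed approximation carries a factor
1/2 relative to the exact P_t → ∞ limit of the normalized rate (which is
alpha*T_t/P_t); both are kept — ``saturation_regime_rate`` implements the
approximation verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .equilibrium import EquilibriumParams, EquilibriumError

__all__ = [
    "RateModelInputs",
    "ubiquitination_rate",
    "normalized_rate",
    "linear_regime_rate",
    "saturation_regime_rate",
]


def _tp_denominator(p_total: float, t_total: float, k_tp: float) -> float:
    """D = (P+T+K) - sqrt((P+T+K)^2 - 4PT), computed without cancellation.

    For large P the naive difference loses all significant digits; the
    factored form D = 4PT / ((P+T+K) + sqrt(...)) is exact in both limits.
    """
    s = p_total + t_total + k_tp
    disc = (p_total - t_total) ** 2 + k_tp * k_tp + 2.0 * k_tp * (p_total + t_total)
    return 4.0 * p_total * t_total / (s + math.sqrt(disc))


@dataclass(frozen=True)
class RateModelInputs:
    """Inputs for one rate evaluation: totals (nM), binding params, V_max."""

    p_total: float
    t_total: float
    params: EquilibriumParams
    v_max: float = 1.0

    def __post_init__(self) -> None:
        if not (self.v_max > 0):
            raise EquilibriumError(f"v_max must be > 0, got {self.v_max!r}")
        if self.p_total < 0 or self.t_total < 0:
            raise EquilibriumError("totals must be non-negative")


def normalized_rate(
    p_total: float, t_total: float, k_lp: float, k_tp: float, alpha: float
) -> float:
    """Normalized ubiquitination initial rate v/V_max, in (0, 1).

    Zero dose or zero target returns the analytic limit 0.
    """
    if k_lp <= 0 or k_tp <= 0 or alpha <= 0:
        raise EquilibriumError("k_lp, k_tp and alpha must be > 0")
    if p_total < 0 or t_total < 0:
        raise EquilibriumError("totals must be non-negative")
    if p_total == 0.0 or t_total == 0.0:
        return 0.0
    d = _tp_denominator(p_total, t_total, k_tp)
    return alpha / (alpha + 2.0 * (k_lp + p_total) / d - 1.0)


def ubiquitination_rate(inputs: RateModelInputs) -> float:
    """Absolute ubiquitination initial rate v (units of V_max).

    Evaluates the full rapid-equilibrium expression in K_LPT form; it is
    algebraically identical to ``v_max * normalized_rate``.
    """
    p = inputs.params
    if inputs.p_total == 0.0 or inputs.t_total == 0.0:
        return 0.0
    d = _tp_denominator(inputs.p_total, inputs.t_total, p.k_tp)
    denom = (1.0 - p.k_lpt / p.k_lp) + (1.0 + inputs.p_total / p.k_lp) * 2.0 * p.k_lpt / d
    return inputs.v_max / denom


def linear_regime_rate(p_total: float, k_lpt: float) -> float:
    """Low-dose limit: v/V_max ≈ [P]_t / (2 K_LPT).

    Valid when [P]_t is far below [T]_t, K_LP and K_TP; in this regime
    potency tracks ternary-complex affinity.
    """
    if p_total <= 0 or k_lpt <= 0:
        raise EquilibriumError("p_total and k_lpt must be > 0")
    return p_total / (2.0 * k_lpt)


def saturation_regime_rate(alpha: float, t_total: float, p_total: float) -> float:
    """High-dose approximation: v/V_max ≈ alpha [T]_t / (2 [P]_t), verbatim.

    In this regime the rate is set by cooperativity.  The exact asymptote
    of the full model is alpha*T_t/P_t (twice this value); the printed
    approximation is kept as-is and the discrepancy is documented.
    """
    if alpha <= 0 or t_total <= 0 or p_total <= 0:
        raise EquilibriumError("all inputs must be > 0")
    return alpha * t_total / (2.0 * p_total)
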