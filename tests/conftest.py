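import numpy as np
import pytest

from ternary_sar.equilibrium import EquilibriumParams
from ternary_sar.synthetic import load_paper_tables


@pytest.fixture(scope="session")
def paper_tables():
    return load_paper_tables()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def brute_force_equilibrium(l_total, t_total, p_total, params: EquilibriumParams,
                            tol=1e-14, inner_iters=400):
    """Independent oracle: bisection on free P with damped fixed-point
    iteration for free L and T at each trial P.

    Deliberately avoids the quadratic closed form used by the solver.
    """
    k_lp, k_tp, alpha = params.k_lp, params.k_tp, params.alpha

    def free_lt(p):
        l, t = l_total, t_total
        for _ in range(inner_iters):
            l_new = l_total / (1 + p / k_lp + alpha * p * t / (k_lp * k_tp))
            t_new = t_total / (1 + p / k_tp + alpha * p * l / (k_lp * k_tp))
            l = 0.5 * (l + l_new)
            t = 0.5 * (t + t_new)
        return l, t

    def residual(p):
        l, t = free_lt(p)
        lp = l * p / k_lp
        tp = t * p / k_tp
        lpt = alpha * l * t * p / (k_lp * k_tp)
        return p + lp + tp + lpt - p_total

    lo, hi = 0.0, p_total
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol * p_total:
            break
    p = 0.5 * (lo + hi)
    l, t = free_lt(p)
    return {
        "L": l, "T": t, "P": p,
        "LP": l * p / k_lp, "TP": t * p / k_tp,
        "LPT": alpha * l * t * p / (k_lp * k_tp),
    }
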