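"""Structure-activity correlation analysis over compound-level parameters.

Pairs biophysical ternary-complex attributes (K_LPT, cooperativity alpha,
SPR half-life) with cellular degradation readouts (AUC, DC50, initial
degradation rate) per target domain and reports Pearson r or Spearman rho
with two-tailed significance.  Affinity and cooperativity span orders of
magnitude, so each axis can be analysed on a linear or log10 scale; the
scale convention is configuration, recorded per pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CompoundRecord",
    "CorrelationResult",
    "CorrelationError",
    "pearson",
    "spearman",
    "build_sar_table",
    "DEFAULT_PAIRS",
]

VALID_SCALES = ("linear", "log10")


class CorrelationError(ValueError):
    """Undefined correlation (zero variance, too few points, bad scale)."""


@dataclass(frozen=True)
class CompoundRecord:
    """One compound's merged biophysical and cellular parameters.

    ``dc50_nM`` may carry a censoring bound instead of a value (e.g. the
    titration never reached 50 POC); censored entries are excluded from
    correlations by default.  ``alpha`` is validated against K_LP/K_LPT
    with a tolerance absorbing table rounding.
    """

    compound_id: str
    target_domain: str
    k_lp_nM: float | None = None
    k_lpt_nM: float | None = None
    alpha: float | None = None
    auc: float | None = None
    dc50_nM: float | None = None
    dc50_censored_above_nM: float | None = None
    dmax: float | None = None
    initial_rate: float | None = None
    t_half_spr_s: float | None = None
    k_lpt_approximate: bool = False

    def __post_init__(self) -> None:
        if (
            self.alpha is not None
            and self.k_lp_nM is not None
            and self.k_lpt_nM is not None
            and not self.k_lpt_approximate
        ):
            implied = self.k_lp_nM / self.k_lpt_nM
            # 3% absorbs rounding of all three printed values
            if abs(implied - self.alpha) > 0.03 * max(self.alpha, implied) and (
                abs(implied - self.alpha) > 0.05
            ):
                raise CorrelationError(
                    f"{self.compound_id}: alpha={self.alpha} inconsistent with "
                    f"K_LP/K_LPT={implied:.3g}"
                )

    def value(self, name: str, *, include_censored: bool = False) -> float | None:
        if name == "dc50_nM" and self.dc50_nM is None:
            if include_censored and self.dc50_censored_above_nM is not None:
                return self.dc50_censored_above_nM
            return None
        return getattr(self, name)


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p_value: float
    n: int
    method: str
    x_scale: str = "linear"
    y_scale: str = "linear"
    x_name: str = "x"
    y_name: str = "y"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.coefficient <= 1.0 + 1e-12:
            raise CorrelationError("coefficient outside [-1, 1]")

    def rounded(self, digits: int = 2) -> float:
        """Coefficient at reporting precision (2 decimals by convention)."""
        return round(self.coefficient, digits)


def _transform(values: Sequence[float], scale: str, name: str) -> np.ndarray:
    arr = np.asarray(values, float)
    if scale not in VALID_SCALES:
        raise CorrelationError(f"unknown scale {scale!r} for {name}")
    if scale == "log10":
        if np.any(arr <= 0):
            raise CorrelationError(f"log10 scale for {name} requires positive values")
        arr = np.log10(arr)
    return arr


def pearson(
    x: Sequence[float],
    y: Sequence[float],
    x_scale: str = "linear",
    y_scale: str = "linear",
    *,
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationResult:
    """Pearson product-moment correlation with two-tailed t-test p-value."""
    xv = _transform(x, x_scale, x_name)
    yv = _transform(y, y_scale, y_name)
    if xv.size != yv.size or xv.size < 3:
        raise CorrelationError("need >= 3 matched observations")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise CorrelationError("zero variance: correlation undefined")
    r, p = stats.pearsonr(xv, yv)
    return CorrelationResult(float(r), float(p), int(xv.size), "pearson",
                             x_scale, y_scale, x_name, y_name)


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    *,
    exact: bool = False,
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties), two-tailed.

    ``exact=True`` computes the permutation p-value by full enumeration
    (feasible for n <= 10); otherwise the t approximation is used.
    Rank correlation is scale-free, so no transform options exist.
    """
    xv = np.asarray(x, float)
    yv = np.asarray(y, float)
    if xv.size != yv.size or xv.size < 3:
        raise CorrelationError("need >= 3 matched observations")
    xr = stats.rankdata(xv)
    yr = stats.rankdata(yv)
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        raise CorrelationError("zero rank variance: correlation undefined")
    rho, p = stats.spearmanr(xv, yv)
    if exact:
        if xv.size > 10:
            raise CorrelationError("exact permutation p only for n <= 10")
        observed = abs(rho)
        count = total = 0
        for perm in permutations(yr):
            r_perm = stats.pearsonr(xr, np.asarray(perm)).statistic
            total += 1
            if abs(r_perm) >= observed - 1e-12:
                count += 1
        p = count / total
    return CorrelationResult(float(rho), float(p), int(xv.size), "spearman",
                             "rank", "rank", x_name, y_name)


@dataclass(frozen=True)
class PairSpec:
    """One requested correlation: fields of CompoundRecord plus scales."""

    x: str
    y: str
    x_scale: str = "linear"
    y_scale: str = "linear"
    method: str = "pearson"


#: The scatter analyses run on the compound tables: affinity and
#: cooperativity against AUC, DC50 and the initial degradation rate.
#: Scales are the ones that reproduce the printed coefficients.
DEFAULT_PAIRS: tuple[PairSpec, ...] = (
    PairSpec("k_lpt_nM", "auc"),
    PairSpec("k_lpt_nM", "dc50_nM"),
    PairSpec("alpha", "initial_rate", x_scale="log10"),
    PairSpec("k_lpt_nM", "initial_rate"),
    PairSpec("t_half_spr_s", "initial_rate", x_scale="log10"),
)


def build_sar_table(
    records: Iterable[CompoundRecord],
    pairs: Sequence[PairSpec] = DEFAULT_PAIRS,
    *,
    include_censored: bool = False,
) -> dict[str, dict[str, CorrelationResult | str]]:
    """Correlation report per target domain and requested pair.

    Pairs with fewer than 3 complete records are skipped with a recorded
    reason instead of failing the whole report.
    """
    by_domain: dict[str, list[CompoundRecord]] = {}
    for rec in records:
        by_domain.setdefault(rec.target_domain, []).append(rec)

    report: dict[str, dict[str, CorrelationResult | str]] = {}
    for domain, recs in by_domain.items():
        row: dict[str, CorrelationResult | str] = {}
        for pair in pairs:
            xs, ys = [], []
            for rec in recs:
                xv = rec.value(pair.x, include_censored=include_censored)
                yv = rec.value(pair.y, include_censored=include_censored)
                if xv is not None and yv is not None:
                    xs.append(xv)
                    ys.append(yv)
            key = f"{pair.x}~{pair.y}"
            if len(xs) < 3:
                row[key] = f"skipped: only {len(xs)} complete records"
                continue
            try:
                if pair.method == "pearson":
                    row[key] = pearson(xs, ys, pair.x_scale, pair.y_scale,
                                       x_name=pair.x, y_name=pair.y)
                else:
                    row[key] = spearman(xs, ys, x_name=pair.x, y_name=pair.y)
            except CorrelationError as exc:
                row[key] = f"skipped: {exc}"
        report[domain] = row
    return report
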