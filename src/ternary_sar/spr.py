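"""SPR sensorgram simulation and fitting (1:1 Langmuir model).

Covers the two assay formats used for degrader characterisation: binary
(PROTAC over immobilised ligase, multi-cycle with regeneration between
cycles) and ternary (preformed target-PROTAC mix over a low-density ligase
surface, single-cycle without regeneration).  With the target held in
saturating excess, ternary-complex formation on the chip reduces to a 1:1
pseudo-first-order interaction in PROTAC concentration, so both formats
are fitted with the same model.

The 1:1 binding ODE has a closed-form solution per injection phase:

    association  (analyte C):  R(t) = Req + (R0 - Req) * exp(-(kon*C + koff) t),
                               Req = C * Rmax / (C + KD)
    dissociation:              R(t) = R0 * exp(-koff t)

Fits use these analytic expressions directly.  Complex stability is
summarised as t_half = ln 2 / koff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "Injection",
    "Sensorgram",
    "KineticFit",
    "SteadyStateFit",
    "FitFailure",
    "simulate_sensorgram",
    "fit_langmuir",
    "fit_steady_state",
    "reference_subtract",
]


class SensorgramError(ValueError):
    """Invalid sensorgram structure (grid, schedule)."""


class FitFailure(RuntimeError):
    """Raised when a fit is non-identifiable or does not converge.

    Carries a human-readable reason rather than crashing mid-pipeline.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class Injection:
    start_s: float
    stop_s: float
    conc_nM: float

    def __post_init__(self) -> None:
        if not (self.stop_s > self.start_s):
            raise SensorgramError("injection stop must follow start")
        if self.conc_nM < 0:
            raise SensorgramError("analyte concentration must be >= 0")


@dataclass(frozen=True)
class Sensorgram:
    """One SPR time series (RU vs s) with its injection schedule.

    ``mode`` is ``"multi-cycle"`` (surface regenerated before each
    injection: response resets to 0) or ``"single-cycle"`` (injections
    applied sequentially without regeneration).
    """

    time_s: np.ndarray
    response_ru: np.ndarray
    injections: tuple[Injection, ...]
    mode: str = "multi-cycle"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, float)
        r = np.asarray(self.response_ru, float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "response_ru", r)
        if t.ndim != 1 or t.shape != r.shape:
            raise SensorgramError("time and response must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise SensorgramError("time must be strictly increasing")
        if self.mode not in ("multi-cycle", "single-cycle"):
            raise SensorgramError(f"unknown mode {self.mode!r}")
        inj = sorted(self.injections, key=lambda i: i.start_s)
        for a, b in zip(inj, inj[1:]):
            if b.start_s < a.stop_s:
                raise SensorgramError("injections overlap")
        if inj and (inj[0].start_s < t[0] or inj[-1].stop_s > t[-1]):
            raise SensorgramError("injections outside the time range")
        object.__setattr__(self, "injections", tuple(inj))

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV layout: time_s, response_ru, conc_nM, cycle, phase."""
        conc = np.zeros_like(self.time_s)
        cycle = np.zeros(self.time_s.size, dtype=int)
        phase = np.full(self.time_s.size, "dissoc", dtype=object)
        for k, inj in enumerate(self.injections, start=1):
            assoc = (self.time_s >= inj.start_s) & (self.time_s < inj.stop_s)
            conc[assoc] = inj.conc_nM
            cycle[self.time_s >= inj.start_s] = k
            phase[assoc] = "assoc"
        return pd.DataFrame(
            {"time_s": self.time_s, "response_ru": self.response_ru,
             "conc_nM": conc, "cycle": cycle, "phase": phase}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mode: str = "multi-cycle") -> "Sensorgram":
        t = df["time_s"].to_numpy(float)
        injections = []
        for _, grp in df[df["phase"] == "assoc"].groupby("cycle"):
            injections.append(Injection(
                start_s=float(grp["time_s"].iloc[0]),
                stop_s=float(grp["time_s"].iloc[-1]) + float(np.median(np.diff(t))),
                conc_nM=float(grp["conc_nM"].iloc[0]),
            ))
        return cls(t, df["response_ru"].to_numpy(float), tuple(injections), mode=mode)


@dataclass(frozen=True)
class KineticFit:
    """1:1 Langmuir kinetic parameters.

    kon in 1/(nM s), koff in 1/s; KD = koff/kon (nM) and
    t_half = ln2/koff (s) are derived, never fitted independently.
    """

    kon: float
    koff: float
    rmax: float
    residual_rmse: float = 0.0

    @property
    def kd(self) -> float:
        return self.koff / self.kon

    @property
    def t_half(self) -> float:
        return math.log(2.0) / self.koff

    def as_dict(self) -> dict:
        return {
            "kon": self.kon, "koff": self.koff, "kd_nM": self.kd,
            "rmax_ru": self.rmax, "t_half_s": self.t_half,
            "rmse_ru": self.residual_rmse,
        }


@dataclass(frozen=True)
class SteadyStateFit:
    kd_nM: float
    rmax_ru: float
    residual_rmse: float = 0.0


def _model_response(
    time_s: np.ndarray,
    injections: tuple[Injection, ...],
    kon: float,
    koff: float,
    rmax: float,
    mode: str,
) -> np.ndarray:
    """Piecewise closed-form 1:1 response over an injection schedule."""
    out = np.zeros_like(time_s, dtype=float)
    if not injections:
        return out
    kd = koff / kon

    def segment(mask, t0, r0, conc):
        t = time_s[mask] - t0
        if conc > 0:
            req = conc * rmax / (conc + kd)
            out[mask] = req + (r0 - req) * np.exp(-(kon * conc + koff) * t)
        else:
            out[mask] = r0 * np.exp(-koff * t)

    boundaries = []
    for inj in injections:
        boundaries.append((inj.start_s, inj.conc_nM))
        boundaries.append((inj.stop_s, 0.0))
    boundaries.append((time_s[-1] + 1.0, 0.0))

    r_carry = 0.0
    for (t0, conc), (t1, _) in zip(boundaries, boundaries[1:]):
        if mode == "multi-cycle" and conc > 0:
            r_carry = 0.0  # regenerated surface before each cycle
        mask = (time_s >= t0) & (time_s < t1)
        if mask.any():
            segment(mask, t0, r_carry, conc)
        # propagate the boundary value analytically (grid-independent)
        dt = t1 - t0
        if conc > 0:
            req = conc * rmax / (conc + kd)
            r_carry = req + (r_carry - req) * math.exp(-(kon * conc + koff) * dt)
        else:
            r_carry = r_carry * math.exp(-koff * dt)
    return out


def simulate_sensorgram(
    kon: float,
    koff: float,
    rmax: float,
    injections: list[Injection] | list[tuple[float, float, float]],
    *,
    mode: str = "multi-cycle",
    time_step_s: float = 1.0,
    tail_s: float = 120.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Sensorgram:
    """Generate a synthetic sensorgram from known 1:1 kinetics.

    Deterministic for a fixed ``seed``; ``noise_sd`` adds i.i.d. Gaussian
    noise in RU on top of the exact piecewise solution.
    """
    if kon <= 0 or koff <= 0 or rmax <= 0:
        raise SensorgramError("kon, koff and rmax must be > 0")
    inj = tuple(
        i if isinstance(i, Injection) else Injection(*i) for i in injections
    )
    if not inj:
        raise SensorgramError("at least one injection required")
    inj = tuple(sorted(inj, key=lambda i: i.start_s))
    for a, b in zip(inj, inj[1:]):
        if b.start_s < a.stop_s:
            raise SensorgramError("injections overlap")
    t0 = min(0.0, inj[0].start_s)
    t = np.arange(t0, inj[-1].stop_s + tail_s + time_step_s / 2, time_step_s)
    r = _model_response(t, inj, kon, koff, rmax, mode)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return Sensorgram(t, r, inj, mode=mode,
                      meta={"simulated": True, "noise_sd": noise_sd})


def fit_langmuir(sensorgram: Sensorgram) -> KineticFit:
    """Global 1:1 Langmuir fit of a sensorgram (kon, koff, Rmax shared).

    Requires at least two analyte concentrations so the on-rate and Rmax
    are separable.  Raises :class:`FitFailure` on non-identifiable input
    (flat trace, single concentration) instead of returning garbage.
    """
    concs = {i.conc_nM for i in sensorgram.injections if i.conc_nM > 0}
    if len(concs) < 2:
        raise FitFailure("need >= 2 analyte concentrations for a 1:1 kinetic fit")
    resp = sensorgram.response_ru
    if np.ptp(resp) < 1e-9 or not np.all(np.isfinite(resp)):
        raise FitFailure("flat or non-finite response: kinetics not identifiable")

    r_scale = float(np.max(np.abs(resp)))
    c_mid = float(np.median(sorted(concs)))
    t_span = float(sensorgram.time_s[-1] - sensorgram.time_s[0])

    params = lmfit.Parameters()
    params.add("log_kon", value=math.log10(1.0 / (c_mid * t_span * 0.1)),
               min=-9, max=3)
    params.add("log_koff", value=math.log10(2.0 / t_span), min=-7, max=2)
    params.add("rmax", value=1.5 * r_scale, min=1e-6 * r_scale)

    def residual(p):
        model = _model_response(
            sensorgram.time_s, sensorgram.injections,
            10.0 ** p["log_kon"].value, 10.0 ** p["log_koff"].value,
            p["rmax"].value, sensorgram.mode,
        )
        return model - resp

    result = lmfit.minimize(residual, params, method="least_squares")
    if not result.success:
        raise FitFailure(f"kinetic fit did not converge: {result.message}")
    kon = 10.0 ** result.params["log_kon"].value
    koff = 10.0 ** result.params["log_koff"].value
    rmax = result.params["rmax"].value
    rmse = float(np.sqrt(np.mean(result.residual**2)))
    return KineticFit(kon=kon, koff=koff, rmax=rmax, residual_rmse=rmse)


def fit_steady_state(conc_nM, r_eq) -> SteadyStateFit:
    """Steady-state affinity fit R = Rmax * C / (C + KD).

    The recovered KD equals the analyte concentration at half-maximal
    equilibrium response; for the ternary format this is K_LPT.
    """
    c = np.asarray(conc_nM, float)
    r = np.asarray(r_eq, float)
    if c.size != r.size or c.size < 4:
        raise FitFailure("need >= 4 matched (conc, R_eq) points")
    if np.any(c < 0):
        raise FitFailure("concentrations must be non-negative")
    if np.ptp(r) < 1e-12 or np.max(np.abs(r)) < 1e-12:
        raise FitFailure("no curvature in steady-state data")

    params = lmfit.Parameters()
    params.add("rmax", value=float(np.max(r)) * 1.2, min=1e-12)
    params.add("log_kd", value=math.log10(max(float(np.median(c[c > 0])), 1e-6)),
               min=-6, max=9)

    def residual(p):
        kd = 10.0 ** p["log_kd"].value
        return p["rmax"].value * c / (c + kd) - r

    result = lmfit.minimize(residual, params, method="least_squares")
    if not result.success:
        raise FitFailure(f"steady-state fit did not converge: {result.message}")
    kd = 10.0 ** result.params["log_kd"].value
    rmse = float(np.sqrt(np.mean(result.residual**2)))
    return SteadyStateFit(kd_nM=kd, rmax_ru=result.params["rmax"].value,
                          residual_rmse=rmse)


def reference_subtract(raw: Sensorgram, reference: Sensorgram) -> Sensorgram:
    """Subtract a reference-channel trace point-by-point (single pass)."""
    if raw.time_s.shape != reference.time_s.shape or not np.allclose(
        raw.time_s, reference.time_s
    ):
        raise SensorgramError("time grids do not match; align before subtracting")
    meta = dict(raw.meta)
    meta["reference_subtracted"] = True
    return replace(raw, response_ru=raw.response_ru - reference.response_ru,
                   meta=meta)
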