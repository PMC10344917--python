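"""Seeded generators for every input the pipeline consumes, plus the
packaged compound tables.

Generators emulate the assay designs the fitters are built for: 1:1
Langmuir sensorgrams (multi-cycle binary and single-cycle ternary
formats, 5-point five-fold dilutions), 10-point 1:3 dose-response
titrations on the POC scale with an optional hook-effect distortion
driven by the exact three-body equilibrium, one-phase-decay time courses,
and toy atom clusters whose surface burial is known in closed form
(spherical caps).  Every generator draws from one explicit
``numpy.random.default_rng(seed)`` and emits a truth record so recovery
can be tested quantitatively.

``load_paper_tables`` returns the packaged compound records (affinities,
cooperativities, AUCs, rates, DC50/Dmax with censoring flags) after
verifying fixture checksums.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .correlation import CompoundRecord
from .degradation import DoseResponseCurve
from .equilibrium import EquilibriumParams, hook_curve
from .geometry import StructureModel
from .spr import Injection, Sensorgram, simulate_sensorgram

__all__ = [
    "GeneratorSpec",
    "generate_spr_dataset",
    "generate_degradation_dataset",
    "generate_toy_complex",
    "load_paper_tables",
    "two_sphere_analytic_areas",
    "FixtureIntegrityError",
]


class FixtureIntegrityError(RuntimeError):
    """Packaged fixture bytes do not match the recorded checksum."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Seed and truth parameters for one synthetic dataset.

    Identical specs produce identical output (all randomness flows
    through ``numpy.random.default_rng(seed)``).
    """

    seed: int = 0
    #: SPR truth: association/dissociation rates and surface capacity
    kon: float = 1e-3       # 1/(nM s)
    koff: float = 5e-3      # 1/s
    rmax: float = 100.0     # RU
    spr_noise_sd: float = 1.0   # RU
    #: dose-response truth (POC scale)
    dc50_nM: float = 8.0
    dmax: float = 98.0
    hill: float = 1.0
    dr_noise_sd: float = 3.0
    top_dose_nM: float = 10000.0
    n_doses: int = 10
    dilution: float = 3.0
    #: time-course truth (t_half ~ 36.6 min: a fast degrader)
    tc_k: float = 0.0195    # 1/min
    tc_plateau: float = 2.0
    tc_noise_sd: float = 2.0


def generate_spr_dataset(
    spec: GeneratorSpec,
    *,
    mode: str = "single-cycle",
    top_conc_nM: float = 100.0,
    n_concs: int = 5,
    dilution: float = 5.0,
    contact_s: float = 60.0,
    dissociation_s: float = 120.0,
) -> tuple[Sensorgram, dict]:
    """Synthetic sensorgram for a serial dilution plus its truth record.

    Default schedule mirrors the ternary assay format: 5-point five-fold
    dilution injected sequentially without regeneration (single-cycle);
    ``mode="multi-cycle"`` emulates the binary format instead.
    """
    concs = [top_conc_nM / dilution**i for i in range(n_concs)][::-1]
    injections = []
    t = 0.0
    final_dissoc = 300.0 if mode == "single-cycle" else dissociation_s
    for i, c in enumerate(concs):
        injections.append(Injection(t, t + contact_s, c))
        t += contact_s + (dissociation_s if i < len(concs) - 1 else final_dissoc)
    gram = simulate_sensorgram(
        spec.kon, spec.koff, spec.rmax, injections, mode=mode,
        noise_sd=spec.spr_noise_sd, seed=spec.seed,
    )
    truth = {
        "kon": spec.kon, "koff": spec.koff, "rmax": spec.rmax,
        "kd_nM": spec.koff / spec.kon,
        "t_half_s": math.log(2.0) / spec.koff,
        "mode": mode, "conc_nM": concs, "noise_sd": spec.spr_noise_sd,
        "seed": spec.seed,
    }
    return gram, truth


def _four_pl_poc(conc, dc50, dmax, hill):
    bottom = 100.0 - dmax
    return bottom + (100.0 - bottom) / (1.0 + (conc / dc50) ** hill)


def generate_degradation_dataset(
    spec: GeneratorSpec,
    *,
    hook: bool = False,
    hook_params: EquilibriumParams | None = None,
    censored: bool = False,
    times_min: np.ndarray | None = None,
) -> dict:
    """Dose-response and time-course POC tables with a truth record.

    The dose response is a 10-point 1:3 titration.  ``hook=True`` distorts
    the top doses using the exact three-body equilibrium: measured POC is
    re-expressed as 100 minus degradation proportional to the normalized
    ternary-complex level from :func:`~ternary_sar.equilibrium.hook_curve`.
    ``censored=True`` emits a flat non-degrader curve near 100 POC.
    """
    rng = np.random.default_rng(spec.seed)
    conc = np.array(
        [spec.top_dose_nM / spec.dilution**i for i in range(spec.n_doses)]
    )[::-1]

    if censored:
        poc_true = np.full_like(conc, 100.0)
    elif hook:
        params = hook_params or EquilibriumParams(k_lp=100.0, k_tp=100.0, alpha=1.0)
        lpt = hook_curve(10.0, 100.0, conc, params)
        poc_true = 100.0 - spec.dmax * lpt / lpt.max()
    else:
        poc_true = _four_pl_poc(conc, spec.dc50_nM, spec.dmax, spec.hill)
    poc = poc_true + rng.normal(0.0, spec.dr_noise_sd, size=conc.shape)

    if times_min is None:
        times_min = np.array([0.0, 15, 30, 45, 60, 90, 120, 180, 240, 360])
    tc_true = (100.0 - spec.tc_plateau) * np.exp(-spec.tc_k * times_min) + spec.tc_plateau
    tc_poc = tc_true + rng.normal(0.0, spec.tc_noise_sd, size=times_min.shape)

    t_half = (
        math.log((100.0 - spec.tc_plateau) / (50.0 - spec.tc_plateau)) / spec.tc_k
        if spec.tc_plateau < 50.0 else None
    )
    # ec50 is the 4PL inflection; dc50 is the 50-POC crossing of the
    # noiseless curve (the reported potency convention)
    bottom = 100.0 - spec.dmax
    dc50 = (
        spec.dc50_nM * ((100.0 - bottom) / (50.0 - bottom) - 1.0) ** (1.0 / spec.hill)
        if (not censored and not hook and bottom < 50.0)
        else None
    )
    truth = {
        "ec50_nM": None if censored else spec.dc50_nM,
        "dc50_nM": dc50,
        "dmax": 0.0 if censored else spec.dmax,
        "hill": spec.hill,
        "tc_k": spec.tc_k, "tc_plateau": spec.tc_plateau,
        "tc_t_half_min": t_half,
        "initial_rate": None if t_half is None else 100.0 * 0.693 / t_half,
        "hook": hook, "censored": censored, "seed": spec.seed,
    }
    return {
        "dose_response": pd.DataFrame({"conc_nM": conc, "poc": poc}),
        "dose_response_curve": DoseResponseCurve(conc, poc),
        "time_course": pd.DataFrame({"time_min": times_min, "poc": tc_poc}),
        "truth": truth,
    }


def two_sphere_analytic_areas(r: float, d: float, probe: float) -> dict:
    """Closed-form SASA/BSA for two equal spheres at center distance d.

    With expanded radius R = r + probe and R > d/2, each sphere loses a
    cap of area 2*pi*R*h, h = R - d/2.  Used as the quadrature oracle.
    """
    R = r + probe
    single = 4.0 * math.pi * R * R
    if d >= 2.0 * R:
        return {"sasa_total": 2 * single, "bsa": 0.0, "sasa_single": single}
    h = R - d / 2.0
    cap = 2.0 * math.pi * R * h
    total = 2.0 * (single - cap)
    return {"sasa_total": total, "bsa": 2 * single - total, "sasa_single": single}


def generate_toy_complex(
    spec: GeneratorSpec,
    *,
    separation: float = 2.0,
    jitter_sd: float = 0.0,
) -> tuple[StructureModel, dict]:
    """Toy ternary assembly with analytically known surface burial.

    A linear triatomic: a "ligase" atom and a "target" atom bridged by a
    central "protac" atom, equally spaced by ``separation`` Å along x.
    Spherical-cap formulas give the exact burial: the total BSA is twice
    the adjacent-pair cap burial (for collinear equal spheres the cap an
    outer atom loses to the far atom lies entirely inside the cap it
    loses to the middle atom), and the protein-protein term is the cap
    burial of the outer pair at distance 2*separation (zero once they
    separate beyond 2*(r+probe)).  Optional seeded jitter perturbs
    coordinates perpendicular to the axis only, preserving pairwise
    clash-count truth to first order.
    """
    coords = np.array([
        [-separation, 0.0, 0.0],
        [0.0, 0.0, 0.0],
        [separation, 0.0, 0.0],
    ])
    if jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + np.column_stack([
            np.zeros(3), rng.normal(0, jitter_sd, 3), rng.normal(0, jitter_sd, 3)
        ])
    model = StructureModel(
        coords=coords,
        elements=("S", "S", "S"),
        components=("ligase", "protac", "target"),
        radii=np.array([1.6, 1.6, 1.6]),
        name="toy-linear-triatomic",
    )
    pair = two_sphere_analytic_areas(1.6, separation, 1.4)
    outer = two_sphere_analytic_areas(1.6, 2.0 * separation, 1.4)
    total = 2.0 * pair["bsa"]
    truth = {
        "bsa_total": total,
        "bsa_protein_protein": outer["bsa"],
        "bsa_protein_protac": total - outer["bsa"],
        "pairwise_bsa": pair["bsa"],
        "sasa_single_atom": pair["sasa_single"],
        "separation": separation,
    }
    return model, truth


def _fixture_bytes(name: str) -> bytes:
    return resources.files("ternary_sar.fixtures").joinpath(name).read_bytes()


def _verify_checksums() -> None:
    manifest = json.loads(_fixture_bytes("manifest.json"))
    for name, digest in manifest.items():
        actual = hashlib.sha256(_fixture_bytes(name)).hexdigest()
        if actual != digest:
            raise FixtureIntegrityError(
                f"fixture {name} checksum mismatch: {actual} != {digest}"
            )


def _read_fixture(name: str) -> pd.DataFrame:
    import io

    return pd.read_csv(io.BytesIO(_fixture_bytes(name)))


def load_paper_tables(verify: bool = True) -> dict[str, list[CompoundRecord]]:
    """Packaged compound tables as :class:`CompoundRecord` lists per domain.

    Merges the per-domain binding/degradation parameters with the
    dose-response DC50/Dmax values (censoring preserved, e.g. ">10000").
    Keys: ``"SMARCA2-BD"``, ``"BRD4-BD1"``, ``"BRD4-BD2"``.
    """
    if verify:
        _verify_checksums()
    dc50 = _read_fixture("table1_table2_dc50.csv").set_index("compound_id")

    def _opt(row, col):
        v = row.get(col)
        return None if pd.isna(v) else float(v)

    out: dict[str, list[CompoundRecord]] = {}
    for fname in ("table3_smarca2.csv", "table3_brd4_bd1.csv", "table3_brd4_bd2.csv"):
        records = []
        for _, row in _read_fixture(fname).iterrows():
            cid = int(row["compound_id"])
            d = dc50.loc[cid]
            records.append(CompoundRecord(
                compound_id=str(cid),
                target_domain=row["target_domain"],
                k_lp_nM=_opt(row, "k_lp_nM"),
                k_lpt_nM=_opt(row, "k_lpt_nM"),
                alpha=_opt(row, "alpha"),
                auc=_opt(row, "auc"),
                initial_rate=_opt(row, "initial_rate"),
                dc50_nM=_opt(d, "dc50_nM"),
                dc50_censored_above_nM=_opt(d, "dc50_censored_above_nM"),
                dmax=_opt(d, "dmax"),
                k_lpt_approximate=bool(row["k_lpt_approximate"]),
            ))
        out[records[0].target_domain] = records
    return out
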