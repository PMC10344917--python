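"""Geometric scoring and filtering of candidate ternary-complex models.

A modeled ligase-PROTAC-target assembly is screened in stages: (1) steric
clash counting between components at a hard distance cutoff; (2) pruning
by similarity of the target-warhead placement to reference poses (center
of geometry distance and principal-axis deviations after superposing the
models on the ligase); (3) a linker-strain / warhead-RMSD selection gate
(strain energies are supplied by an external force-field calculation —
only the filter logic lives here); (4) interface characterisation via
Shrake-Rupley solvent-accessible surface area (SASA) and buried surface
area (BSA = sum of component SASAs minus complex SASA), split into
protein-protein and protein-PROTAC terms.

The SASA sphere point set is a deterministic Fibonacci lattice, so every
area is reproducible bit-for-bit.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "StructureModel",
    "ModelMetrics",
    "GeometryError",
    "vdw_radius",
    "count_clashes",
    "assembly_filter",
    "warhead_similarity",
    "model_selection",
    "kabsch_rotation",
    "kabsch_rmsd",
    "sasa",
    "buried_surface_area",
    "structure_from_pdb",
]

COMPONENTS = ("ligase", "target", "protac")
PROTAC_PARTS = ("ligase_ligand", "linker", "target_warhead")

#: Steric clash distance cutoff between heavy atoms (Å).
CLASH_CUTOFF = 2.2
#: Assembly-stage clash tolerances: protein-protein and protein-PROTAC.
MAX_CLASHES_PROTEIN_PROTEIN = 5
MAX_CLASHES_PROTEIN_PROTAC = 2
#: Pose-similarity thresholds: warhead COG distance (Å) and the first two
#: principal-axis deviations (degrees).
COG_CUTOFF = 6.0
AXIS_CUTOFF_DEG = 20.0
#: Strain gates: pruning keeps models under 4 kcal/mol; final selection
#: demands strain within thermal fluctuation and warhead RMSD < 3 Å.
STRAIN_PRUNE_KCAL = 4.0
STRAIN_SELECT_KCAL = 0.6
WARHEAD_RMSD_CUTOFF = 3.0


class GeometryError(ValueError):
    """Invalid structure, labels or coordinates."""


def _load_radii() -> dict[str, float]:
    with resources.files("ternary_sar.fixtures").joinpath(
        "vdw_radii.json"
    ).open() as fh:
        data = json.load(fh)
    return {k.upper(): float(v) for k, v in data["radii_angstrom"].items()}


_RADII: dict[str, float] | None = None


def vdw_radius(element: str) -> float:
    """Van der Waals radius (Å) from the pinned Bondi-style table."""
    global _RADII
    if _RADII is None:
        _RADII = _load_radii()
    try:
        return _RADII[element.upper()]
    except KeyError:
        raise GeometryError(f"no van der Waals radius for element {element!r}")


@dataclass(frozen=True)
class StructureModel:
    """Labeled atom set of one candidate ternary-complex model.

    Each atom carries an element, coordinates (Å), a vdW radius, a
    heavy-atom flag and exactly one component label (ligase / target /
    protac); PROTAC atoms may additionally carry a sub-label
    (ligase_ligand / linker / target_warhead).
    """

    coords: np.ndarray
    elements: tuple[str, ...]
    components: tuple[str, ...]
    radii: np.ndarray = None
    sub_labels: tuple[str | None, ...] = None
    name: str = ""

    def __post_init__(self) -> None:
        xyz = np.asarray(self.coords, float)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise GeometryError("coords must be (N, 3)")
        if not np.all(np.isfinite(xyz)):
            raise GeometryError("coordinates must be finite")
        n = xyz.shape[0]
        if len(self.elements) != n or len(self.components) != n:
            raise GeometryError("elements/components length mismatch")
        for comp in self.components:
            if comp not in COMPONENTS:
                raise GeometryError(f"unknown component label {comp!r}")
        radii = self.radii
        if radii is None:
            radii = np.array([vdw_radius(e) for e in self.elements])
        else:
            radii = np.asarray(radii, float)
            if radii.shape != (n,):
                raise GeometryError("radii length mismatch")
        subs = self.sub_labels if self.sub_labels is not None else (None,) * n
        if len(subs) != n:
            raise GeometryError("sub_labels length mismatch")
        for s in subs:
            if s is not None and s not in PROTAC_PARTS:
                raise GeometryError(f"unknown PROTAC sub-label {s!r}")
        object.__setattr__(self, "coords", xyz)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "sub_labels", tuple(subs))

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements])

    def component_mask(self, component: str) -> np.ndarray:
        return np.array([c == component for c in self.components])

    def sub_label_mask(self, sub: str) -> np.ndarray:
        return np.array([s == sub for s in self.sub_labels])

    def select(self, mask: np.ndarray) -> "StructureModel":
        idx = np.flatnonzero(np.asarray(mask))
        return StructureModel(
            coords=self.coords[idx],
            elements=tuple(self.elements[i] for i in idx),
            components=tuple(self.components[i] for i in idx),
            radii=self.radii[idx],
            sub_labels=tuple(self.sub_labels[i] for i in idx),
            name=self.name,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        return replace(self, coords=self.coords @ rotation.T + translation)

    def warhead(self) -> "StructureModel":
        mask = self.sub_label_mask("target_warhead") & self.heavy_mask
        if not mask.any():
            raise GeometryError("no target_warhead heavy atoms labeled")
        return self.select(mask)


@dataclass
class ModelMetrics:
    """Derived per-model metrics; unset fields stay None."""

    clashes_pp: int | None = None
    clashes_pl: int | None = None
    cog_distance: float | None = None
    axis_angle_1: float | None = None
    axis_angle_2: float | None = None
    linker_strain: float | None = None  # kcal/mol, externally computed
    warhead_rmsd: float | None = None
    bsa_total: float | None = None
    bsa_protein_protein: float | None = None
    bsa_protein_protac: float | None = None

    def as_dict(self) -> dict:
        return dict(vars(self))


def count_clashes(
    coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float = CLASH_CUTOFF
) -> int:
    """Number of cross pairs closer than ``cutoff`` Å (heavy atoms assumed).

    KD-tree pair counting; an empty subset yields 0 with a warning.
    """
    a = np.atleast_2d(np.asarray(coords_a, float))
    b = np.atleast_2d(np.asarray(coords_b, float))
    if a.size == 0 or b.size == 0:
        warnings.warn("empty atom subset in clash count", stacklevel=2)
        return 0
    tree_b = cKDTree(b)
    pairs = cKDTree(a).query_ball_tree(tree_b, r=cutoff)
    # query_ball_tree includes distances == cutoff; the criterion is strict
    n = 0
    for i, hits in enumerate(pairs):
        for j in hits:
            if np.linalg.norm(a[i] - b[j]) < cutoff:
                n += 1
    return n


def assembly_filter(
    metrics: ModelMetrics,
    *,
    max_pp: int = MAX_CLASHES_PROTEIN_PROTEIN,
    max_pl: int = MAX_CLASHES_PROTEIN_PROTAC,
) -> tuple[bool, list[str]]:
    """Keep/reject verdict from the assembly-stage clash tolerances."""
    if metrics.clashes_pp is None or metrics.clashes_pl is None:
        raise GeometryError("clash counts not populated")
    reasons = []
    if metrics.clashes_pp > max_pp:
        reasons.append(f"protein-protein clashes {metrics.clashes_pp} > {max_pp}")
    if metrics.clashes_pl > max_pl:
        reasons.append(f"protein-PROTAC clashes {metrics.clashes_pl} > {max_pl}")
    return (not reasons), reasons


def model_selection(
    strain_kcal: float | None,
    warhead_rmsd: float | None,
    *,
    prune_cutoff: float = STRAIN_PRUNE_KCAL,
    select_strain: float = STRAIN_SELECT_KCAL,
    select_rmsd: float = WARHEAD_RMSD_CUTOFF,
) -> dict:
    """Two-stage strain/RMSD verdict.

    Pruning retains models with linker strain <= 4 kcal/mol; final
    selection requires strain within thermal fluctuation (0.6 kcal/mol)
    and warhead heavy-atom RMSD < 3 Å.  Missing strain prunes the model
    with an explicit reason (a system whose models all lack passing
    strain simply drops out of downstream averages).
    """
    if strain_kcal is None:
        return {"prune_pass": False, "select_pass": False,
                "reason": "no strain available"}
    prune = strain_kcal <= prune_cutoff
    if not prune:
        return {"prune_pass": False, "select_pass": False,
                "reason": f"strain {strain_kcal} > {prune_cutoff} kcal/mol"}
    if warhead_rmsd is None:
        return {"prune_pass": True, "select_pass": False,
                "reason": "no warhead RMSD available"}
    select = strain_kcal <= select_strain and warhead_rmsd < select_rmsd
    reason = "" if select else (
        f"strain {strain_kcal} kcal/mol vs {select_strain} or "
        f"RMSD {warhead_rmsd} Å vs {select_rmsd}"
    )
    return {"prune_pass": True, "select_pass": select, "reason": reason}


def kabsch_rotation(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t mapping mobile onto
    reference (least-squares, SVD with determinant correction)."""
    p = np.asarray(mobile, float)
    q = np.asarray(reference, float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise GeometryError("coordinate sets must be matching (N, 3) arrays")
    if p.shape[0] < 3:
        raise GeometryError("need >= 3 points for superposition")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = q.mean(axis=0) - rot @ p.mean(axis=0)
    return rot, trans


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal RMSD (Å) over rigid superposition of matched atom sets."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    rot, trans = kabsch_rotation(a, b)
    moved = a @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    """Rows = principal axes of the coordinate scatter, largest first."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    return evecs[:, ::-1].T  # descending eigenvalue order


def _axis_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between axes folded to [0, 90]° (sign-ambiguous eigenvectors)."""
    c = abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(min(c, 1.0)))


def warhead_similarity(
    model_a: StructureModel,
    model_b: StructureModel,
    *,
    cog_cutoff: float = COG_CUTOFF,
    axis_cutoff_deg: float = AXIS_CUTOFF_DEG,
    align_on_ligase: bool = True,
) -> tuple[float, float, float, bool]:
    """Pose similarity of two models' target warheads.

    Model A is first superposed onto model B using their shared ligase
    atoms (equal counts assumed: same ligase structure), then the warhead
    center-of-geometry distance and the angles between the first and
    second principal axes are compared.  Similar iff COG distance <
    6 Å and both axis deviations < 20°.
    """
    a, b = model_a, model_b
    if align_on_ligase:
        la = a.select(a.component_mask("ligase") & a.heavy_mask)
        lb = b.select(b.component_mask("ligase") & b.heavy_mask)
        if la.n_atoms != lb.n_atoms or la.n_atoms < 3:
            raise GeometryError("ligase atom sets must match for alignment")
        rot, trans = kabsch_rotation(la.coords, lb.coords)
        a = a.transformed(rot, trans)
    wa = a.warhead()
    wb = b.warhead()
    if wa.n_atoms < 3 or wb.n_atoms < 3:
        raise GeometryError("principal axes undefined for < 3 warhead atoms")
    cog = float(np.linalg.norm(wa.coords.mean(axis=0) - wb.coords.mean(axis=0)))
    axes_a = _principal_axes(wa.coords)
    axes_b = _principal_axes(wb.coords)
    ang1 = _axis_angle_deg(axes_a[0], axes_b[0])
    ang2 = _axis_angle_deg(axes_a[1], axes_b[1])
    similar = cog < cog_cutoff and ang1 < axis_cutoff_deg and ang2 < axis_cutoff_deg
    return cog, ang1, ang2, similar


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points via the Fibonacci lattice.

    Deterministic by construction — no RNG — so SASA values are
    bit-for-bit reproducible.
    """
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    *,
    per_atom: bool = False,
    include_hydrogens: bool = False,
):
    """Shrake-Rupley solvent-accessible surface area (Å²).

    For each (heavy) atom, test points on the sphere of radius
    r_vdw + probe are counted as accessible when outside every
    neighbour's expanded sphere; the accessible fraction scales
    4·pi·(r+probe)².  Hydrogens are ignored by default.
    """
    if probe < 0 or n_points < 8:
        raise GeometryError("probe must be >= 0 and n_points >= 8")
    sub = model if include_hydrogens else model.select(model.heavy_mask)
    if sub.n_atoms == 0:
        return (np.zeros(0), 0.0) if per_atom else 0.0
    coords = sub.coords
    radii = sub.radii + probe
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = float(radii.max())
    areas = np.zeros(sub.n_atoms)
    for i in range(sub.n_atoms):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 >= radii[j] ** 2
        areas[i] = accessible.mean() * 4.0 * math.pi * radii[i] ** 2
    total = float(areas.sum())
    return (areas, total) if per_atom else total


def buried_surface_area(
    model: StructureModel, probe: float = 1.4, n_points: int = 960
) -> dict[str, float]:
    """Interface burial of the ternary assembly (Å²).

    total BSA = SASA(ligase) + SASA(target) + SASA(protac) - SASA(complex).
    The protein-protein term is the burial of the PROTAC-free two-protein
    sub-system; the protein-PROTAC term is the remainder, so the two terms
    sum to the total by construction.  Quadrature can leave tiny negative
    remainders for non-interacting components; these are clamped at 0.
    """
    masks = {c: model.component_mask(c) for c in COMPONENTS}
    for comp, mask in masks.items():
        if not mask.any():
            raise GeometryError(f"component {comp!r} has no atoms")
    kw = dict(probe=probe, n_points=n_points)
    sasa_parts = {c: sasa(model.select(m), **kw) for c, m in masks.items()}
    sasa_complex = sasa(model, **kw)
    total = sum(sasa_parts.values()) - sasa_complex

    two_protein = model.select(masks["ligase"] | masks["target"])
    bsa_pp = (
        sasa_parts["ligase"] + sasa_parts["target"] - sasa(two_protein, **kw)
    )
    total = max(total, 0.0)
    bsa_pp = min(max(bsa_pp, 0.0), total)
    return {
        "bsa_total": total,
        "bsa_protein_protein": bsa_pp,
        "bsa_protein_protac": total - bsa_pp,
    }


def structure_from_pdb(
    path,
    component_map: dict,
    *,
    model: int = 1,
) -> StructureModel:
    """Read a PDB file into a labeled :class:`StructureModel`.

    ``component_map`` assigns chains/residues to components, e.g.::

        {"ligase": ["A", "B", "C"], "target": ["D"],
         "protac": {"resnames": ["LIG"]},
         "warhead_atoms": ["C1", "C2", ...]}   # optional, names within protac

    First model only; where alternate locations exist, altloc 'A' is kept.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=model, altloc="first")

    protac_spec = component_map.get("protac", {})
    protac_resnames = set(
        protac_spec.get("resnames", protac_spec)
        if isinstance(protac_spec, (dict,)) else protac_spec
    )
    chain_to_comp: dict[str, str] = {}
    for comp in ("ligase", "target"):
        for chain in component_map.get(comp, []):
            chain_to_comp[str(chain)] = comp
    warhead_atoms = set(component_map.get("warhead_atoms", []))

    components, sub_labels, keep = [], [], []
    for i in range(atoms.array_length()):
        resname = atoms.res_name[i]
        chain = atoms.chain_id[i]
        if resname in protac_resnames:
            components.append("protac")
            sub_labels.append(
                "target_warhead" if atoms.atom_name[i] in warhead_atoms else None
            )
            keep.append(i)
        elif chain in chain_to_comp and not atoms.hetero[i]:
            components.append(chain_to_comp[chain])
            sub_labels.append(None)
            keep.append(i)
    if not keep:
        raise GeometryError("no atoms matched the component map")
    idx = np.array(keep)
    return StructureModel(
        coords=atoms.coord[idx],
        elements=tuple(atoms.element[i] for i in keep),
        components=tuple(components),
        sub_labels=tuple(sub_labels),
        name=str(path),
    )
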