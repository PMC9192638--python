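"""Solvent-accessible surface area, buried surface area, and contacts.

SASA is computed by Shrake-Rupley quadrature: each atom is dressed with a
quasi-uniform spherical point set (a Fibonacci lattice) at radius
``r_atom + r_probe``; the accessible fraction is the fraction of points not
inside any neighbour's probe-expanded sphere, and the atom's area is that
fraction times the full sphere area.  Neighbour lookup uses a KD-tree.

Buried surface area (BSA) follows the context-limited convention used for
factor-ribosome interfaces: the component's SASA computed alone, minus its
SASA computed in the presence of all non-component atoms lying within a
context radius (default 30 Å) of any component atom.  Only the component's
own atoms are integrated in both runs; context atoms merely occlude.

Contact classes are purely geometric — distance (and ring-plane) criteria
only, no energetics: ``vdw`` (heavy-atom pair within 4.0 Å),
``hbond-candidate`` (N/O pair within 3.5 Å), ``stacking-candidate``
(aromatic/base ring centroids within 4.5 Å with near-parallel planes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ribomotion.structure_model import (
    AtomRecord,
    SelectionExpr,
    SelectionError,
    StructureModel,
    select,
)

# Heavy-atom vdW radii (Å), NACCESS-flavoured element table.  Hydrogens get
# an explicit entry so runs with generated/modelled protons resolve too.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "H": 1.10, "D": 1.10, "SE": 1.90, "F": 1.47, "CL": 1.75,
    "BR": 1.85, "I": 1.98, "MG": 1.73, "NA": 2.27, "K": 2.75,
    "ZN": 1.39, "FE": 1.40, "MN": 1.39, "CA": 2.31,
}

HBOND_ELEMENTS = {"N", "O"}

# Ring-system atom names used for stacking geometry.  Purines use the fused
# 9-atom system; pyrimidines the 6-ring; TRP both rings are merged (a single
# plane is an adequate stacking proxy).
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "A": ("N9", "C8", "N7", "C5", "C4", "C6", "N1", "C2", "N3"),
    "G": ("N9", "C8", "N7", "C5", "C4", "C6", "N1", "C2", "N3"),
    "DA": ("N9", "C8", "N7", "C5", "C4", "C6", "N1", "C2", "N3"),
    "DG": ("N9", "C8", "N7", "C5", "C4", "C6", "N1", "C2", "N3"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "DC": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "DT": ("N1", "C2", "N3", "C4", "C5", "C6"),
}


class RadiusTableError(Exception):
    """One or more atoms have no resolvable vdW radius."""


class ContactConfigError(Exception):
    pass


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4            # Å, water probe
    points_per_atom: int = 960           # Fibonacci lattice size
    radii: dict = field(default_factory=lambda: dict(DEFAULT_RADII))
    atom_name_radii: dict = field(default_factory=dict)  # explicit per-name overrides
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if self.points_per_atom < 64:
            raise ValueError("points_per_atom must be >= 64")
        if any(r <= 0 for r in (*self.radii.values(), *self.atom_name_radii.values())):
            raise ValueError("all radii must be > 0")

    def radius_of(self, atom: AtomRecord) -> float | None:
        # explicit atom-name overrides take precedence, then the element table
        # (atom names alone are ambiguous: CA is both Cα and calcium)
        r = self.atom_name_radii.get(atom.atom_name.upper())
        if r is None:
            r = self.radii.get(atom.element.upper())
        return r


@dataclass(frozen=True)
class BsaResult:
    component: str
    sasa_alone: float          # Å²
    sasa_in_context: float     # Å²
    buried: float              # Å², alone - in_context
    context_radius: float      # Å
    n_context_atoms: int
    per_residue_buried: dict   # (chain, resnum, insertion) -> Å²


@dataclass(frozen=True)
class Contact:
    atom_a: tuple
    atom_b: tuple
    distance: float
    contact_class: str         # vdw | hbond-candidate | stacking-candidate


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (deterministic Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii_for(atoms: list[AtomRecord], params: SasaParams) -> np.ndarray:
    radii = []
    unknown = []
    for a in atoms:
        r = params.radius_of(a)
        if r is None:
            unknown.append(f"{a.chain_id}/{a.residue_number}/{a.atom_name} ({a.element})")
        else:
            radii.append(r)
    if unknown:
        raise RadiusTableError("no vdW radius for: " + ", ".join(unknown[:20]))
    return np.asarray(radii)


def _drop_h(atoms: list[AtomRecord], params: SasaParams) -> list[AtomRecord]:
    if params.include_hydrogens:
        return list(atoms)
    return [a for a in atoms if not a.is_hydrogen]


def sasa(
    atoms: list[AtomRecord],
    params: SasaParams | None = None,
    context_atoms: list[AtomRecord] | None = None,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley per-atom accessible areas (Å²) and their total.

    ``context_atoms`` occlude surface but are not themselves integrated;
    this is how the component-in-context run of a BSA calculation is done.
    """
    params = params or SasaParams()
    atoms = _drop_h(atoms, params)
    if not atoms:
        raise ValueError("empty atom list")
    context_atoms = _drop_h(context_atoms or [], params)

    coords = np.array([a.coord for a in atoms])
    radii = _radii_for(atoms, params) + params.probe_radius
    if context_atoms:
        occ_coords = np.vstack([coords, np.array([a.coord for a in context_atoms])])
        occ_radii = np.concatenate([radii, _radii_for(context_atoms, params) + params.probe_radius])
    else:
        occ_coords, occ_radii = coords, radii

    sphere = fibonacci_sphere(params.points_per_atom)
    tree = cKDTree(occ_coords)
    rmax = float(occ_radii.max())
    areas = np.empty(len(atoms))
    n_total = len(coords)  # index of atom i in occ arrays equals i
    for i in range(n_total):
        pts = coords[i] + radii[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
                 if j != i]
        if neigh:
            nc = occ_coords[neigh]
            nr = occ_radii[neigh]
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nr ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return areas, float(areas.sum())


def buried_surface_area(
    complex_model: StructureModel,
    component: SelectionExpr,
    context_radius: float = 30.0,
    params: SasaParams | None = None,
    component_name: str = "component",
) -> BsaResult:
    """Context-limited buried surface area of one component of a complex.

    ``buried = SASA(component alone) - SASA(component | non-component atoms
    within context_radius of any component atom)``.  Membership in the
    context is atom-level.  With ``context_radius = inf`` this equals the
    plain two-run SASA difference against the whole rest of the complex.
    """
    if context_radius <= 0:
        raise ValueError("context_radius must be > 0")
    params = params or SasaParams()
    comp_atoms = select(complex_model, component)
    if not comp_atoms:
        raise SelectionError(f"component selection {component.text()!r} is empty")
    comp_keys = {a.key for a in comp_atoms}
    other = [a for a in complex_model.atoms if a.key not in comp_keys]

    if other and np.isfinite(context_radius):
        comp_tree = cKDTree(np.array([a.coord for a in comp_atoms]))
        dists, _ = comp_tree.query(np.array([a.coord for a in other]), k=1)
        context = [a for a, d in zip(other, dists) if d <= context_radius]
    else:
        context = other

    comp_heavy = _drop_h(comp_atoms, params)
    alone_areas, alone_total = sasa(comp_atoms, params)
    ctx_areas, ctx_total = sasa(comp_atoms, params, context_atoms=context)

    per_res: dict[tuple, float] = {}
    for a, da in zip(comp_heavy, alone_areas - ctx_areas):
        per_res[a.residue_key] = per_res.get(a.residue_key, 0.0) + float(da)

    return BsaResult(
        component=component_name,
        sasa_alone=alone_total,
        sasa_in_context=ctx_total,
        buried=alone_total - ctx_total,
        context_radius=context_radius,
        n_context_atoms=len(context),
        per_residue_buried=per_res,
    )


def _ring_systems(atoms: list[AtomRecord]):
    """Group ring atoms by residue; yield (rep_key, centroid, unit normal)."""
    by_res: dict[tuple, list[AtomRecord]] = {}
    for a in atoms:
        names = RING_ATOMS.get(a.residue_name.strip().upper())
        if names and a.atom_name in names:
            by_res.setdefault(a.residue_key, []).append(a)
    out = []
    for rk, ring in by_res.items():
        if len(ring) < 4:
            continue  # incomplete ring, plane unreliable
        coords = np.array([a.coord for a in ring])
        centroid = coords.mean(axis=0)
        _, _, vt = np.linalg.svd(coords - centroid)
        out.append((ring[0].key, centroid, vt[2]))
    return out


def find_contacts(
    model: StructureModel,
    sel_a: SelectionExpr,
    sel_b: SelectionExpr,
    vdw_cutoff: float = 4.0,
    hbond_cutoff: float = 3.5,
    stacking_cutoff: float = 4.5,
    stacking_max_plane_angle: float = 30.0,
) -> list[Contact]:
    """Enumerate cross contacts between two disjoint selections.

    Heavy-atom pairs within ``vdw_cutoff`` are reported; N/O pairs within
    ``hbond_cutoff`` are upgraded to ``hbond-candidate``.  Ring systems
    (aromatic side chains, nucleobases) whose centroids lie within
    ``stacking_cutoff`` with planes within ``stacking_max_plane_angle`` are
    reported as ``stacking-candidate`` contacts keyed by a representative
    ring atom of each residue, with the centroid-centroid distance.
    """
    atoms_a = [a for a in select(model, sel_a) if not a.is_hydrogen]
    atoms_b = [a for a in select(model, sel_b) if not a.is_hydrogen]
    if {a.key for a in atoms_a} & {a.key for a in atoms_b}:
        raise ContactConfigError("selections overlap")
    if not atoms_a or not atoms_b:
        return []

    contacts: list[Contact] = []
    ca = np.array([a.coord for a in atoms_a])
    cb = np.array([a.coord for a in atoms_b])
    tree_b = cKDTree(cb)
    for i, hits in enumerate(tree_b.query_ball_point(ca, vdw_cutoff)):
        for j in hits:
            d = float(np.linalg.norm(ca[i] - cb[j]))
            if d <= 0:
                continue
            cls = "vdw"
            if (d <= hbond_cutoff
                    and atoms_a[i].element.upper() in HBOND_ELEMENTS
                    and atoms_b[j].element.upper() in HBOND_ELEMENTS):
                cls = "hbond-candidate"
            contacts.append(Contact(atoms_a[i].key, atoms_b[j].key, d, cls))

    for key_a, cen_a, nrm_a in _ring_systems(atoms_a):
        for key_b, cen_b, nrm_b in _ring_systems(atoms_b):
            d = float(np.linalg.norm(cen_a - cen_b))
            if d > stacking_cutoff:
                continue
            cosang = abs(float(nrm_a @ nrm_b))
            ang = np.rad2deg(np.arccos(np.clip(cosang, 0.0, 1.0)))
            if ang <= stacking_max_plane_angle:
                contacts.append(Contact(key_a, key_b, d, "stacking-candidate"))
    return contacts
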