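"""Synthetic structures with known ground-truth motions.

These generators stand in for deposited cryo-EM models so that every
measurement in the package is testable without downloads:

* ``make_ideal_helix`` — a Cα-only α-helix (1.5 Å rise, 100° twist) with an
  optional kink of known angle at a chosen residue, for bend/tilt tests;
* ``make_two_body_assembly`` — a large and a small pseudo-random atom body
  (chains "L" and "S", mimicking 50S + 30S) plus a copy in which the small
  body is rotated by a known angle about a known axis through a designated
  vertex atom, with a probe atom placed perpendicular to that axis so the
  vertex/probe protocol angle equals the constructed rotation;
* ``make_multidomain_factor`` — a multi-domain chain ("F", mimicking IF2)
  in two conformations related by per-domain rigid transforms.

Atom clouds are seeded and enforce a minimum inter-atom spacing of 3 Å so
SASA runs see steric realism.  Every generator returns a ``TruthTable``
recording the applied transforms and the protocol outputs they imply; the
table serializes to JSON alongside PDB fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ribomotion.rigid_geometry import RigidTransform, rotation_about_axis, rotation_angle
from ribomotion.structure_model import AtomRecord, StructureModel

MIN_SPACING = 3.0  # Å


@dataclass
class TruthTable:
    """Ground truth for a generated fixture pair."""

    transforms: dict[str, RigidTransform] = field(default_factory=dict)   # body/domain -> applied transform
    expected: dict[str, float] = field(default_factory=dict)              # named scalar truths
    vertex: tuple[str, int, str] | None = None                            # (chain, resnum, atom)
    probe: tuple[str, int, str] | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "transforms": {k: v.to_dict() for k, v in self.transforms.items()},
            "expected": self.expected,
            "vertex": self.vertex,
            "probe": self.probe,
        }
        s = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "TruthTable":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text_or_path).read_text()
        d = json.loads(text)
        return cls(
            transforms={k: RigidTransform.from_dict(v) for k, v in d["transforms"].items()},
            expected=d["expected"],
            vertex=tuple(d["vertex"]) if d.get("vertex") else None,
            probe=tuple(d["probe"]) if d.get("probe") else None,
        )


def _ca(chain: str, resnum: int, xyz, resname: str = "ALA") -> AtomRecord:
    return AtomRecord(chain, resnum, "", resname, "CA", "C", tuple(float(v) for v in xyz))


def make_ideal_helix(
    n_res: int,
    rise: float = 1.5,
    twist: float = 100.0,
    kink_angle: float = 0.0,
    kink_pos: int | None = None,
    radius: float = 2.3,
    chain_id: str = "H",
) -> StructureModel:
    """Cα-only ideal helix along +z, optionally kinked at ``kink_pos``.

    ``kink_pos`` is a 0-based residue index; the trace beyond it is rotated
    by ``kink_angle`` about an axis through that Cα perpendicular to the
    helix axis, so a fitted bend angle at the kink equals ``kink_angle``.
    """
    if n_res < 8:
        raise ValueError(f"n_res must be >= 8, got {n_res}")
    if kink_angle != 0.0:
        if kink_pos is None or not (0 < kink_pos < n_res - 1):
            raise ValueError(f"kink_pos must be interior (0 < pos < {n_res - 1})")
    th = np.deg2rad(twist) * np.arange(n_res)
    coords = np.column_stack([radius * np.cos(th), radius * np.sin(th),
                              rise * np.arange(n_res, dtype=float)])
    if kink_angle != 0.0:
        pivot = coords[kink_pos]
        # bend about an axis through the kink Cα, perpendicular to z
        t = rotation_about_axis(kink_angle, np.array([1.0, 0.0, 0.0]), point=pivot)
        coords[kink_pos + 1:] = t.apply(coords[kink_pos + 1:])
    atoms = [_ca(chain_id, i + 1, c) for i, c in enumerate(coords)]
    return StructureModel(f"helix_n{n_res}_k{kink_angle:g}", atoms)


def _spaced_cloud(rng: np.random.Generator, n: int, box: float,
                  center: np.ndarray, min_spacing: float = MIN_SPACING) -> np.ndarray:
    """n points in a cube of side ``box`` around ``center``, pairwise >= min_spacing.

    Dart-throwing on a coarse grid; deterministic for a given generator state.
    """
    from scipy.spatial import cKDTree
    pts: list[np.ndarray] = []
    attempts = 0
    max_attempts = 200 * n
    while len(pts) < n:
        if attempts > max_attempts:
            raise RuntimeError(
                f"cannot place {n} atoms with {min_spacing} Å spacing in a {box} Å box")
        cand = center + (rng.random(3) - 0.5) * box
        attempts += 1
        if pts:
            tree = cKDTree(np.array(pts))
            if tree.query(cand, k=1)[0] < min_spacing:
                continue
        pts.append(cand)
    return np.array(pts)


def make_two_body_assembly(
    n_large: int = 400,
    n_small: int = 200,
    small_body_rotation: float = 1.4,
    axis: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[StructureModel, StructureModel, TruthTable]:
    """A reference two-body assembly and a copy with the small body rotated.

    Returns ``(reference, rotated, truth)``.  Chain "L" (large body) is
    identical in both models; chain "S" (small body) in the rotated model is
    the reference small body moved by ``small_body_rotation`` degrees about
    ``axis`` through the designated vertex atom.  The probe atom is placed
    25 Å from the vertex, perpendicular to the axis, so the vertex/probe
    protocol recovers the constructed angle exactly.
    """
    if not (0.0 <= small_body_rotation < 180.0):
        raise ValueError("rotation must be in [0, 180)")
    if n_large <= 0 or n_small < 3:
        raise ValueError("large body needs >= 1 atom, small body >= 3 (incl. vertex/probe)")
    rng = np.random.default_rng(seed)
    axis = np.array([0.0, 0.0, 1.0]) if axis is None else np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)

    box_l = max(20.0, 2.2 * (n_large * 27.0) ** (1 / 3))
    box_s = max(15.0, 2.2 * (n_small * 27.0) ** (1 / 3))
    large = _spaced_cloud(rng, n_large, box_l, np.array([0.0, 0.0, 0.0]))
    small_center = np.array([0.6 * (box_l + box_s), 0.0, 0.0])
    small = _spaced_cloud(rng, n_small - 2, box_s, small_center)

    # designated protocol atoms: vertex at the small-body center (pivot),
    # probe 25 Å away perpendicular to the rotation axis
    vertex_xyz = small_center
    perp = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    probe_xyz = vertex_xyz + 25.0 * perp

    atoms = [_ca("L", i + 1, c, "GLY") for i, c in enumerate(large)]
    small_all = np.vstack([vertex_xyz, probe_xyz, small])
    atoms += [_ca("S", i + 1, c, "ALA") for i, c in enumerate(small_all)]
    reference = StructureModel(f"twobody_ref_s{seed}", atoms)

    t = rotation_about_axis(small_body_rotation, axis, point=vertex_xyz)
    rotated_small = t.apply(small_all)
    atoms_rot = [_ca("L", i + 1, c, "GLY") for i, c in enumerate(large)]
    atoms_rot += [_ca("S", i + 1, c, "ALA") for i, c in enumerate(rotated_small)]
    rotated = StructureModel(f"twobody_rot{small_body_rotation:g}_s{seed}", atoms_rot)

    truth = TruthTable(
        transforms={"S": t},
        expected={"rotation_deg": small_body_rotation},
        vertex=("S", 1, "CA"),
        probe=("S", 2, "CA"),
    )
    return reference, rotated, truth


def make_multidomain_factor(
    domain_sizes: list[int],
    per_domain_transforms: list[RigidTransform | None],
    seed: int = 0,
    linker_length: int = 4,
    chain_id: str = "F",
) -> tuple[StructureModel, StructureModel, TruthTable]:
    """A multi-domain chain in two conformations with known per-domain motion.

    ``per_domain_transforms[i]`` moves domain ``i`` from conformation A to B
    (``None`` or identity for the anchor; domain 0 is conventionally the
    anchor).  Domains are compact seeded clouds strung along x and joined by
    ``linker_length`` interpolated residues.  The truth table records, per
    domain ``D1..Dn``, the applied transform, its rotation angle, and the
    exact centroid displacement it produces.

    Residue numbering is sequential; the truth table's ``expected`` dict also
    stores each domain's residue span as ``D<i>_first`` / ``D<i>_last`` so
    selections can be built without re-deriving the layout.
    """
    if len(domain_sizes) < 2:
        raise ValueError("need >= 2 domains")
    if len(per_domain_transforms) != len(domain_sizes):
        raise ValueError("one transform (or None) per domain required")
    rng = np.random.default_rng(seed)

    domains_a: list[np.ndarray] = []
    centers = []
    offset = 0.0
    for n in domain_sizes:
        box = max(12.0, 2.0 * (n * 27.0) ** (1 / 3))
        center = np.array([offset + box / 2.0, 0.0, 0.0])
        centers.append(center)
        domains_a.append(_spaced_cloud(rng, n, box, center))
        offset += box + linker_length * 3.5

    truth = TruthTable()
    resnum = 1
    atoms_a: list[AtomRecord] = []
    atoms_b: list[AtomRecord] = []
    spans = []
    for i, (coords, tr) in enumerate(zip(domains_a, per_domain_transforms)):
        t = tr if tr is not None else RigidTransform.identity()
        name = f"D{i}"
        first = resnum
        moved = t.apply(coords)
        for ca, cb in zip(coords, moved):
            atoms_a.append(_ca(chain_id, resnum, ca))
            atoms_b.append(_ca(chain_id, resnum, cb))
            resnum += 1
        last = resnum - 1
        spans.append((first, last))
        truth.transforms[name] = t
        truth.expected[f"{name}_rotation_deg"] = rotation_angle(t)
        truth.expected[f"{name}_centroid_displacement_A"] = float(
            np.linalg.norm(moved.mean(axis=0) - coords.mean(axis=0)))
        truth.expected[f"{name}_first"] = first
        truth.expected[f"{name}_last"] = last
        # linker between this domain and the next, interpolated per conformation
        if i < len(domain_sizes) - 1:
            nxt = domains_a[i + 1]
            nxt_t = per_domain_transforms[i + 1] or RigidTransform.identity()
            for conf_atoms, end_a, end_b in (
                (atoms_a, coords[-1], nxt[0]),
                (atoms_b, moved[-1], nxt_t.apply(nxt[0][None])[0]),
            ):
                for j in range(linker_length):
                    f = (j + 1) / (linker_length + 1)
                    conf_atoms.append(_ca(chain_id, resnum + j, (1 - f) * end_a + f * end_b, "GLY"))
            resnum += linker_length
    conf_a = StructureModel(f"factor_a_s{seed}", atoms_a)
    conf_b = StructureModel(f"factor_b_s{seed}", atoms_b)
    return conf_a, conf_b, truth


def make_factor_with_motions(
    domain_sizes: list[int],
    motions: list[tuple[float, np.ndarray, float] | None],
    seed: int = 0,
) -> tuple[StructureModel, StructureModel, TruthTable]:
    """Multi-domain factor whose domains rotate about their own centroids.

    ``motions[i]`` is ``(angle_deg, axis, displacement_A)`` or ``None`` for
    the anchor: domain i is rotated by ``angle_deg`` about ``axis`` through
    its exact centroid and its centroid translated by exactly
    ``displacement_A`` (along +y), so both truth magnitudes match the
    requested values to machine precision.  Built by generating the
    conformation-A clouds once (cloud layout depends only on sizes and
    seed), reading off the exact centroids, and regenerating with the
    centered transforms.
    """
    if len(motions) != len(domain_sizes):
        raise ValueError("one motion (or None) per domain required")
    identity = [None] * len(domain_sizes)
    conf_a, _, truth0 = make_multidomain_factor(domain_sizes, identity, seed=seed)
    transforms: list[RigidTransform | None] = []
    for i, motion in enumerate(motions):
        if motion is None:
            transforms.append(None)
            continue
        angle, axis, displacement = motion
        sel = domain_selection(truth0, f"D{i}")
        coords = np.array([a.coord for a in conf_a.atoms if sel.matches(a)])
        centroid = coords.mean(axis=0)
        transforms.append(rotation_about_axis(
            angle, axis, point=centroid,
            extra_translation=np.array([0.0, displacement, 0.0])))
    return make_multidomain_factor(domain_sizes, transforms, seed=seed)


def domain_selection(truth: TruthTable, name: str, chain_id: str = "F"):
    """SelectionExpr for a generated domain, from the truth table's spans."""
    from ribomotion.structure_model import SelectionExpr
    first = int(truth.expected[f"{name}_first"])
    last = int(truth.expected[f"{name}_last"])
    return SelectionExpr.parse(f"chain:{chain_id} res:{first}-{last}")
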