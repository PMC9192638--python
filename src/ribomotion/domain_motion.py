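"""Per-domain rigid-body motion between two conformations of a factor.

Two models (e.g. the extended GTP-analog-bound and compact GDP-bound states
of initiation factor IF2) are first superposed on a user-chosen anchor
domain (typically the G-domain).  Each remaining domain's motion is then
summarized as:

* rotation angle and axis of the Kabsch fit of its paired representative
  atoms (Cα for protein, P for RNA),
* displacement of its centroid,
* the maximum representative-atom displacement and the residue achieving
  it (figure annotations usually point at a specific Cα),
* the internal RMSD of the domain-only superposition — near zero if the
  domain really moved as a rigid body.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ribomotion.rigid_geometry import (
    InsufficientPairsError,
    kabsch_superpose,
    rotation_angle,
    rotation_axis,
)
from ribomotion.structure_model import (
    SelectionExpr,
    StructureModel,
    pair_atoms,
)

REPRESENTATIVE_ATOMS = ("CA", "P")


class DomainConfigError(Exception):
    pass


@dataclass(frozen=True)
class DomainDefinition:
    """A named domain: a selection plus the representative atom names."""

    name: str
    selection: SelectionExpr
    representative_atoms: tuple[str, ...] = REPRESENTATIVE_ATOMS

    @classmethod
    def from_text(cls, name: str, selection_text: str,
                  representative_atoms: tuple[str, ...] = REPRESENTATIVE_ATOMS) -> "DomainDefinition":
        return cls(name, SelectionExpr.parse(selection_text), tuple(representative_atoms))


@dataclass(frozen=True)
class DomainMotionResult:
    domain: str
    rotation: float                 # degrees, [0, 180]
    axis: np.ndarray                # unit vector (frame of conformation A)
    centroid_displacement: float    # Å
    max_displacement: float         # Å, over paired representative atoms
    max_displacement_residue: tuple[str, int, str]  # (chain, resnum, insertion)
    internal_rmsd: float            # Å, domain treated as rigid
    n_pairs: int
    error: str | None = None        # set when a batch entry failed

    @property
    def failed(self) -> bool:
        return self.error is not None


def _overlap(a: StructureModel, anchor: DomainDefinition, domain: DomainDefinition) -> bool:
    sel_anchor = {x.key for x in _selected(a, anchor)}
    sel_domain = {x.key for x in _selected(a, domain)}
    return bool(sel_anchor & sel_domain)


def _selected(m: StructureModel, d: DomainDefinition):
    from ribomotion.structure_model import select
    names = set(d.representative_atoms)
    return [a for a in select(m, d.selection) if a.atom_name in names]


def domain_motion(
    conf_a: StructureModel,
    conf_b: StructureModel,
    anchor: DomainDefinition,
    domain: DomainDefinition,
) -> DomainMotionResult:
    """Rigid-body motion of *domain* from conformation A to B, anchored on *anchor*."""
    if _overlap(conf_a, anchor, domain):
        raise DomainConfigError(
            f"anchor {anchor.name!r} and domain {domain.name!r} share atoms")

    # anchor B onto A
    aa, ab, _, _ = pair_atoms(conf_a, conf_b, anchor.selection,
                              atom_names=anchor.representative_atoms)
    anchor_fit = kabsch_superpose(aa, ab)
    b_anchored = conf_b.transformed(anchor_fit.transform)

    da, db, keys, _ = pair_atoms(conf_a, b_anchored, domain.selection,
                                 atom_names=domain.representative_atoms)
    if len(da) < 3:
        raise InsufficientPairsError(
            f"domain {domain.name!r}: only {len(da)} paired atoms")

    # rigid fit of the domain b -> a gives the rotation the domain underwent
    fit = kabsch_superpose(da, db)
    angle = rotation_angle(fit.transform)
    axis = rotation_axis(fit.transform) if angle > 1e-6 else np.zeros(3)

    disp = np.linalg.norm(da - db, axis=1)
    imax = int(np.argmax(disp))
    centroid_disp = float(np.linalg.norm(da.mean(axis=0) - db.mean(axis=0)))
    return DomainMotionResult(
        domain=domain.name,
        rotation=angle,
        axis=axis,
        centroid_displacement=centroid_disp,
        max_displacement=float(disp[imax]),
        max_displacement_residue=keys[imax][:3],
        internal_rmsd=fit.rmsd,
        n_pairs=len(da),
    )


def batch_domain_motions(
    conf_a: StructureModel,
    conf_b: StructureModel,
    domains: list[DomainDefinition],
    anchor_name: str,
) -> list[DomainMotionResult]:
    """One DomainMotionResult per non-anchor domain, in config order.

    Per-domain failures are recorded on the result (``error`` set, metrics
    NaN) so one bad definition does not abort the batch.
    """
    by_name = {d.name: d for d in domains}
    if anchor_name not in by_name:
        raise DomainConfigError(f"anchor {anchor_name!r} not among domain definitions")
    anchor = by_name[anchor_name]
    results = []
    for d in domains:
        if d.name == anchor_name:
            continue
        try:
            results.append(domain_motion(conf_a, conf_b, anchor, d))
        except Exception as exc:  # keep batch going, mark the entry
            results.append(DomainMotionResult(
                domain=d.name, rotation=float("nan"), axis=np.zeros(3),
                centroid_displacement=float("nan"), max_displacement=float("nan"),
                max_displacement_residue=("", 0, ""), internal_rmsd=float("nan"),
                n_pairs=0, error=f"{type(exc).__name__}: {exc}"))
    return results
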