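"""Intersubunit rotation of the small ribosomal subunit.

The measurement follows the vertex/probe convention used for ribosome
cryo-EM models: the target 70S model is superposed onto a non-rotated
reference by its 50S subunit — excluding the mobile uL1-stalk (23S rRNA
2090-2174), uL11-stalk (23S 1045-1099) and proteins uL10/uL11 — and the
rotation of the 30S is then read as the angle at a vertex atom (the
phosphate of 16S rRNA C1478 in helix h44, taken as the pivot) between the
reference's probe atom (the phosphate of U81 in the 30S foot) and the
superposed target's probe atom.  A full rigid-body Kabsch fit of the 16S
selection serves as an independent cross-check and supplies the rotation
axis, which the two-point protocol cannot define.

Anchor representative atoms are phosphorus for nucleotides and Cα for amino
acids: one atom per residue keeps the pairing robust to side-chain and
modelling differences between sister structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ribomotion.helix_geometry import angle_between
from ribomotion.rigid_geometry import kabsch_superpose, rotation_angle, rotation_axis
from ribomotion.structure_model import (
    SelectionExpr,
    StructureModel,
    StructureError,
    pair_atoms,
    select,
)

logger = logging.getLogger(__name__)

ANCHOR_ATOM_NAMES = ("P", "CA")


class ProtocolError(StructureError):
    """A vertex or probe atom required by the protocol is missing."""


@dataclass(frozen=True)
class AtomAddress:
    """(chain, residue number, atom name) of a single protocol atom."""

    chain_id: str
    residue_number: int
    atom_name: str

    def locate(self, model: StructureModel) -> np.ndarray:
        for a in model.atoms:
            if (a.chain_id == self.chain_id and a.residue_number == self.residue_number
                    and a.atom_name == self.atom_name and a.insertion == ""):
                return a.xyz
        raise ProtocolError(
            f"atom {self.chain_id}/{self.residue_number}/{self.atom_name} "
            f"not found in model {model.identifier!r}")


@dataclass(frozen=True)
class RotationProtocolConfig:
    """Anchor/mobile selections plus the vertex and probe atoms.

    ``anchor`` should already carry its exclusion terms (use
    ``SelectionExpr.excluding``); ``mobile`` is the small-subunit rRNA
    selection used for the rigid-body cross-check.
    """

    anchor: SelectionExpr
    mobile: SelectionExpr
    vertex: AtomAddress
    probe: AtomAddress
    vertex_from: str = "reference"   # or "midpoint" of reference and target vertices

    def __post_init__(self) -> None:
        if self.vertex == self.probe:
            raise ValueError("vertex and probe must differ")
        if self.vertex_from not in ("reference", "midpoint"):
            raise ValueError(f"vertex_from must be 'reference' or 'midpoint', got {self.vertex_from!r}")


@dataclass(frozen=True)
class RotationMeasurement:
    protocol_angle: float          # degrees, vertex/probe construction
    rigid_body_angle: float        # degrees, Kabsch fit of the mobile selection
    rigid_body_axis: np.ndarray    # unit vector in the reference frame
    anchor_rmsd: float             # Å, residual of the 50S anchoring
    n_anchor_pairs: int
    n_mobile_pairs: int
    mobile_rmsd: float             # Å, residual of the mobile-body rigid fit


def intersubunit_rotation(
    target: StructureModel,
    reference: StructureModel,
    config: RotationProtocolConfig,
) -> RotationMeasurement:
    """Measure the small-subunit rotation of *target* relative to *reference*."""
    # 1. anchor the target on the reference large subunit
    fa, fb, _, _ = pair_atoms(reference, target, config.anchor,
                              atom_names=ANCHOR_ATOM_NAMES)
    if len(fa) < 100:
        logger.warning("small anchor: only %d pairs", len(fa))
    anchor_fit = kabsch_superpose(fa, fb)
    target_aligned = target.transformed(anchor_fit.transform,
                                        identifier=f"{target.identifier}|anchored")

    # 2. vertex/probe protocol angle
    v_ref = config.vertex.locate(reference)
    probe_ref = config.probe.locate(reference)
    probe_tgt = config.probe.locate(target_aligned)
    if config.vertex_from == "midpoint":
        vertex = 0.5 * (v_ref + config.vertex.locate(target_aligned))
    else:
        vertex = v_ref
    protocol = angle_between(probe_ref - vertex, probe_tgt - vertex)

    # 3. rigid-body cross-check on the mobile selection
    ma, mb, _, _ = pair_atoms(reference, target_aligned, config.mobile,
                              atom_names=ANCHOR_ATOM_NAMES)
    mobile_fit = kabsch_superpose(ma, mb)
    rb_angle = rotation_angle(mobile_fit.transform)
    axis = (rotation_axis(mobile_fit.transform) if rb_angle > 1e-6
            else np.array([0.0, 0.0, 0.0]))

    return RotationMeasurement(
        protocol_angle=protocol,
        rigid_body_angle=rb_angle,
        rigid_body_axis=axis,
        anchor_rmsd=anchor_fit.rmsd,
        n_anchor_pairs=anchor_fit.n_pairs,
        n_mobile_pairs=mobile_fit.n_pairs,
        mobile_rmsd=mobile_fit.rmsd,
    )


def default_50s_anchor(
    large_chains: list[str],
    rrna_23s_chain: str,
    ul10_chain: str | None = None,
    ul11_chain: str | None = None,
) -> SelectionExpr:
    """The published anchoring selection: all 50S chains minus flexible regions.

    Excluded: 23S rRNA 2090-2174 (uL1-stalk) and 1045-1099 (uL11-stalk),
    plus the whole chains of proteins uL10 and uL11 when their chain IDs are
    supplied (chain-to-protein mapping depends on the deposition).
    """
    inc = SelectionExpr.parse("chain:" + ",".join(large_chains))
    excl_terms = [f"!chain:{rrna_23s_chain} res:2090-2174",
                  f"!chain:{rrna_23s_chain} res:1045-1099"]
    for ch in (ul10_chain, ul11_chain):
        if ch:
            excl_terms.append(f"!chain:{ch}")
    return SelectionExpr.parse(inc.text() + "; " + "; ".join(excl_terms))
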