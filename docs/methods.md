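# Methods

## Scope and model of the data

The package operates on atomic coordinate models (mmCIF/PDB) of large
assemblies — ribosomal subunits and multi-domain translation factors — and
treats conformational change as piecewise-rigid motion: subunits and
domains are compared as rigid bodies after superposition on an anchor
region, and deviations from rigidity are reported (anchor RMSD, domain
internal RMSD) rather than modelled. Author chain IDs and author residue
numbers are the canonical addressing throughout, because measurement
protocols in the structural literature cite author numbering; no sequence
alignment is attempted, so sister structures must share chain naming.

## Superposition and rotation algebra

Superposition minimizes RMSD over proper rigid transforms via SVD of the
cross-covariance matrix. When the unconstrained optimum is a reflection the
smallest singular direction is flipped (standard determinant correction):
physical motions are proper rotations. Collinear/degenerate clouds (second
singular value below 1e-12 of the first) and fewer than 3 pairs are
rejected. The rotation angle is arccos((tr R − 1)/2) with the argument
clamped to [−1, 1]; matrices are validated orthonormal (1e-6) first. The
angle has a noise floor of ~1e-6 degrees near 0° and 180° because the
arccos derivative diverges there; identity checks in the tests therefore
use 1e-5 degrees, not machine epsilon.

Screw decomposition returns the unique axis direction (unit eigenvector of
R for eigenvalue 1, oriented by the skew part), the translation component
along the axis, and the axis point nearest the origin obtained by solving
(I − R)c = t⊥ in least squares and removing the axial component. Below
1e-6° the axis is undefined and the transform is flagged as a pure
translation. Recomposition reproduces the original transform to better
than 1e-6 Å over a 100 Å cloud (verified over 1000 random transforms).

## Intersubunit rotation

Two estimates are always reported. The *protocol* angle follows the
vertex/probe convention: anchor the target on the reference large subunit
(one representative atom per residue — P for nucleotides, Cα for amino
acids — which makes pairing robust to side-chain and modelling
differences), then measure the angle at the vertex atom between the vectors
to the reference probe and to the superposed target probe. The vertex
position is taken from the reference model, which defines the unrotated
frame; a midpoint option exists for sensitivity checks. The *rigid-body*
angle is the Kabsch rotation of the full mobile (small-subunit) selection
and also supplies the axis, which a two-point construction cannot define.
The protocol angle equals the true body rotation exactly only when the
probe is perpendicular to the rotation axis through the vertex; for other
geometries it is an underestimate, which is why both numbers appear in
every report. No sign is assigned to the protocol angle (it is a magnitude);
direction information lives in the reported axis.

The default anchoring exclusions are the flexible 50S regions conventionally
removed before measuring 30S rotation: 23S rRNA 2090–2174 (uL1-stalk),
1045–1099 (uL11-stalk), and proteins uL10/uL11 as whole chains. The
chain-to-protein mapping is configuration, not code, because it differs
between depositions. Whether 5S rRNA and the remaining 50S proteins belong
in the anchor is not standardized; the default is all 50S chains minus the
exclusions, and the anchor selection is fully configurable.

## Domain motion

Conformation B is anchored onto conformation A via the anchor domain's
representative atoms (Cα default); each analysis domain is then fit B→A by
Kabsch over its paired representative atoms. Reported per domain: rotation
angle and axis, centroid displacement, maximum per-atom displacement with
the residue achieving it, and the internal RMSD of the domain-only fit.
Centroid and maximum displacement are both reported deliberately: published
displacement figures are sometimes a specific Cα and sometimes a body
average, and the two can differ severalfold when the domain also rotates.
Batch runs continue past per-domain failures and mark the failed entries.
Domain definitions (residue spans) are configuration; no automatic hinge
or domain segmentation is attempted.

## Helix axes, bends and tilts

The axis of an ordered Cα trace is estimated by the discrete-helix
construction: chord vectors v_i = p_{i+1} − p_i have differences
c_i = v_{i+1} − v_i that point radially at the axis, so successive cross
products c_i × c_{i+1} all lie along the axis; their oriented mean is the
fitted direction. This is exact for an ideal helix of any length ≥ 4
residues. The design was chosen over a principal-component fit of the
smoothed trace because short segments matter here: with the default
6-residue flanks used for kink measurement, a 7-point window covers ~1.9
helical turns, and a line fit through the smoothed points inherits a bias
of order 10° from the unbalanced final partial turn, while the
cross-product construction does not. The smoothed-trace line fit (3-residue
sliding mean, SVD principal direction) is retained as the fallback for
degenerate traces whose curvature vectors vanish (collinear input), where
it is exact. *Bend* is the angle between the fitted axes of the two
flanking segments around a kink residue in one conformation; *tilt* is the
angle between the same segment's axes in two conformations, after the
caller has placed both on a common anchor. Flank default is 6 residues —
stable on the 7–15-residue segments typical of factor helices.

## SASA, buried surface area, contacts

SASA is Shrake–Rupley quadrature: each atom is dressed with a deterministic
Fibonacci lattice (default 960 points) at radius r_vdw + r_probe
(probe 1.4 Å); the accessible fraction is the fraction of points outside
every neighbour's expanded sphere. Radii come from an element-keyed
NACCESS-flavoured table (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.10,
common ions included); explicit per-atom-name overrides take precedence
when configured — atom names alone are ambiguous (CA is both Cα and
calcium), so names are never used as an implicit radius key. Unknown
elements raise an error naming the offending atoms. Hydrogens are excluded
by default and included with a flag; comparisons against values computed
from hydrogenated models should enable the flag and carry a ±10% tolerance,
since hydrogen placement is itself under-specified. Single-sphere totals
match the analytic value to ≪1% at 960 points, two-sphere totals match the
spherical-cap closed form to 1%, and doubling the lattice changes cluster
totals by <1% — that 1% is the documented quadrature tolerance, and it also
bounds the orientation dependence of the lab-frame lattice (totals are
invariant under rigid motion only to quadrature accuracy).

Buried surface area uses the context-limited convention: context = all
non-component atoms with any component atom within the context radius
(atom-level membership, default 30 Å); buried = SASA(component alone) −
SASA(component, occluded by context). Context atoms occlude but are not
integrated. With an infinite radius this reduces to the plain two-run
difference. A per-residue breakdown is included.

Contacts are geometric classes only — no energetics: heavy-atom pairs
within 4.0 Å (vdW), N/O pairs within 3.5 Å (hydrogen-bond candidates), and
ring systems (aromatic side chains, nucleobases; purines as the fused
9-atom system) whose centroids lie within 4.5 Å with planes within 30°
(stacking candidates, keyed by a representative ring atom per residue).

## Synthetic generator

The generator emulates the *geometry* of the measured phenomena, not the
chemistry: seeded uniform atom clouds with a 3 Å minimum spacing (dart
throwing) stand in for subunits and domains, chains "L"/"S"/"F" for
large body, small body and factor. The two-body assembly rotates the small
body about a known axis through a designated vertex atom, with the probe
atom placed 25 Å away perpendicular to the axis, so both the rigid-body
metric and the vertex/probe protocol have exact expected values. The
multi-domain factor applies per-domain rigid transforms with interpolated
linker residues; `make_factor_with_motions` centers each rotation on the
domain's exact centroid so the requested rotation angle and centroid
displacement are ground truth to machine precision. Ideal helices use a
1.5 Å rise and 100° twist (radius 2.3 Å), with kinks applied as rigid
rotations of the trace beyond the kink residue. Every generator is
deterministic given a seed and writes PDB fixtures plus a JSON truth table.

What passing these tests shows: the measurement pipeline recovers known
rigid motions, kinks and occlusions exactly or within quadrature tolerance.
What it does not show: robustness to the ways real models deviate from the
synthetic idealization — partial disorder, modelling error correlated with
local resolution, genuinely non-rigid domains, alternate conformers beyond
highest-occupancy selection, and chain-naming mismatches between sister
depositions. Measurements on real depositions therefore report the
diagnostics (anchor RMSD, internal RMSD, pair counts, dropped-atom counts)
needed to judge whether the rigid-body idealization held.

## Problem sizes and defaults used in the shipped analyses

Acceptance runs use 400 + 200-atom two-body assemblies and a
60/40/40/30/30-atom five-domain factor: the anchors superpose exactly by
construction, so larger clouds add statistical weight but no information.
SASA defaults (960 points, 1.4 Å probe) follow common practice for
production-quality quadrature. Reports print degrees and Å to one decimal
and Å² as integers, with full precision retained in JSON.

## Known limitations

- Chain identity across models is by chain-ID string match only.
- The protocol angle is geometry-dependent (see above); the rigid-body
  angle is the robust quantity and both are always reported.
- SASA is numeric quadrature; no analytic (probe-rolling) surface.
- No head-swivel/tilt decomposition of the small subunit; one rotation
  value per comparison.
- Contact classes are distance/plane criteria, not chemistry.
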