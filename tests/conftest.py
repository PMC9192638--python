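"""Shared fixtures and independent oracles.

The oracles here are deliberately coded independently of the package's own
algorithms: the quaternion (Horn) superposition oracle checks the SVD-based
Kabsch fit, and the brute-force selection filter checks the selection
evaluator.
"""

from __future__ import annotations

import numpy as np
import pytest

from ribomotion.structure_model import AtomRecord, StructureModel


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def horn_superpose(fixed: np.ndarray, moving: np.ndarray):
    """Horn's quaternion-eigenvalue superposition (independent of Kabsch/SVD).

    Returns (rotation_matrix, rmsd).  The optimal rotation's quaternion is
    the eigenvector of the 4x4 key matrix with the largest eigenvalue.
    """
    fixed = np.asarray(fixed, float)
    moving = np.asarray(moving, float)
    fc = fixed - fixed.mean(axis=0)
    mc = moving - moving.mean(axis=0)
    S = mc.T @ fc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy,       Szx - Sxz,       Sxy - Syx],
        [Syz - Szy,       Sxx - Syy - Szz, Sxy + Syx,       Szx + Sxz],
        [Szx - Sxz,       Sxy + Syx,       Syy - Sxx - Szz, Syz + Szy],
        [Sxy - Syx,       Szx + Sxz,       Syz + Szy,       Szz - Sxx - Syy],
    ])
    w, v = np.linalg.eigh(K)
    q = v[:, np.argmax(w)]  # (w, x, y, z)
    a, b, c, d = q
    R = np.array([
        [a*a + b*b - c*c - d*d, 2*(b*c - a*d),         2*(b*d + a*c)],
        [2*(b*c + a*d),         a*a - b*b + c*c - d*d, 2*(c*d - a*b)],
        [2*(b*d - a*c),         2*(c*d + a*b),         a*a - b*b - c*c + d*d],
    ])
    diff = mc @ R.T - fc
    rmsd = float(np.sqrt((diff ** 2).sum() / len(fixed)))
    return R, rmsd


def quaternion_multiply(q1, q2):
    """Hamilton product, (w, x, y, z) convention."""
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array([
        w1*w2 - x1*x2 - y1*y2 - z1*z2,
        w1*x2 + x1*w2 + y1*z2 - z1*y2,
        w1*y2 - x1*z2 + y1*w2 + z1*x2,
        w1*z2 + x1*y2 - y1*x2 + z1*w2,
    ])


def axis_angle_quaternion(axis, angle_deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    half = np.deg2rad(angle_deg) / 2.0
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


# ---------------------------------------------------------------------------
# model-building helpers
# ---------------------------------------------------------------------------

def make_peptide(chain_id: str = "A", n_res: int = 10, start: int = 1,
                 offset=(0.0, 0.0, 0.0), resname: str = "ALA") -> list[AtomRecord]:
    """A fake peptide: one CA + one N + one O per residue along x."""
    atoms = []
    ox, oy, oz = offset
    for i in range(n_res):
        num = start + i
        x = ox + 3.8 * i
        atoms.append(AtomRecord(chain_id, num, "", resname, "N", "N", (x - 1.0, oy, oz)))
        atoms.append(AtomRecord(chain_id, num, "", resname, "CA", "C", (x, oy, oz)))
        atoms.append(AtomRecord(chain_id, num, "", resname, "O", "O", (x + 1.0, oy + 1.0, oz)))
    return atoms


@pytest.fixture
def peptide_model() -> StructureModel:
    return StructureModel("peptide", make_peptide())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231207)
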