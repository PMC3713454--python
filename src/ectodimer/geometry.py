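"""Rigid-body geometry: superposition, RMSD, bend angle, clashes, χ angles.

Everything here operates on plain coordinate arrays or on the light-weight
containers from :mod:`ectodimer.structio`.  The domain-II bend angle θ is the
interior angle at the hinge Cα of three anchor residues along the
dimerization face (EGFR 194/239/296 or their equivalents in other
receptors); a straight domain II gives θ near 180°, a bent one smaller
values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import NotFoundError, ResidueRef, Structure


class DegenerateInputError(ValueError):
    """Coordinate set too degenerate (collinear / too few points) to fit."""


# ---------------------------------------------------------------------------
# rigid transforms


@dataclass
class Transform:
    """Proper rigid-body transform: ``x -> R x + t`` (row convention below)."""

    rotation: np.ndarray      # (3, 3), det = +1
    translation: np.ndarray   # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (error {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("improper rotation (reflection) rejected")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array of row vectors."""
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    def inverse(self) -> "Transform":
        return Transform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_json(self) -> str:
        return json.dumps({"rotation": self.rotation.tolist(),
                           "translation": self.translation.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "Transform":
        d = json.loads(text)
        return cls(np.array(d["rotation"]), np.array(d["translation"]))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[Transform, float]:
    """Least-squares rigid superposition of paired coordinate sets.

    Returns the proper rigid transform minimizing the RMSD of
    ``transform.apply(mobile)`` to ``reference`` (Kabsch SVD solution with
    reflections rejected), together with that minimal RMSD in Å.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("need equal-length (n, 3) paired coordinate sets")
    n = len(mobile)
    if n < 3:
        raise DegenerateInputError(f"need >= 3 points, got {n}")
    mob_mean = mobile.mean(axis=0)
    ref_mean = reference.mean(axis=0)
    mob_c = mobile - mob_mean
    ref_c = reference - ref_mean
    # collinear sets leave a free rotation about the common axis
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise DegenerateInputError("mobile coordinates are collinear")
    cov = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transform = Transform(rot, ref_mean - rot @ mob_mean)
    fitted = transform.apply(mobile)
    return transform, float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))


def rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = False) -> float:
    """Root-mean-square deviation between paired coordinate sets, in Å."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    if superpose:
        return kabsch_superpose(a, b)[1]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# domain-II bend angle


@dataclass
class BendAnchors:
    """Three anchor residues (top, hinge, bottom of the dimerization face)."""

    top: ResidueRef
    hinge: ResidueRef
    bottom: ResidueRef
    atom_name: str = "CA"

    @classmethod
    def from_numbers(cls, chain_id: str, top: int, hinge: int, bottom: int,
                     atom_name: str = "CA") -> "BendAnchors":
        return cls(ResidueRef(chain_id, top), ResidueRef(chain_id, hinge),
                   ResidueRef(chain_id, bottom), atom_name)


def bend_angle(structure: Structure, anchors: BendAnchors) -> float:
    """Interior angle (degrees, in (0, 180]) at the hinge anchor atom."""
    pts = []
    for ref in (anchors.top, anchors.hinge, anchors.bottom):
        try:
            res = structure.residue(ref)
            pts.append(res.atom(anchors.atom_name).coords)
        except NotFoundError as exc:
            raise NotFoundError(f"bend anchor {ref} ({anchors.atom_name}) "
                                f"unresolvable: {exc}") from exc
    v1 = pts[0] - pts[1]
    v2 = pts[2] - pts[1]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise DegenerateInputError("coincident bend anchors")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# clash detection


def _heavy_atoms(structure: Structure):
    meta, xyz = [], []
    for ch, res, atom in structure.iter_atoms():
        if atom.element.upper() == "H":
            continue
        meta.append((ResidueRef(ch.chain_id, res.number, res.icode, res.name),
                     atom.name))
        xyz.append(atom.coords)
    return meta, (np.array(xyz) if xyz else np.zeros((0, 3)))


def detect_clashes(sel_a: Structure, sel_b: Structure, cutoff: float = 2.5
                   ) -> list[tuple[ResidueRef, str, ResidueRef, str, float]]:
    """All heavy-atom pairs across the two selections closer than ``cutoff`` Å.

    Returns ``(residue_a, atom_a, residue_b, atom_b, distance)`` tuples
    sorted by distance.  The selections must be disjoint atom sets.
    """
    meta_a, xyz_a = _heavy_atoms(sel_a)
    meta_b, xyz_b = _heavy_atoms(sel_b)
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return []
    keys_a = {(m[0].key, m[1]) for m in meta_a}
    if any((m[0].key, m[1]) in keys_a for m in meta_b):
        raise ValueError("clash selections overlap")
    tree = cKDTree(xyz_b)
    out = []
    for i, neighbours in enumerate(tree.query_ball_point(xyz_a, cutoff)):
        for j in neighbours:
            dist = float(np.linalg.norm(xyz_a[i] - xyz_b[j]))
            if dist < cutoff:
                out.append((meta_a[i][0], meta_a[i][1],
                            meta_b[j][0], meta_b[j][1], dist))
    out.sort(key=lambda rec: (rec[4], rec[0], rec[1], rec[2], rec[3]))
    return out


# ---------------------------------------------------------------------------
# side-chain χ angles

# χ dihedral atom quadruples per residue type (heavy-atom standard topology)
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# atoms rigidly carried by each χ rotation (everything distal to the axis)
CHI_ROTATES: dict[str, list[set[str]]] = {
    "ARG": [{"CG", "CD", "NE", "CZ", "NH1", "NH2"},
            {"CD", "NE", "CZ", "NH1", "NH2"},
            {"NE", "CZ", "NH1", "NH2"}, {"CZ", "NH1", "NH2"}],
    "ASN": [{"CG", "OD1", "ND2"}, {"OD1", "ND2"}],
    "ASP": [{"CG", "OD1", "OD2"}, {"OD1", "OD2"}],
    "CYS": [{"SG"}],
    "GLN": [{"CG", "CD", "OE1", "NE2"}, {"CD", "OE1", "NE2"}, {"OE1", "NE2"}],
    "GLU": [{"CG", "CD", "OE1", "OE2"}, {"CD", "OE1", "OE2"}, {"OE1", "OE2"}],
    "HIS": [{"CG", "ND1", "CD2", "CE1", "NE2"}, {"ND1", "CD2", "CE1", "NE2"}],
    "ILE": [{"CG1", "CG2", "CD1"}, {"CD1"}],
    "LEU": [{"CG", "CD1", "CD2"}, {"CD1", "CD2"}],
    "LYS": [{"CG", "CD", "CE", "NZ"}, {"CD", "CE", "NZ"}, {"CE", "NZ"}, {"NZ"}],
    "MET": [{"CG", "SD", "CE"}, {"SD", "CE"}, {"CE"}],
    "PHE": [{"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
            {"CD1", "CD2", "CE1", "CE2", "CZ"}],
    "SER": [{"OG"}],
    "THR": [{"OG1", "CG2"}],
    "TRP": [{"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
            {"CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"}],
    "TYR": [{"CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"},
            {"CD1", "CD2", "CE1", "CE2", "CZ", "OH"}],
    "VAL": [{"CG1", "CG2"}],
}


class ChiUndefinedError(ValueError):
    """The requested χ index is not defined for this residue type."""


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def chi_angle(structure: Structure, residue_ref, chi_index: int) -> float:
    """Current χ_k dihedral (degrees) of a residue."""
    res = structure.residue(residue_ref)
    defs = CHI_ATOMS.get(res.name)
    if not defs or chi_index < 1 or chi_index > len(defs):
        raise ChiUndefinedError(f"chi{chi_index} undefined for {res.name}")
    p = [res.atom(n).coords for n in defs[chi_index - 1]]
    return dihedral(*p)


def set_chi_angle(structure: Structure, residue_ref, chi_index: int,
                  delta: float) -> Structure:
    """Rotate a side chain's χ_k by ``delta`` degrees (returns a copy).

    Atoms distal to the rotated bond move rigidly; bond lengths and angles
    are untouched.  Used e.g. for the 180° χ2 flip of an interface histidine
    or for clash-resolving rotamer adjustment.
    """
    out = structure.copy()
    res = out.residue(residue_ref)
    defs = CHI_ATOMS.get(res.name)
    if not defs or chi_index < 1 or chi_index > len(defs):
        raise ChiUndefinedError(f"chi{chi_index} undefined for {res.name}")
    a, b, c, d = defs[chi_index - 1]
    axis_from = res.atom(b).coords
    axis_to = res.atom(c).coords
    axis = axis_to - axis_from
    axis = axis / np.linalg.norm(axis)
    moving = CHI_ROTATES[res.name][chi_index - 1]
    theta = np.radians(delta)
    k = axis
    for atom in res.atoms:
        if atom.name in moving:
            v = atom.coords - axis_from
            # Rodrigues rotation about the bond axis
            v_rot = (v * np.cos(theta) + np.cross(k, v) * np.sin(theta)
                     + k * np.dot(k, v) * (1 - np.cos(theta)))
            atom.coords = axis_from + v_rot
    return out
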