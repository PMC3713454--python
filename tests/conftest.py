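"""Shared fixtures: small synthetic structures built programmatically."""

import numpy as np
import pytest

from ectodimer.structio import AtomRecord, Chain, Residue, Structure


def make_residue(number: int, name: str, atom_specs) -> Residue:
    """atom_specs: list of (atom_name, element, xyz) or (..., radius)."""
    atoms = []
    for spec in atom_specs:
        radius = spec[3] if len(spec) > 3 else None
        atoms.append(AtomRecord(spec[0], spec[1], np.asarray(spec[2], float),
                                radius=radius))
    return Residue(number, name, atoms=atoms)


@pytest.fixture
def tiny_structure() -> Structure:
    """One chain, one residue, three atoms — minimal parse/write fixture."""
    res = make_residue(1, "GLY", [("N", "N", (0.0, 0.0, 0.0)),
                                  ("CA", "C", (1.458, 0.0, 0.0)),
                                  ("C", "C", (2.0, 1.4, 0.0))])
    return Structure("tiny", chains=[Chain("A", [res])])


@pytest.fixture
def helix_like_chain() -> Structure:
    """A 20-residue Cα/CB trace with varied coordinates (non-degenerate)."""
    rng = np.random.default_rng(7)
    chain = Chain("A")
    t = np.arange(20)
    ca = np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * t])
    for i in range(20):
        cb = ca[i] + rng.normal(0, 0.5, 3) + [1.0, 0, 0]
        chain.residues.append(make_residue(
            i + 1, "ALA", [("CA", "C", ca[i]), ("CB", "C", cb)]))
    return Structure("helixlike", chains=[chain])


@pytest.fixture
def lys_residue_structure() -> Structure:
    """A lysine with an extended side chain, for χ-angle manipulation."""
    res = make_residue(5, "LYS", [
        ("N", "N", (0.0, 1.0, 0.2)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (-1.2, -0.7, 0.1)),
        ("O", "O", (-1.3, -1.9, 0.0)),
        ("CB", "C", (1.3, -0.8, 0.1)),
        ("CG", "C", (2.55, 0.05, 0.2)),
        ("CD", "C", (3.8, -0.8, 0.1)),
        ("CE", "C", (5.05, 0.05, 0.2)),
        ("NZ", "N", (6.3, -0.75, 0.1)),
    ])
    return Structure("lys", chains=[Chain("A", [res])])
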