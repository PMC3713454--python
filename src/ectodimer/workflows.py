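"""Composite analyses over crystallographic inputs.

These functions wire the primitive operations (alignment, equivalence
mapping, superposition, SASA) into the handful of headline measurements the
package exists for: the domain-II bend angle of the Her2 ectodomain monomer,
cross-entry Cα RMSD of EGFR dimer structures, ectodomain sequence
identities, and domain I–III buried interface areas of dEGFR dimers.  They
operate on locally available PDB/mmCIF files and FASTA sequences supplied by
the user (see the fetch helpers in :mod:`ectodimer.cli` and the analysis
scripts).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import BendAnchors, bend_angle, kabsch_superpose, rmsd
from .metrics import buried_interface_area
from .modelbuild import DimerModel
from .seqmap import (AlignmentResult, EquivalenceMap, build_equivalence,
                     global_align, map_residues, percent_identity)
from .structio import DomainMap, NotFoundError, Structure, select

#: Cα anchors of the domain-II bend angle, in EGFR mature numbering
EGFR_BEND_ANCHORS = (194, 239, 296)
#: dimerization-critical stretch of domain II, EGFR mature numbering
EGFR_DIMERIZATION_RANGE = (240, 309)


def ectodomain_equivalence(seq_egfr: str, seq_other: str,
                           name_other: str = "OTHER") -> EquivalenceMap:
    """EGFR -> homolog residue-number map from a global ectodomain alignment.

    Both sequences must be mature-numbered (first residue = 1).
    """
    aln = global_align(seq_egfr, seq_other)
    return build_equivalence(aln, range(1, len(seq_egfr) + 1),
                             range(1, len(seq_other) + 1), "EGFR", name_other)


def mapped_bend_anchors(emap: EquivalenceMap, chain_id: str,
                        anchors: Sequence[int] = EGFR_BEND_ANCHORS) -> BendAnchors:
    """Transfer the EGFR bend anchors into a homolog's numbering."""
    mapped = map_residues(emap, anchors)
    missing = [a for a, m in zip(anchors, mapped) if m is None]
    if missing:
        raise NotFoundError(f"bend anchors {missing} align to gaps in "
                            f"{emap.receptor_b}")
    return BendAnchors.from_numbers(chain_id, *mapped)


def monomer_bend_angle(structure: Structure, seq_egfr: str, seq_monomer: str,
                       receptor_name: str = "HER2",
                       chain_id: str | None = None) -> float:
    """Domain-II bend angle θ of a homolog monomer, anchors mapped from EGFR.

    θ is the interior angle at the Cα of the hinge anchor; ~180° for a
    straight (active, ligand-bound-like) domain II and ~150–160° for the
    bent conformation characteristic of ligand-free receptors and of Her2.
    """
    emap = ectodomain_equivalence(seq_egfr, seq_monomer, receptor_name)
    chain = chain_id or structure.chains[0].chain_id
    return bend_angle(structure, mapped_bend_anchors(emap, chain))


def receptor_chains_by_size(structure: Structure, n: int = 2) -> list[str]:
    """The ``n`` largest polymer chains — the receptor subunits of a dimer
    entry, with ligands/peptides left over."""
    sizes = sorted(((len(c.residues), c.chain_id) for c in structure.chains),
                   reverse=True)
    return sorted(chain_id for _, chain_id in sizes[:n])


def dimer_ca_rmsd(st_a: Structure, st_b: Structure,
                  interval: tuple[int, int] = (1, 480),
                  chains_a: Sequence[str] | None = None,
                  chains_b: Sequence[str] | None = None) -> float:
    """Cα RMSD between two two-subunit entries over a residue interval.

    Both subunits enter a single global superposition.  The subunit
    correspondence between the two entries is not fixed a priori: both
    pairings are fitted and the smaller RMSD is returned.
    """
    ca = chains_a or receptor_chains_by_size(st_a)
    cb = chains_b or receptor_chains_by_size(st_b)
    if len(ca) != 2 or len(cb) != 2:
        raise ValueError("need two receptor chains in each structure")

    def pair_coords(chain_x: str, chain_y: str):
        res_x = {r.number: r for r in st_a.chain(chain_x).residues
                 if interval[0] <= r.number <= interval[1] and r.has_atom("CA")}
        res_y = {r.number: r for r in st_b.chain(chain_y).residues
                 if interval[0] <= r.number <= interval[1] and r.has_atom("CA")}
        common = sorted(set(res_x) & set(res_y))
        if len(common) < 3:
            raise NotFoundError(f"chains {chain_x}/{chain_y}: {len(common)} "
                                "common Cα in the interval")
        return (np.array([res_x[n].atom("CA").coords for n in common]),
                np.array([res_y[n].atom("CA").coords for n in common]))

    best = None
    for pairing in ((0, 1), (1, 0)):
        xs, ys = [], []
        for i, j in zip((0, 1), pairing):
            x, y = pair_coords(ca[i], cb[j])
            xs.append(x)
            ys.append(y)
        _, fit_rmsd = kabsch_superpose(np.vstack(xs), np.vstack(ys))
        best = fit_rmsd if best is None else min(best, fit_rmsd)
    return float(best)


def ectodomain_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of two ectodomain sequences (global alignment)."""
    return percent_identity(global_align(seq_a, seq_b))


def region_identity(seq_egfr: str, seq_other: str,
                    interval: tuple[int, int] = EGFR_DIMERIZATION_RANGE) -> float:
    """Percent identity restricted to an EGFR-numbered region.

    Columns of the global ectodomain alignment whose EGFR residue falls in
    ``interval`` form the denominator (interior gaps included), matching the
    aligned-columns convention of :func:`percent_identity`.
    """
    aln = global_align(seq_egfr, seq_other)
    lo, hi = interval
    n_cols = 0
    n_ident = 0
    for (ia, ib), col_a, col_b in zip(aln.columns, aln.aligned_a, aln.aligned_b):
        if ia is None or not (lo - 1 <= ia <= hi - 1):
            continue
        n_cols += 1
        if col_a == col_b and col_a != "-":
            n_ident += 1
    if n_cols == 0:
        raise ValueError("no alignment columns in the requested region")
    return 100.0 * n_ident / n_cols


def crystal_dimer_interface_area(structure: Structure, receptor: str = "DEGFR",
                                 restrict: Sequence[str] = ("I", "II", "III"),
                                 probe: float = 1.4, points: int = 960) -> float:
    """Domain-restricted buried interface area of a crystal dimer entry (Å²).

    The two largest chains are taken as the receptor subunits; everything
    else (bound ligands, peptides) is excluded from the metric.
    """
    rec = receptor_chains_by_size(structure)
    ligands = [c for c in structure.chain_ids if c not in rec]
    model = DimerModel(structure, (rec[0], rec[1]), ligands)
    dm = DomainMap.load(receptor)
    return buried_interface_area(model, restrict=restrict,
                                 domain_maps={rec[0]: dm, rec[1]: dm},
                                 probe=probe, points=points)
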