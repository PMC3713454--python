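"""Chimeric dimer construction by anchored rigid-body superposition.

The modelling protocol mirrors homology practice for ErbB ectodomain dimers:
start from a two-subunit template, replace one subunit with a homologous
monomer by superposing it over the dimerization-critical stretch of domain II
(EGFR 240–309 or its equivalents), optionally placing a donor whose domain II
is bent in several rigid segments, graft a ligand into the binding site over
a shared anchor region, and resolve residual side-chain clashes on a χ-angle
grid.  No energetics: every step is rigid-body geometry plus side-chain
torsions, and every superposition is recorded in the model's provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import geometry
from .geometry import CHI_ATOMS, Transform, chi_angle, detect_clashes, set_chi_angle
from .structio import (Chain, InsufficientAnchorError, NotFoundError, Residue,
                       ResidueRef, Structure, select)

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass
class DimerModel:
    """A two-subunit receptor assembly with 0–2 ligand chains and provenance."""

    structure: Structure
    receptor_chains: tuple[str, str]
    ligand_chains: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        present = set(self.structure.chain_ids)
        missing = [c for c in self.receptor_chains if c not in present]
        if len(self.receptor_chains) != 2 or missing:
            raise ValueError(f"receptor chains {missing} absent from structure")
        self.provenance.setdefault("steps", [])

    def subunit(self, which: int | str) -> Structure:
        chain_id = self.receptor_chains[which] if isinstance(which, int) else which
        return select(self.structure, chain=chain_id, warn_empty=False)

    def ligand(self, chain_id: str) -> Structure:
        if chain_id not in self.ligand_chains:
            raise NotFoundError(f"no ligand chain {chain_id!r}")
        return select(self.structure, chain=chain_id, warn_empty=False)

    def copy(self) -> "DimerModel":
        import copy as _copy
        return DimerModel(self.structure.copy(), tuple(self.receptor_chains),
                          list(self.ligand_chains),
                          _copy.deepcopy(self.provenance))

    def log_step(self, kind: str, **details) -> None:
        self.provenance["steps"].append({"kind": kind, **details})


@dataclass
class SegmentPlan:
    """Rigid segments for piecewise placement of a bent donor.

    ``segments`` pairs (donor interval, template interval), ordered and
    non-overlapping in both numberings; ``junctions`` lists donor residue
    numbers at segment borders whose backbone is blended between the two
    flanking rigid placements to restore connectivity.
    """

    segments: list[tuple[tuple[int, int], tuple[int, int]]]
    junctions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for key in (0, 1):
            spans = [seg[key] for seg in self.segments]
            if spans != sorted(spans):
                raise ValueError("plan segments must be ordered")
            for (a, b), (c, d) in zip(spans, spans[1:]):
                if c <= b:
                    raise ValueError(f"plan segments overlap: {(a, b)} and {(c, d)}")


def _anchor_pairs(template_sub: Structure, donor: Structure,
                  anchor_range: tuple[int, int], equivalence=None,
                  donor_chain: str | None = None):
    """Paired Cα coordinates over an anchor range given in template numbering."""
    t_chain = template_sub.chains[0]
    d_chain = donor.chain(donor_chain or donor.chains[0].chain_id)
    lo, hi = anchor_range
    t_xyz, d_xyz, covered = [], [], []
    for n in range(lo, hi + 1):
        d_num = equivalence.map_ab(n) if equivalence is not None else n
        if d_num is None or not t_chain.has_residue(n) or not d_chain.has_residue(d_num):
            continue
        t_res, d_res = t_chain.residue(n), d_chain.residue(d_num)
        if not (t_res.has_atom("CA") and d_res.has_atom("CA")):
            continue
        t_xyz.append(t_res.atom("CA").coords)
        d_xyz.append(d_res.atom("CA").coords)
        covered.append(n)
    return np.array(t_xyz), np.array(d_xyz), covered


def replace_subunit(template: DimerModel, donor: Structure,
                    anchor_range: tuple[int, int], equivalence=None,
                    slot: int | str = 0, donor_chain: str | None = None,
                    min_coverage: float = 0.8) -> DimerModel:
    """Replace one template subunit with a homologous donor monomer.

    The donor is rigidly superposed on the chosen subunit over the Cα atoms
    of ``anchor_range`` (template numbering; ``equivalence`` translates it to
    donor numbering), then substituted for it.  The partner subunit and any
    ligands are untouched.  Placement depends only on the anchor fit, so it
    is invariant to the donor's initial pose.
    """
    slot_id = template.receptor_chains[slot] if isinstance(slot, int) else slot
    if slot_id not in template.receptor_chains:
        raise NotFoundError(f"{slot_id!r} is not a receptor chain of the template")
    template_sub = template.subunit(slot_id)
    t_xyz, d_xyz, covered = _anchor_pairs(template_sub, donor, anchor_range,
                                          equivalence, donor_chain)
    lo, hi = anchor_range
    need = hi - lo + 1
    if len(covered) < max(3, int(np.ceil(min_coverage * need))):
        raise InsufficientAnchorError(
            f"anchor {lo}-{hi}: only {len(covered)}/{need} residues pair up")
    transform, anchor_rmsd = geometry.kabsch_superpose(d_xyz, t_xyz)

    d_chain = donor.chain(donor_chain or donor.chains[0].chain_id)
    new_chain = Chain(slot_id, [r.copy() for r in d_chain.residues])
    for res in new_chain.residues:
        for a in res.atoms:
            a.coords = transform.apply(a.coords[None, :])[0]

    out = template.copy()
    out.structure.chains = [new_chain if ch.chain_id == slot_id else ch
                            for ch in out.structure.chains]
    out.log_step("replace_subunit", slot=slot_id, donor=donor.source_id,
                 anchor_range=[lo, hi], anchor_residues=len(covered),
                 anchor_rmsd=round(anchor_rmsd, 4))
    return out


def segmented_replace(template: DimerModel, donor: Structure, plan: SegmentPlan,
                      equivalence=None, slot: int | str = 0,
                      donor_chain: str | None = None) -> DimerModel:
    """Replace a subunit by placing the donor as several rigid segments.

    Used when the donor's domain II is bent while the template's is straight:
    each donor segment is independently superposed on its template
    counterpart (Cα), residues outside all segments are dropped (and
    reported), and junction residues are linearly blended between the
    flanking placements.
    """
    slot_id = template.receptor_chains[slot] if isinstance(slot, int) else slot
    template_sub = template.subunit(slot_id)
    t_chain = template_sub.chains[0]
    d_chain = donor.chain(donor_chain or donor.chains[0].chain_id)

    transforms: list[Transform] = []
    seg_rmsds: list[float] = []
    for (d_lo, d_hi), (t_lo, t_hi) in plan.segments:
        d_nums = [n for n in range(d_lo, d_hi + 1) if d_chain.has_residue(n)]
        if equivalence is not None:
            pairs = [(equivalence.map_ba(n), n) for n in d_nums
                     if equivalence.map_ba(n) is not None]
        else:
            pairs = [(n, n) for n in d_nums]
        pairs = [(t, d) for t, d in pairs
                 if t_lo <= t <= t_hi and t_chain.has_residue(t)
                 and t_chain.residue(t).has_atom("CA")
                 and d_chain.residue(d).has_atom("CA")]
        if len(pairs) < 3:
            raise NotFoundError(
                f"segment {d_lo}-{d_hi} -> {t_lo}-{t_hi}: "
                f"only {len(pairs)} Cα pairs resolvable")
        t_xyz = np.array([t_chain.residue(t).atom("CA").coords for t, _ in pairs])
        d_xyz = np.array([d_chain.residue(d).atom("CA").coords for _, d in pairs])
        transform, seg_rmsd = geometry.kabsch_superpose(d_xyz, t_xyz)
        transforms.append(transform)
        seg_rmsds.append(round(seg_rmsd, 4))

    new_chain = Chain(slot_id)
    dropped = []
    for res in d_chain.residues:
        seg_idx = next((i for i, ((d_lo, d_hi), _) in enumerate(plan.segments)
                        if d_lo <= res.number <= d_hi), None)
        if seg_idx is None:
            dropped.append(res.number)
            continue
        new_res = res.copy()
        tr = transforms[seg_idx]
        blend = None
        if res.number in plan.junctions:
            if seg_idx + 1 < len(transforms) and res.number == plan.segments[seg_idx][0][1]:
                blend = transforms[seg_idx + 1]
            elif seg_idx > 0 and res.number == plan.segments[seg_idx][0][0]:
                blend = transforms[seg_idx - 1]
        for a in new_res.atoms:
            xyz = tr.apply(a.coords[None, :])[0]
            if blend is not None:
                xyz = 0.5 * (xyz + blend.apply(a.coords[None, :])[0])
            a.coords = xyz
        new_chain.residues.append(new_res)

    out = template.copy()
    out.structure.chains = [new_chain if ch.chain_id == slot_id else ch
                            for ch in out.structure.chains]
    out.log_step("segmented_replace", slot=slot_id, donor=donor.source_id,
                 segments=[list(map(list, seg)) for seg in plan.segments],
                 segment_rmsds=seg_rmsds, junctions=plan.junctions,
                 dropped_residues=dropped)
    return out


def graft_ligand(target: DimerModel, ligand: Structure, template_chain: str,
                 anchor_range: tuple[int, int], equivalence=None,
                 ligand_chain: str | None = None) -> DimerModel:
    """Place a ligand by superposition onto a template-bound ligand.

    ``anchor_range`` is in the template ligand's numbering (e.g. EGF 26–46);
    ``equivalence`` translates it to the incoming ligand's numbering.  The
    template ligand is removed and the graft takes over its chain id.
    """
    if template_chain not in target.ligand_chains:
        raise NotFoundError(f"template ligand chain {template_chain!r} absent")
    template_lig = target.ligand(template_chain)
    t_xyz, d_xyz, covered = _anchor_pairs(template_lig, ligand, anchor_range,
                                          equivalence, ligand_chain)
    lo, hi = anchor_range
    if len(covered) < 3:
        raise InsufficientAnchorError(
            f"ligand anchor {lo}-{hi}: only {len(covered)} residues pair up")
    transform, anchor_rmsd = geometry.kabsch_superpose(d_xyz, t_xyz)

    src = ligand.chain(ligand_chain or ligand.chains[0].chain_id)
    new_chain = Chain(template_chain, [r.copy() for r in src.residues])
    for res in new_chain.residues:
        for a in res.atoms:
            a.coords = transform.apply(a.coords[None, :])[0]

    out = target.copy()
    out.structure.chains = [new_chain if ch.chain_id == template_chain else ch
                            for ch in out.structure.chains]
    out.log_step("graft_ligand", chain=template_chain, donor=ligand.source_id,
                 anchor_range=[lo, hi], anchor_residues=len(covered),
                 anchor_rmsd=round(anchor_rmsd, 4))
    return out


def remove_ligand(model: DimerModel, ligand_chain: str) -> DimerModel:
    """Delete a ligand chain; receptor coordinates are untouched."""
    if ligand_chain not in model.ligand_chains:
        raise NotFoundError(f"no ligand chain {ligand_chain!r} in model")
    out = model.copy()
    out.structure.chains = [ch for ch in out.structure.chains
                            if ch.chain_id != ligand_chain]
    out.ligand_chains = [c for c in out.ligand_chains if c != ligand_chain]
    out.log_step("remove_ligand", chain=ligand_chain)
    return out


def _residue_clash_count(res: Residue, other_xyz: np.ndarray, cutoff: float) -> int:
    side = np.array([a.coords for a in res.atoms
                     if a.name not in _BACKBONE and a.element.upper() != "H"])
    if len(side) == 0 or len(other_xyz) == 0:
        return 0
    d2 = ((side[:, None, :] - other_xyz[None, :, :]) ** 2).sum(axis=2)
    return int((d2 < cutoff ** 2).sum())


def resolve_clashes(model: DimerModel, cutoff: float = 2.5,
                    chi_step: float = 30.0) -> DimerModel:
    """Resolve inter-subunit side-chain clashes by χ1/χ2 grid search.

    For each residue whose side chain clashes with the partner subunit, a
    grid over χ1 (and χ2 where defined) in ``chi_step`` degree increments is
    searched for the rotamer minimizing the clash count, ties broken by the
    smallest deviation from the input angles.  Backbone atoms never move;
    clashes that involve only backbone atoms are reported as unresolvable.
    Residual clashes are recorded in provenance, never fatal.
    """
    out = model.copy()
    chain_a, chain_b = out.receptor_chains
    unresolvable: list[str] = []

    def inter_clashes():
        return detect_clashes(out.subunit(0), out.subunit(1), cutoff)

    clashes = inter_clashes()
    # residues with at least one clashing side-chain atom, worst first
    from collections import Counter
    counts: Counter = Counter()
    for ref_a, name_a, ref_b, name_b, _ in clashes:
        if name_a not in _BACKBONE:
            counts[ref_a] += 1
        if name_b not in _BACKBONE:
            counts[ref_b] += 1
        if name_a in _BACKBONE and name_b in _BACKBONE:
            unresolvable.append(f"{ref_a}:{name_a}--{ref_b}:{name_b}")

    for ref, _ in counts.most_common():
        res = out.structure.residue(ref)
        n_chi = min(2, len(CHI_ATOMS.get(res.name, [])))
        if n_chi == 0:
            continue
        partner = chain_b if ref.chain_id == chain_a else chain_a
        other_xyz = np.array([a.coords for _, r, a in out.subunit(partner).iter_atoms()
                              if a.element.upper() != "H"])
        base = _residue_clash_count(res, other_xyz, cutoff)
        if base == 0:
            continue
        angles = np.arange(0.0, 360.0, chi_step)
        best = (base, 0.0, (0.0, 0.0))
        grid = [(d1, d2) for d1 in angles for d2 in (angles if n_chi == 2 else [0.0])]
        for d1, d2 in grid:
            trial = set_chi_angle(out.structure, ref, 1, d1)
            if n_chi == 2:
                trial = set_chi_angle(trial, ref, 2, d2)
            count = _residue_clash_count(trial.residue(ref), other_xyz, cutoff)
            dev = min(d1, 360 - d1) + min(d2, 360 - d2)
            if (count, dev) < (best[0], best[1]):
                best = (count, dev, (d1, d2))
        if best[2] != (0.0, 0.0):
            d1, d2 = best[2]
            out.structure = set_chi_angle(out.structure, ref, 1, d1)
            if n_chi == 2:
                out.structure = set_chi_angle(out.structure, ref, 2, d2)
            out.log_step("rotamer_adjust", residue=str(ref),
                         chi_deltas=[d1, d2][:n_chi],
                         clashes_before=int(base), clashes_after=int(best[0]))

    residual = inter_clashes()
    out.log_step("resolve_clashes", cutoff=cutoff, chi_step=chi_step,
                 initial_clashes=len(clashes), residual_clashes=len(residual),
                 backbone_unresolvable=sorted(set(unresolvable)))
    out.provenance["residual_clashes"] = [
        [str(ra), na, str(rb), nb, round(d, 3)] for ra, na, rb, nb, d in residual]
    return out
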