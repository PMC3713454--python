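"""Dimer construction: replacement, segmented placement, grafting, clashes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ectodimer.geometry import Transform, detect_clashes, kabsch_superpose
from ectodimer.modelbuild import (DimerModel, SegmentPlan, graft_ligand,
                                  remove_ligand, replace_subunit,
                                  resolve_clashes, segmented_replace)
from ectodimer.structio import (Chain, InsufficientAnchorError, NotFoundError,
                                Structure, select)
from ectodimer.synthetic import (ToyDimerParams, hinge_residue, make_toy_arm,
                                 make_toy_dimer, toy_domain_maps)

from conftest import make_residue

N = 30
M = hinge_residue(N)


@pytest.fixture
def template() -> DimerModel:
    return make_toy_dimer(ToyDimerParams(bend_a=172.0, bend_b=172.0, n_residues=N))


def _as_monomer(model: DimerModel, chain: str, source="donor") -> Structure:
    s = model.subunit(chain)
    s.source_id = source
    return s


class TestReplaceSubunit:
    def test_self_replacement_is_noop(self, template):
        donor = _as_monomer(template, "A")
        out = replace_subunit(template, donor, (1, N))
        assert np.abs(out.structure.coords() - template.structure.coords()).max() <= 1e-6
        step = out.provenance["steps"][-1]
        assert step["kind"] == "replace_subunit"
        assert step["anchor_rmsd"] <= 1e-4

    def test_pose_independent_placement(self, template):
        donor = _as_monomer(template, "A")
        rot = Rotation.from_euler("xyz", [31, -12, 77], degrees=True).as_matrix()
        moved = donor.transformed(Transform(rot, np.array([8.0, -3.0, 2.0])))
        out_a = replace_subunit(template, donor, (1, N))
        out_b = replace_subunit(template, moved, (1, N))
        assert np.abs(out_a.structure.coords() - out_b.structure.coords()).max() <= 1e-6

    def test_partner_and_provenance_untouched(self, template):
        donor = make_toy_arm(150.0, N, chain_id="Q")
        out = replace_subunit(template, donor, (M, N), slot="A")
        assert np.array_equal(out.subunit("B").coords(),
                              template.subunit("B").coords())
        assert out.receptor_chains == ("A", "B")
        # replaced subunit keeps the slot's chain id
        assert out.subunit("A").n_atoms == donor.n_atoms

    def test_insufficient_anchor_coverage(self, template):
        donor = _as_monomer(template, "A")
        donor.chains[0].residues = donor.chains[0].residues[: N // 2]
        with pytest.raises(InsufficientAnchorError):
            replace_subunit(template, donor, (1, N))


class TestSegmentedReplace:
    def test_single_segment_reduces_to_replace_subunit(self, template):
        donor = make_toy_arm(160.0, N, chain_id="A")
        whole = replace_subunit(template, donor, (1, N))
        seg = segmented_replace(template, donor, SegmentPlan([((1, N), (1, N))]))
        assert np.abs(seg.structure.coords() - whole.structure.coords()).max() <= 1e-6

    def test_bent_donor_on_straight_template_piecewise(self, template):
        """Per-segment fits of a bent arm beat the whole-body rigid fit."""
        donor = make_toy_arm(140.0, N, chain_id="A")
        t_sub = template.subunit("A")
        d_ca = select(donor, names="CA", warn_empty=False).coords()
        t_ca = select(t_sub, names="CA", warn_empty=False).coords()
        _, whole_rmsd = kabsch_superpose(d_ca, t_ca)  # oracle: one rigid body
        plan = SegmentPlan([((1, M), (1, M)), ((M + 1, N), (M + 1, N))])
        out = segmented_replace(template, donor, plan)
        seg_rmsds = out.provenance["steps"][-1]["segment_rmsds"]
        assert max(seg_rmsds) < 0.25 * whole_rmsd
        # placed arm tracks the straight template far better than one rigid fit
        placed_ca = select(out.subunit("A"), names="CA", warn_empty=False).coords()
        assert np.sqrt(np.mean(np.sum((placed_ca - t_ca) ** 2, axis=1))) < whole_rmsd

    def test_junction_blended_between_segments(self, template):
        donor = make_toy_arm(140.0, N, chain_id="A")
        plan = SegmentPlan([((1, M), (1, M)), ((M + 1, N), (M + 1, N))],
                           junctions=[M + 1])
        blended = segmented_replace(template, donor, plan)
        plain = segmented_replace(
            template, donor, SegmentPlan([((1, M), (1, M)), ((M + 1, N), (M + 1, N))]))
        moved = ~np.all(np.isclose(blended.structure.coords(),
                                   plain.structure.coords(), atol=1e-9), axis=1)
        # only the junction residue differs between the two builds
        refs = [(ch.chain_id, r.number) for ch, r, _ in blended.structure.iter_atoms()]
        assert {refs[i] for i in np.flatnonzero(moved)} == {("A", M + 1)}

    def test_unresolvable_segment_named(self, template):
        donor = make_toy_arm(140.0, N, chain_id="A")
        with pytest.raises(NotFoundError, match="777"):
            segmented_replace(template, donor,
                              SegmentPlan([((770, 777), (1, 8))]))

    def test_overlapping_plan_rejected(self):
        with pytest.raises(ValueError):
            SegmentPlan([((1, 10), (1, 10)), ((5, 20), (11, 26))])


def _with_ligand(template: DimerModel) -> DimerModel:
    lig_chain = Chain("L")
    rng = np.random.default_rng(5)
    base = np.array([3.5, 60.0, 0.0])  # off the dimer interface
    for i in range(1, 9):
        ca = base + [0.0, 3.8 * i, 0.4 * (-1) ** i]
        lig_chain.residues.append(make_residue(i, "GLY", [
            ("CA", "C", ca), ("O", "O", ca + rng.normal(0, 0.5, 3))]))
    s = template.structure.copy()
    s.chains.append(lig_chain)
    return DimerModel(s, template.receptor_chains, ["L"])


class TestLigands:
    def test_self_graft_is_noop(self, template):
        model = _with_ligand(template)
        lig = model.ligand("L")
        lig.source_id = "self"
        out = graft_ligand(model, lig, "L", (1, 8))
        assert np.abs(out.structure.coords() - model.structure.coords()).max() <= 1e-6

    def test_graft_pose_invariance_and_anchor_error(self, template):
        model = _with_ligand(template)
        lig = model.ligand("L")
        rot = Rotation.from_euler("y", 45, degrees=True).as_matrix()
        moved = lig.transformed(Transform(rot, np.array([1.0, 2.0, 3.0])))
        out = graft_ligand(model, moved, "L", (1, 8))
        assert np.abs(out.structure.coords() - model.structure.coords()).max() <= 1e-6
        with pytest.raises(InsufficientAnchorError):
            graft_ligand(model, lig, "L", (100, 120))

    def test_remove_ligand_leaves_receptors_bitwise(self, template):
        model = _with_ligand(template)
        out = remove_ligand(model, "L")
        assert out.ligand_chains == []
        for c in ("A", "B"):
            assert np.array_equal(out.subunit(c).coords(), model.subunit(c).coords())
        with pytest.raises(NotFoundError):
            remove_ligand(model, "Z")

    def test_two_ligands_remove_one(self, template):
        model = _with_ligand(template)
        s = model.structure.copy()
        second = s.chain("L").copy()
        second.chain_id = "K"
        for r in second.residues:
            for a in r.atoms:
                a.coords = a.coords + np.array([0.0, 40.0, 0.0])
        s.chains.append(second)
        model2 = DimerModel(s, model.receptor_chains, ["L", "K"])
        out = remove_ligand(model2, "K")
        assert out.ligand_chains == ["L"]
        assert "K" not in out.structure.chain_ids


def _clash_model() -> DimerModel:
    """One rotatable lysine (chain A) with its tip buried in a chain-B wall."""
    lys = make_residue(5, "LYS", [
        ("N", "N", (0.0, 1.0, 0.2)), ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (-1.2, -0.7, 0.1)), ("O", "O", (-1.3, -1.9, 0.0)),
        ("CB", "C", (1.3, -0.8, 0.1)), ("CG", "C", (2.55, 0.05, 0.2)),
        ("CD", "C", (3.8, -0.8, 0.1)), ("CE", "C", (5.05, 0.05, 0.2)),
        ("NZ", "N", (6.3, -0.75, 0.1))])
    wall = make_residue(1, "GLY", [("CB", "C", (5.5, 0.0, 0.2))])
    s = Structure(chains=[Chain("A", [lys]), Chain("B", [wall])])
    return DimerModel(s, ("A", "B"))


class TestResolveClashes:
    def test_clash_free_model_unchanged(self, template):
        out = resolve_clashes(template)
        assert np.array_equal(out.structure.coords(), template.structure.coords())
        assert out.provenance["residual_clashes"] == []

    def test_rotamer_search_matches_exhaustive_oracle(self):
        from ectodimer.geometry import set_chi_angle

        model = _clash_model()
        before = detect_clashes(model.subunit(0), model.subunit(1), 2.5)
        assert before  # the fixture does clash
        out = resolve_clashes(model, cutoff=2.5, chi_step=30.0)
        after = detect_clashes(out.subunit(0), out.subunit(1), 2.5)

        # independent exhaustive grid oracle over chi1 x chi2
        best = len(before)
        for d1 in np.arange(0.0, 360.0, 30.0):
            for d2 in np.arange(0.0, 360.0, 30.0):
                trial = set_chi_angle(model.structure, ("A", 5), 1, d1)
                trial = set_chi_angle(trial, ("A", 5), 2, d2)
                n = len(detect_clashes(
                    select(trial, chain="A", warn_empty=False),
                    select(trial, chain="B", warn_empty=False), 2.5))
                best = min(best, n)
        assert len(after) == best == 0

    def test_backbone_never_moves_and_count_never_increases(self):
        model = _clash_model()
        out = resolve_clashes(model, cutoff=2.5)
        res0 = model.structure.residue(("A", 5))
        res1 = out.structure.residue(("A", 5))
        for name in ("N", "CA", "C", "O"):
            assert np.array_equal(res0.atom(name).coords, res1.atom(name).coords)
        n_before = len(detect_clashes(model.subunit(0), model.subunit(1), 2.5))
        n_after = len(detect_clashes(out.subunit(0), out.subunit(1), 2.5))
        assert n_after <= n_before

    def test_backbone_backbone_clash_flagged_unresolvable(self):
        gly_a = make_residue(1, "GLY", [("N", "N", (0, 1.3, 0)), ("CA", "C", (0, 0, 0)),
                                        ("C", "C", (1.2, -0.7, 0))])
        gly_b = make_residue(1, "GLY", [("CA", "C", (0.8, 0.0, 0.0))])
        s = Structure(chains=[Chain("A", [gly_a]), Chain("B", [gly_b])])
        out = resolve_clashes(DimerModel(s, ("A", "B")), cutoff=2.5)
        step = out.provenance["steps"][-1]
        assert step["residual_clashes"] >= 1
        assert step["backbone_unresolvable"]
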