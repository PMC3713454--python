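"""Synthetic structures emulating the geometry the analysis pipeline assumes.

Real ErbB ectodomain dimers bury their interface through domain II: a
"straight" domain II (bend angle θ near 180°) keeps the two subunits'
dimerization faces in contact, a bent one (θ ~ 150–160°) together with a
wedge-shaped interface gap pulls the N-terminal half of the face away from
the partner.  The generators here produce desk-scale stand-ins with exactly
those two degrees of freedom — a per-subunit bend angle and an interface gap
in Å — plus Gaussian coordinate noise, so the bend-angle metric, the buried
interface area, the windowed trajectory series and the model-building steps
can all be exercised and validated without any crystallographic input.

Toy residues are alanine-like: one Cα plus one pseudo side-chain sphere (CB,
radius 1.9 Å) on the interface-forming half of each subunit, giving the SASA
and clash machinery volume to act on.  Deliberately non-physical: no claim
of thermodynamic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import BendAnchors
from .modelbuild import DimerModel
from .structio import (AtomRecord, Chain, DomainMap, Residue, Structure,
                       Trajectory)

_SPACING = 3.8          # Cα–Cα spacing along the arm, Å
_SIDE_OFFSET = 1.5      # Cα -> pseudo side-chain sphere offset, Å
_SIDE_RADIUS = 1.9      # pseudo side-chain sphere radius, Å
_SEPARATION = 7.0       # interface separation between the two Cα columns, Å


@dataclass(frozen=True)
class ToyDimerParams:
    """Study conditions for a toy two-subunit assembly."""

    bend_a: float = 170.0      # domain-II-like bend angle of subunit A, deg
    bend_b: float = 170.0      # and of subunit B
    gap: float = 0.0           # interface gap, Å (wedge at the N-terminal half)
    n_residues: int = 30       # residues per subunit
    noise_sigma: float = 0.0   # i.i.d. Gaussian coordinate noise, Å
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.bend_a <= 180.0) or not (0.0 < self.bend_b <= 180.0):
            raise ValueError("bend angles must lie in (0, 180] degrees")
        if self.gap < 0 or self.noise_sigma < 0:
            raise ValueError("gap and noise sigma must be non-negative")
        if self.n_residues < 9:
            raise ValueError("need at least 9 residues per subunit")


@dataclass(frozen=True)
class PseudoTrajectoryParams:
    """A linear closed→open (or arbitrary) interpolation with noise."""

    start: ToyDimerParams = field(default_factory=ToyDimerParams)
    end: ToyDimerParams = field(
        default_factory=lambda: ToyDimerParams(bend_a=150.0, bend_b=150.0, gap=10.0))
    n_frames: int = 21
    frame_spacing_ns: float = 20.0   # 10 frames then span a 200-ns window
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.frame_spacing_ns <= 0:
            raise ValueError("frame spacing must be positive")
        if self.start.n_residues != self.end.n_residues:
            raise ValueError("start and end must have the same topology")


def hinge_residue(n_residues: int) -> int:
    """Residue number of the arm hinge (1-based, middle of the chain)."""
    return (n_residues + 1) // 2


def toy_bend_anchors(chain_id: str, n_residues: int) -> BendAnchors:
    """Anchors (first residue, hinge, last residue) of a toy arm."""
    return BendAnchors.from_numbers(chain_id, 1, hinge_residue(n_residues),
                                    n_residues)


def toy_domain_maps(n_residues: int, chain_ids=("A", "B")) -> dict[str, DomainMap]:
    """Thirds-of-the-chain domain maps (labels I/II/III) for toy subunits."""
    third = n_residues // 3
    dm = DomainMap("TOY", {"I": (1, third), "II": (third + 1, 2 * third),
                           "III": (2 * third + 1, n_residues)})
    return {c: dm for c in chain_ids}


def _arm_coords(bend: float, n_residues: int) -> np.ndarray:
    """Cα trace of a bent arm: arms along ±y, tilted toward −x by the bend.

    A small alternating z offset (zero at the three bend anchors, which
    therefore realize the requested angle exactly) keeps every sub-segment
    non-collinear so rigid superposition on any anchor stretch is
    well-posed.
    """
    m = hinge_residue(n_residues)
    phi = np.radians((180.0 - bend) / 2.0)
    d_top = np.array([-np.sin(phi), np.cos(phi), 0.0])
    d_bot = np.array([-np.sin(phi), -np.cos(phi), 0.0])
    out = np.zeros((n_residues, 3))
    for idx in range(n_residues):
        r = idx + 1
        if r < m:
            out[idx] = d_top * (m - r) * _SPACING
        elif r > m:
            out[idx] = d_bot * (r - m) * _SPACING
        if r not in (1, m, n_residues):
            out[idx, 2] = 0.25 if r % 2 else -0.25
    return out


def make_toy_arm(bend: float, n_residues: int = 30, noise_sigma: float = 0.0,
                 seed: int = 0, chain_id: str = "A",
                 side_chains: bool = True) -> Structure:
    """A Cα-trace arm whose noise-free bend angle equals ``bend`` exactly.

    The designated anchors are :func:`toy_bend_anchors`; pseudo side-chain
    spheres sit on the N-terminal (interface-forming) half, pointing +x.
    """
    params = ToyDimerParams(bend_a=bend, bend_b=bend, n_residues=n_residues,
                            noise_sigma=noise_sigma, seed=seed)  # validation
    ca = _arm_coords(bend, n_residues)
    m = hinge_residue(n_residues)
    chain = Chain(chain_id)
    for idx in range(n_residues):
        r = idx + 1
        atoms = [AtomRecord("CA", "C", ca[idx])]
        if side_chains and r < m:
            atoms.append(AtomRecord("CB", "C", ca[idx] + [_SIDE_OFFSET, 0, 0],
                                    radius=_SIDE_RADIUS))
        chain.residues.append(Residue(r, "ALA", atoms=atoms))
    s = Structure(source_id=f"toy-arm-bend{bend:g}", chains=[chain])
    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        s.set_coords(s.coords() + rng.normal(0.0, params.noise_sigma,
                                             (s.n_atoms, 3)))
    return s


def make_toy_dimer(params: ToyDimerParams) -> DimerModel:
    """Two facing toy arms with a tunable wedge gap at the interface.

    Subunit A sits at x≈0 with side-chain spheres pointing +x; subunit B is
    its mirror at x≈7 Å with spheres pointing −x, so the sphere columns are
    4 Å apart (buried but clash-free) when the gap is closed.  The ``gap``
    parameter shears the N-terminal half of subunit B away from the
    interface: residue i of the half moves +x by ``gap·(m−i)/(m−1)`` (m the
    hinge), producing the V-shaped opening that the bend/gap metrics are
    meant to detect.  Larger gap (and smaller bend) strictly reduce the
    buried interface area.
    """
    m = hinge_residue(params.n_residues)
    arm_a = make_toy_arm(params.bend_a, params.n_residues, 0.0, params.seed, "A")
    arm_b = make_toy_arm(params.bend_b, params.n_residues, 0.0, params.seed, "B")
    # mirror B across the interface midplane
    for res in arm_b.chains[0].residues:
        for atom in res.atoms:
            atom.coords[0] = _SEPARATION - atom.coords[0]
    # wedge gap: shear B's N-terminal half away from the interface
    if params.gap > 0:
        for res in arm_b.chains[0].residues:
            if res.number < m:
                shift = params.gap * (m - res.number) / (m - 1)
                for atom in res.atoms:
                    atom.coords[0] += shift
    structure = Structure(
        source_id=f"toy-dimer-b{params.bend_a:g}-{params.bend_b:g}-g{params.gap:g}",
        chains=[arm_a.chains[0], arm_b.chains[0]])
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        structure.set_coords(structure.coords()
                             + rng.normal(0.0, params.noise_sigma,
                                          (structure.n_atoms, 3)))
    model = DimerModel(structure, ("A", "B"))
    model.provenance["generator"] = {
        "bend_a": params.bend_a, "bend_b": params.bend_b, "gap": params.gap,
        "n_residues": params.n_residues, "noise_sigma": params.noise_sigma,
        "seed": params.seed}
    return model


def make_pseudo_trajectory(params: PseudoTrajectoryParams) -> Trajectory:
    """Frames linearly interpolating start→end geometry, with Gaussian noise.

    Deterministic under a fixed seed; frame times are multiples of
    ``frame_spacing_ns`` (default 20 ns, so ten frames span the 200-ns
    averaging window used for interface-area series).
    """
    start = make_toy_dimer(replace(params.start, noise_sigma=0.0))
    end = make_toy_dimer(replace(params.end, noise_sigma=0.0))
    xyz0 = start.structure.coords()
    xyz1 = end.structure.coords()
    rng = np.random.default_rng(params.seed)
    frames = np.empty((params.n_frames, len(xyz0), 3))
    for f in range(params.n_frames):
        t = f / (params.n_frames - 1) if params.n_frames > 1 else 0.0
        frames[f] = (1.0 - t) * xyz0 + t * xyz1
        if params.noise_sigma > 0:
            frames[f] += rng.normal(0.0, params.noise_sigma, xyz0.shape)
    times = np.arange(params.n_frames) * params.frame_spacing_ns
    topology = start.structure.copy()
    topology.source_id = "toy-trajectory"
    return Trajectory(topology, frames, times)
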