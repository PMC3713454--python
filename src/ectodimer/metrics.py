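"""Quantitative observables: SASA, buried interface area, contacts, drift.

The central observable is the surface area buried within a dimer interface,

    ΔSASA = SASA(A alone) + SASA(B alone) − SASA(A ∪ B),

computed with the Shrake–Rupley probe-sphere quadrature and, following the
convention for ErbB ectodomain dimers, restricted to the contributions of
domains I–III of the two receptor subunits (ligands and the flexible domain
IV excluded).  Trajectory versions of the metrics evaluate a quantity per
frame and smooth it with a centered boxcar window (200 ns by convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .modelbuild import DimerModel
from .structio import (DomainMap, NotFoundError, ResidueRef, Structure,
                       Trajectory, _DEFAULT_RADIUS, _ELEMENT_RADII, select)


class MissingRadiusError(ValueError):
    """An atom has no explicit radius and its element is not in the table."""


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere quadrature points."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaResult:
    """Per-atom solvent-accessible surface areas (Å²)."""

    atoms: list[tuple[ResidueRef, str]]
    areas: np.ndarray
    probe: float
    points: int

    @property
    def total(self) -> float:
        return float(self.areas.sum())

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if np.any(self.areas < -1e-9):
            raise ValueError("negative per-atom area")


def _sasa_arrays(xyz: np.ndarray, radii: np.ndarray, probe: float,
                 points: int) -> np.ndarray:
    """Accessible area per atom for bare coordinate/radius arrays."""
    n = len(xyz)
    sphere = _fibonacci_sphere(points)
    expanded = radii + probe
    tree = cKDTree(xyz)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(n)
    for i in range(n):
        ri = expanded[i]
        neighbours = [j for j in tree.query_ball_point(xyz[i], ri + expanded.max())
                      if j != i]
        pts = xyz[i] + ri * sphere
        if neighbours:
            nb_xyz = xyz[neighbours]
            nb_r2 = (expanded[neighbours] ** 2)
            d2 = ((pts[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            accessible = np.all(d2 >= nb_r2[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ri * ri * frac
    return areas


def _collect_heavy(structure: Structure, strict_radii: bool = True):
    meta, xyz, radii = [], [], []
    for ch, res, atom in structure.iter_atoms():
        if atom.element.upper() == "H":
            continue
        if atom.radius is not None:
            r = atom.radius
        elif atom.element.upper() in _ELEMENT_RADII:
            r = _ELEMENT_RADII[atom.element.upper()]
        elif strict_radii:
            raise MissingRadiusError(
                f"no radius for atom {atom.name} ({atom.element}) in "
                f"{ch.chain_id}:{res.name}{res.number}")
        else:
            r = _DEFAULT_RADIUS
        meta.append((ResidueRef(ch.chain_id, res.number, res.icode, res.name),
                     atom.name))
        xyz.append(atom.coords)
        radii.append(r)
    return meta, np.asarray(xyz, float), np.asarray(radii, float)


def sasa(structure: Structure, probe: float = 1.4, points: int = 960) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area, heavy atoms only.

    ``probe`` is the solvent probe radius (1.4 Å water) and ``points`` the
    number of quadrature points per atom sphere; quadrature error scales as
    ~1/points.  Hydrogens are excluded (crystal structures lack them).
    """
    meta, xyz, radii = _collect_heavy(structure)
    if len(xyz) == 0:
        raise ValueError("structure has no heavy atoms")
    return SasaResult(meta, _sasa_arrays(xyz, radii, probe, points), probe, points)


# ---------------------------------------------------------------------------
# buried interface area


def _domain_mask(meta: list[tuple[ResidueRef, str]],
                 restrict: Sequence[str] | None,
                 domain_maps: dict[str, DomainMap] | None) -> np.ndarray:
    if restrict is None or domain_maps is None:
        return np.ones(len(meta), dtype=bool)
    mask = np.zeros(len(meta), dtype=bool)
    for i, (ref, _) in enumerate(meta):
        dm = domain_maps.get(ref.chain_id)
        if dm is None:
            continue
        label = dm.domain_of(ref.number)
        mask[i] = label in restrict
    return mask


def buried_area_pair(sub_a: Structure, sub_b: Structure, probe: float = 1.4,
                     points: int = 960,
                     restrict: Sequence[str] | None = None,
                     domain_maps: dict[str, DomainMap] | None = None) -> float:
    """ΔSASA between two sub-structures, optionally domain-restricted.

    Per-atom burial (area alone minus area in the complex) is summed over
    the atoms of either subunit whose residue falls in one of the
    ``restrict`` domains of its chain's map; with no restriction all atoms
    count.
    """
    meta_a, xyz_a, r_a = _collect_heavy(sub_a)
    meta_b, xyz_b, r_b = _collect_heavy(sub_b)
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        raise ValueError("both selections must contain heavy atoms")
    alone_a = _sasa_arrays(xyz_a, r_a, probe, points)
    alone_b = _sasa_arrays(xyz_b, r_b, probe, points)
    both = _sasa_arrays(np.vstack([xyz_a, xyz_b]), np.concatenate([r_a, r_b]),
                        probe, points)
    delta = np.concatenate([alone_a, alone_b]) - both
    mask = np.concatenate([_domain_mask(meta_a, restrict, domain_maps),
                           _domain_mask(meta_b, restrict, domain_maps)])
    return float(delta[mask].sum())


def buried_interface_area(model: DimerModel,
                          restrict: Sequence[str] | None = ("I", "II", "III"),
                          domain_maps: dict[str, DomainMap] | None = None,
                          probe: float = 1.4, points: int = 960,
                          include_ligands: bool = False) -> float:
    """Receptor–receptor buried interface area of a dimer model (Å²).

    By default the ligand chains are excluded (the metric tracks the
    receptor–receptor interface) and only atoms of domains I–III contribute,
    as in the standard presentation of ErbB ectodomain interfaces;
    ``domain_maps`` maps receptor chain id -> :class:`DomainMap`.  With
    ``domain_maps=None`` no domain restriction is applied.
    """
    chain_a, chain_b = model.receptor_chains
    extra_a = [c for c in model.ligand_chains] if include_ligands else []
    sub_a = select(model.structure, chain=chain_a, warn_empty=False)
    sub_b = select(model.structure, chain=[chain_b] + extra_a, warn_empty=False)
    if sub_a.n_atoms == 0 or sub_b.n_atoms == 0:
        raise ValueError("empty receptor subunit selection")
    if domain_maps is None:
        restrict = None
    return buried_area_pair(sub_a, sub_b, probe=probe, points=points,
                            restrict=restrict, domain_maps=domain_maps)


# ---------------------------------------------------------------------------
# windowed series


def window_average(times: np.ndarray, values: np.ndarray,
                   window: float) -> np.ndarray:
    """Centered boxcar mean over a time window; edge windows truncated.

    ``window`` is in the same unit as ``times`` (ns throughout the package);
    point ``i`` averages all samples within ``window/2`` of ``times[i]``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if times.shape != values.shape:
        raise ValueError("times and values must have equal length")
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    half = window / 2.0
    out = np.empty_like(values)
    for i, t in enumerate(times):
        mask = (times >= t - half) & (times <= t + half)
        out[i] = values[mask].mean()
    return out


@dataclass
class InterfaceSeries:
    """Per-frame buried interface area with its windowed average."""

    times: np.ndarray           # ns
    areas: np.ndarray           # Å²
    window: float               # ns
    windowed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.areas = np.asarray(self.areas, float)
        if self.windowed is None:
            self.windowed = window_average(self.times, self.areas, self.window)
        if len(self.windowed) != len(self.areas):
            raise ValueError("windowed series length mismatch")

    def summary(self) -> dict:
        return {"n_frames": int(len(self.times)),
                "window_ns": float(self.window),
                "mean": float(self.areas.mean()),
                "min": float(self.areas.min()),
                "max": float(self.areas.max()),
                "windowed_first": float(self.windowed[0]),
                "windowed_last": float(self.windowed[-1])}

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"time_ns": self.times, "buried_area_A2": self.areas,
                      "windowed_A2": self.windowed}).to_csv(path, index=False)


def interface_series(trajectory: Trajectory, receptor_chains: tuple[str, str],
                     restrict: Sequence[str] | None = ("I", "II", "III"),
                     domain_maps: dict[str, DomainMap] | None = None,
                     probe: float = 1.4, points: int = 960,
                     window: float = 200.0) -> InterfaceSeries:
    """Buried interface area per trajectory frame, plus windowed average."""
    areas = []
    for i in range(len(trajectory)):
        frame = trajectory.frame(i)
        model = DimerModel(frame, receptor_chains,
                           [c for c in frame.chain_ids if c not in receptor_chains])
        areas.append(buried_interface_area(model, restrict=restrict,
                                           domain_maps=domain_maps,
                                           probe=probe, points=points))
    return InterfaceSeries(trajectory.times, np.array(areas), window)


# ---------------------------------------------------------------------------
# contacts


_CONTACT_CUTOFFS = {"hbond": 3.5, "salt-bridge": 4.0, "cation-pi": 6.0}


@dataclass
class ContactSpec:
    """A monitored inter-subunit contact.

    ``kind``: ``hbond`` (min heavy donor–acceptor N/O distance, 3.5 Å),
    ``salt-bridge`` (min charged-group N/O distance, 4.0 Å), ``cation-pi``
    (cation nitrogen to aromatic ring centroid, 6.0 Å) or ``distance``
    (explicit atoms, explicit cutoff).  ``select_a``/``select_b`` are keyword
    dicts for :func:`ectodimer.structio.select`.
    """

    kind: str
    select_a: dict
    select_b: dict
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (*_CONTACT_CUTOFFS, "distance"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.cutoff is None:
            self.cutoff = _CONTACT_CUTOFFS.get(self.kind)
        if self.cutoff is None or self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")


_POLAR = ("N", "O")


def _contact_xyz(structure: Structure, sel_kw: dict, kind: str,
                 role: str) -> np.ndarray:
    sub = select(structure, warn_empty=False, **sel_kw)
    want_polar = kind in ("hbond", "salt-bridge")
    xyz = [a.coords for _, _, a in sub.iter_atoms()
           if a.element.upper() != "H"
           and (not want_polar or a.element.upper() in _POLAR)]
    if not xyz:
        raise NotFoundError(f"contact selection ({role}) resolves no atoms: {sel_kw}")
    return np.array(xyz)


def contact_distance(structure: Structure, spec: ContactSpec) -> float:
    """Distance (Å) realizing the contact criterion on one structure."""
    xyz_a = _contact_xyz(structure, spec.select_a, spec.kind, "A")
    xyz_b = _contact_xyz(structure, spec.select_b, spec.kind, "B")
    if spec.kind == "cation-pi":
        # side A: cation nitrogens; side B: aromatic ring -> centroid
        xyz_b = xyz_b.mean(axis=0, keepdims=True)
    d = np.sqrt(((xyz_a[:, None, :] - xyz_b[None, :, :]) ** 2).sum(axis=2))
    return float(d.min())


@dataclass
class ContactSeries:
    spec: ContactSpec
    times: np.ndarray
    distances: np.ndarray
    satisfied: np.ndarray

    def fraction_satisfied(self) -> float:
        return float(self.satisfied.mean())

    def summary(self) -> dict:
        return {"kind": self.spec.kind, "cutoff_A": float(self.spec.cutoff),
                "mean_A": float(self.distances.mean()),
                "min_A": float(self.distances.min()),
                "max_A": float(self.distances.max()),
                "fraction_satisfied": self.fraction_satisfied()}

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"time_ns": self.times, "distance_A": self.distances,
                      "satisfied": self.satisfied.astype(int)}).to_csv(path, index=False)


def contact_series(trajectory: Trajectory, spec: ContactSpec) -> ContactSeries:
    """Evaluate a contact criterion on every trajectory frame."""
    dists = np.array([contact_distance(trajectory.frame(i), spec)
                      for i in range(len(trajectory))])
    return ContactSeries(spec, trajectory.times.copy(), dists,
                         dists <= spec.cutoff)


# ---------------------------------------------------------------------------
# dimerization-arm drift


def arm_drift(trajectory: Trajectory, arm_chain: str,
              arm_interval: tuple[int, int], partner_chain: str,
              partner_interval: tuple[int, int],
              reference: int = 0) -> np.ndarray:
    """Per-frame Cα RMSD of a dimerization arm relative to the partner pocket.

    Each frame is superposed on the reference frame over the partner
    subunit's domain-II Cα atoms (``partner_interval``); the returned value
    is then the unfitted Cα RMSD of ``arm_interval`` in ``arm_chain``, so it
    measures motion of the arm within the partner's binding pocket rather
    than global tumbling.
    """
    from .geometry import kabsch_superpose, rmsd

    if not (0 <= reference < len(trajectory)):
        raise IndexError(f"reference frame {reference} out of range")

    def ca_coords(structure: Structure, chain: str, interval) -> np.ndarray:
        sub = select(structure, chain=chain, resi=tuple(interval), names="CA",
                     warn_empty=False)
        if sub.n_atoms < 3:
            raise NotFoundError(
                f"selection {chain}:{interval} resolves {sub.n_atoms} Cα")
        return sub.coords()

    ref_frame = trajectory.frame(reference)
    ref_partner = ca_coords(ref_frame, partner_chain, partner_interval)
    ref_arm = ca_coords(ref_frame, arm_chain, arm_interval)
    out = np.empty(len(trajectory))
    for i in range(len(trajectory)):
        frame = trajectory.frame(i)
        partner = ca_coords(frame, partner_chain, partner_interval)
        transform, _ = kabsch_superpose(partner, ref_partner)
        arm = transform.apply(ca_coords(frame, arm_chain, arm_interval))
        out[i] = rmsd(arm, ref_arm)
    return out
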