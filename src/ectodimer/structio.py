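"""Macromolecular structure containers, I/O, selection and domain maps.

This module holds the in-memory model used throughout the package: a
:class:`Structure` is an ordered hierarchy of chains -> residues -> atoms in
Cartesian coordinates (Å), keeping the author residue numbering of the
deposited entry (the numbering used for every residue cited in the analyses,
e.g. EGFR 194/239/296 or Her2 608).  Parsing and PDB writing are delegated to
``gemmi``; selection, domain bookkeeping and trajectory handling are defined
here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import gemmi
import numpy as np

_DATA_DIR = Path(__file__).parent / "data"

#: protein one-letter codes for sequence extraction
_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}


class FormatError(ValueError):
    """File does not parse (or cannot be written) under the named standard."""


class NotFoundError(KeyError):
    """A requested model, chain, residue or atom is absent."""


class InsufficientAnchorError(ValueError):
    """An anchor window is too small to define a rigid superposition."""


class EmptySelectionWarning(UserWarning):
    """A selection matched no atoms (returned structure is empty)."""


# ---------------------------------------------------------------------------
# containers


class ResidueRef(NamedTuple):
    """Identifier of a residue: chain id, author number, insertion code, name."""

    chain_id: str
    number: int
    icode: str = ""
    name: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    def __str__(self) -> str:  # e.g. A:GLN194
        return f"{self.chain_id}:{self.name}{self.number}{self.icode}"


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    radius: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.name, self.element, self.coords.copy(),
                          self.occupancy, self.altloc, self.radius)


@dataclass
class Residue:
    number: int
    name: str
    icode: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)
    hetero: bool = False

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise NotFoundError(f"atom {name!r} not in residue {self.name}{self.number}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def copy(self) -> "Residue":
        return Residue(self.number, self.name, self.icode,
                       [a.copy() for a in self.atoms], self.hetero)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        raise NotFoundError(f"residue {number}{icode} not in chain {self.chain_id}")

    def has_residue(self, number: int, icode: str = "") -> bool:
        return any(r.number == number and r.icode == icode for r in self.residues)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class Structure:
    """Ordered chains of ordered residues of atoms, with a source tag."""

    source_id: str = "synthetic"
    model_index: int = 1
    chains: list[Chain] = field(default_factory=list)

    # -- iteration and arrays ------------------------------------------------

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, AtomRecord]]:
        for ch in self.chains:
            for res in ch.residues:
                for atom in res.atoms:
                    yield ch, res, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def coords(self) -> np.ndarray:
        """All atomic coordinates as an (n_atoms, 3) array (copy)."""
        if self.n_atoms == 0:
            return np.zeros((0, 3))
        return np.array([a.coords for _, _, a in self.iter_atoms()])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError(f"expected {(self.n_atoms, 3)} coordinates, got {xyz.shape}")
        for i, (_, _, a) in enumerate(self.iter_atoms()):
            a.coords = xyz[i].copy()

    # -- lookup --------------------------------------------------------------

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise NotFoundError(f"chain {chain_id!r} not in structure {self.source_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def residue(self, ref: ResidueRef | tuple) -> Residue:
        chain_id, number = ref[0], ref[1]
        icode = ref[2] if len(ref) > 2 else ""
        return self.chain(chain_id).residue(number, icode)

    def atom(self, chain_id: str, number: int, atom_name: str, icode: str = "") -> AtomRecord:
        return self.chain(chain_id).residue(number, icode).atom(atom_name)

    def residue_refs(self) -> list[ResidueRef]:
        return [ResidueRef(c.chain_id, r.number, r.icode, r.name)
                for c in self.chains for r in c.residues]

    def sequence(self, chain_id: str) -> str:
        """One-letter amino-acid sequence of a chain (X for non-standard)."""
        return "".join(_3TO1.get(r.name, "X")
                       for r in self.chain(chain_id).residues if not r.hetero)

    # -- editing -------------------------------------------------------------

    def copy(self) -> "Structure":
        return Structure(self.source_id, self.model_index,
                         [c.copy() for c in self.chains])

    def transformed(self, transform) -> "Structure":
        """Return a copy with ``transform`` (geometry.Transform) applied."""
        out = self.copy()
        if out.n_atoms:
            out.set_coords(transform.apply(out.coords()))
        return out

    def validate(self) -> None:
        """Check container invariants: unique refs, monotone residue order."""
        seen: set[tuple[str, int, str]] = set()
        for ch in self.chains:
            prev = None
            for r in ch.residues:
                key = (ch.chain_id, r.number, r.icode)
                if key in seen:
                    raise ValueError(f"duplicate residue {key}")
                seen.add(key)
                order = (r.number, r.icode)
                if prev is not None and order < prev:
                    raise ValueError(
                        f"residue order not monotone in chain {ch.chain_id} at {order}")
                prev = order


# ---------------------------------------------------------------------------
# radii


def _load_radii() -> tuple[dict[str, float], float]:
    cfg = json.loads((_DATA_DIR / "radii.json").read_text())
    return {k.upper(): float(v) for k, v in cfg["elements"].items()}, float(cfg["default"])


_ELEMENT_RADII, _DEFAULT_RADIUS = _load_radii()


def atom_radius(atom: AtomRecord) -> float:
    """Van der Waals radius: explicit per-atom value, else the element table."""
    if atom.radius is not None:
        return atom.radius
    return _ELEMENT_RADII.get(atom.element.upper(), _DEFAULT_RADIUS)


def assign_radii(structure: Structure) -> Structure:
    """Stamp the element-table radius onto every atom lacking one (in place)."""
    for _, _, a in structure.iter_atoms():
        if a.radius is None:
            a.radius = atom_radius(a)
    return structure


# ---------------------------------------------------------------------------
# domain maps


@dataclass(frozen=True)
class DomainMap:
    """Inclusive residue-number intervals assigning residues to domains I–V."""

    receptor: str
    intervals: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        spans = sorted(self.intervals.values())
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if c <= b:
                raise ValueError(f"{self.receptor}: overlapping domain intervals")

    def domain_of(self, resnum: int) -> str | None:
        for label, (lo, hi) in self.intervals.items():
            if lo <= resnum <= hi:
                return label
        return None

    def interval(self, label: str) -> tuple[int, int]:
        if label not in self.intervals:
            raise NotFoundError(f"domain {label!r} not mapped for {self.receptor}")
        return self.intervals[label]

    @classmethod
    def load(cls, receptor: str, path: str | Path | None = None) -> "DomainMap":
        """Load a receptor's map from the shipped config (or an override file)."""
        cfg = json.loads(Path(path).read_text() if path
                         else (_DATA_DIR / "domain_maps.json").read_text())
        key = receptor.upper()
        if key not in cfg:
            raise NotFoundError(f"no domain map for receptor {receptor!r}")
        return cls(key, {k: (int(v[0]), int(v[1])) for k, v in cfg[key].items()})


# ---------------------------------------------------------------------------
# reading / writing


def read_structure(path: str | Path, format: str = "auto", model: int = 1,
                   altloc: str = "occupancy", keep_waters: bool = False) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Hydrogens are retained if present, waters dropped by default, hetero
    residues tagged.  ``altloc`` picks one location per atom name:
    ``"occupancy"`` keeps the highest-occupancy one, ``"first"`` the first
    encountered.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {"auto": gemmi.CoorFormat.Detect,
           "pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    gm = None
    for m in st:
        if m.num == model:
            gm = m
            break
    if gm is None:
        if model == 1:
            gm = st[0]
        else:
            raise NotFoundError(f"model {model} not present in {path}")
    return _from_gemmi_model(gm, source_id=st.name or path.stem,
                             model_index=model, altloc=altloc,
                             keep_waters=keep_waters)


def _from_gemmi_model(gm: "gemmi.Model", source_id: str, model_index: int,
                      altloc: str, keep_waters: bool) -> Structure:
    if altloc not in ("occupancy", "first"):
        raise ValueError(f"unknown altloc policy {altloc!r}")
    out = Structure(source_id=source_id, model_index=model_index)
    for gch in gm:
        chain = Chain(gch.name)
        for gres in gch:
            if gres.is_water() and not keep_waters:
                continue
            res = Residue(number=gres.seqid.num, name=gres.name,
                          icode=gres.seqid.icode.strip(),
                          hetero=(gres.het_flag == "H"))
            chosen: dict[str, AtomRecord] = {}
            for ga in gres:
                rec = AtomRecord(ga.name, ga.element.name,
                                 np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                                 occupancy=ga.occ, altloc=ga.altloc.strip())
                prev = chosen.get(ga.name)
                if prev is None:
                    chosen[ga.name] = rec
                elif altloc == "occupancy" and rec.occupancy > prev.occupancy:
                    chosen[ga.name] = rec
            res.atoms = list(chosen.values())
            for a in res.atoms:
                a.altloc = ""  # one location retained per atom name
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            out.chains.append(chain)
    return out


def to_gemmi(structure: Structure) -> "gemmi.Structure":
    """Convert to a gemmi Structure (single model)."""
    st = gemmi.Structure()
    st.name = structure.source_id
    gm = gemmi.Model(structure.model_index)
    for ch in structure.chains:
        gch = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            gres.het_flag = "H" if res.hetero else "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.b_iso = 0.0
                gres.add_atom(ga)
            gch.add_residue(gres)
        gm.add_chain(gch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path, format: str = "pdb") -> None:
    """Write a structure as PDB (coordinates kept to the format's 0.001 Å)."""
    if format != "pdb":
        raise ValueError("only PDB output is supported")
    if structure.n_atoms == 0:
        raise ValueError("refusing to write an empty structure")
    for ch in structure.chains:
        for r in ch.residues:
            if r.number > 9999 or r.number < -999:
                raise FormatError(
                    f"residue number {r.number} in chain {ch.chain_id} exceeds "
                    "the PDB fixed-column range; renumber before writing")
    if structure.n_atoms > 99999:
        raise FormatError("more than 99999 atoms cannot be written to PDB")
    to_gemmi(structure).write_pdb(str(path))


# ---------------------------------------------------------------------------
# selection


def _as_intervals(resi) -> list[tuple[int, int]]:
    """Normalize residue specs: 5, (3, 9), [5, (3, 9), ...] -> interval list."""
    if resi is None:
        return []
    if isinstance(resi, int):
        return [(resi, resi)]
    if isinstance(resi, tuple) and len(resi) == 2 and all(isinstance(x, int) for x in resi):
        return [resi]
    out = []
    for item in resi:
        out.extend(_as_intervals(item))
    return out


def _parse_selection(spec: str) -> dict:
    """Parse the mini-language: clauses joined by ``and``.

    ``chain A``, ``resi 240-309`` (also ``resi 194+239+296``), ``name CA``,
    ``domain I+II+III``, ``hetero`` / ``nothetero``.
    """
    kw: dict = {}
    for clause in (c.strip() for c in spec.split(" and ")):
        if not clause:
            continue
        tok = clause.split(None, 1)
        head = tok[0].lower()
        arg = tok[1] if len(tok) > 1 else ""
        if head == "chain":
            kw["chain"] = [c for c in arg.replace(",", "+").split("+") if c]
        elif head == "resi":
            ivals = []
            for part in arg.replace(",", "+").split("+"):
                if "-" in part[1:]:
                    a, b = part.rsplit("-", 1)
                    ivals.append((int(a), int(b)))
                else:
                    ivals.append(int(part))
            kw["resi"] = ivals
        elif head == "name":
            kw["names"] = [n for n in arg.replace(",", "+").split("+") if n]
        elif head == "domain":
            kw["domains"] = [d for d in arg.replace(",", "+").split("+") if d]
        elif head == "hetero":
            kw["hetero"] = True
        elif head == "nothetero":
            kw["hetero"] = False
        else:
            raise ValueError(f"cannot parse selection clause {clause!r}")
    return kw


def select(structure: Structure, spec: str | None = None, *,
           chain: str | Sequence[str] | None = None,
           resi=None,
           names: str | Sequence[str] | None = None,
           domains: Sequence[str] | None = None,
           domain_map: DomainMap | None = None,
           hetero: bool | None = None,
           warn_empty: bool = True) -> Structure:
    """Return the sub-structure matching the selection, order preserved.

    Criteria combine conjunctively.  ``spec`` is the string mini-language;
    keyword criteria may be used instead (or in addition).  Selecting by
    ``domains`` requires a ``domain_map`` whose labels cover the request.
    An empty result triggers :class:`EmptySelectionWarning`.
    """
    if spec:
        parsed = _parse_selection(spec)
        chain = parsed.get("chain", chain)
        resi = parsed.get("resi", resi)
        names = parsed.get("names", names)
        domains = parsed.get("domains", domains)
        hetero = parsed.get("hetero", hetero)

    chains = {chain} if isinstance(chain, str) else (set(chain) if chain else None)
    atom_names = {names} if isinstance(names, str) else (set(names) if names else None)
    intervals = _as_intervals(resi)
    if domains:
        if domain_map is None:
            raise ValueError("domain selection requires a domain_map")
        missing = [d for d in domains if d not in domain_map.intervals]
        if missing:
            raise NotFoundError(f"domains {missing} absent from map {domain_map.receptor}")
        intervals = intervals + [domain_map.interval(d) for d in domains]

    def keep_res(ch: Chain, r: Residue) -> bool:
        if chains is not None and ch.chain_id not in chains:
            return False
        if intervals and not any(lo <= r.number <= hi for lo, hi in intervals):
            return False
        if hetero is not None and r.hetero != hetero:
            return False
        return True

    out = Structure(source_id=structure.source_id, model_index=structure.model_index)
    for ch in structure.chains:
        new_ch = Chain(ch.chain_id)
        for r in ch.residues:
            if not keep_res(ch, r):
                continue
            atoms = [a.copy() for a in r.atoms
                     if atom_names is None or a.name in atom_names]
            if atoms:
                new_ch.residues.append(Residue(r.number, r.name, r.icode, atoms, r.hetero))
        if new_ch.residues:
            out.chains.append(new_ch)
    if out.n_atoms == 0 and warn_empty:
        warnings.warn("selection matched no atoms", EmptySelectionWarning, stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# filling missing residues from a donor entry


def merge_missing_residues(target: Structure, donor: Structure,
                           residue_range: tuple[int, int],
                           anchor_window, *,
                           target_chain: str | None = None,
                           donor_chain: str | None = None) -> Structure:
    """Fill a missing residue range in ``target`` from a homologous ``donor``.

    The donor is rigidly superposed on the target over shared Cα atoms of
    ``anchor_window`` (an interval or a list of intervals flanking the gap,
    sharing the target's numbering), then donor residues in ``residue_range``
    are copied in.  Mirrors the practice of completing unresolved loops of one
    crystal form from another deposited entry of the same molecule.
    """
    from .geometry import kabsch_superpose  # local import: keeps layering acyclic

    t_chain = target.chain(target_chain or target.chains[0].chain_id)
    d_chain = donor.chain(donor_chain or donor.chains[0].chain_id)
    lo, hi = residue_range

    present = [n for n in range(lo, hi + 1) if t_chain.has_residue(n)]
    if len(present) == hi - lo + 1:
        warnings.warn(f"residues {lo}-{hi} already present; nothing merged",
                      UserWarning, stacklevel=2)
        return target.copy()
    missing_donor = [n for n in range(lo, hi + 1) if not d_chain.has_residue(n)]
    if missing_donor:
        raise NotFoundError(f"donor lacks residues {missing_donor} of the fill range")

    anchor_nums = sorted({n for lo_a, hi_a in _as_intervals(anchor_window)
                          for n in range(lo_a, hi_a + 1)})
    pairs = [(t_chain.residue(n).atom("CA").coords, d_chain.residue(n).atom("CA").coords)
             for n in anchor_nums
             if t_chain.has_residue(n) and d_chain.has_residue(n)
             and t_chain.residue(n).has_atom("CA") and d_chain.residue(n).has_atom("CA")]
    if len(pairs) < 3:
        raise InsufficientAnchorError(
            f"anchor window resolves only {len(pairs)} shared Cα (need >= 3)")
    t_xyz = np.array([p[0] for p in pairs])
    d_xyz = np.array([p[1] for p in pairs])
    transform, _ = kabsch_superpose(d_xyz, t_xyz)

    out = target.copy()
    out_chain = out.chain(t_chain.chain_id)
    for n in range(lo, hi + 1):
        if out_chain.has_residue(n):
            continue
        res = d_chain.residue(n).copy()
        for a in res.atoms:
            a.coords = transform.apply(a.coords[None, :])[0]
        idx = next((i for i, r in enumerate(out_chain.residues)
                    if (r.number, r.icode) > (n, "")), len(out_chain.residues))
        out_chain.residues.insert(idx, res)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology, with times in ns."""

    topology: Structure
    frames: np.ndarray          # (n_frames, n_atoms, 3)
    times: np.ndarray           # (n_frames,), ns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"{self.topology.n_atoms}")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> Structure:
        """Materialize frame ``i`` as a Structure."""
        s = self.topology.copy()
        s.set_coords(self.frames[i])
        return s

    @classmethod
    def from_structures(cls, structures: Sequence[Structure],
                        times: Sequence[float] | None = None,
                        spacing_ns: float = 20.0) -> "Trajectory":
        if not structures:
            raise ValueError("need at least one frame")
        n = structures[0].n_atoms
        for i, s in enumerate(structures):
            if s.n_atoms != n:
                raise ValueError(f"frame {i}: atom count {s.n_atoms} != {n}")
        frames = np.stack([s.coords() for s in structures])
        if times is None:
            times = np.arange(len(structures)) * spacing_ns
        return cls(structures[0].copy(), frames, np.asarray(times, float))

    @classmethod
    def from_multimodel_pdb(cls, path: str | Path, spacing_ns: float = 20.0,
                            altloc: str = "occupancy") -> "Trajectory":
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        if len(st) == 0:
            raise FormatError(f"{path}: no models")
        frames = [_from_gemmi_model(m, source_id=st.name or Path(path).stem,
                                    model_index=m.num, altloc=altloc,
                                    keep_waters=False)
                  for m in st]
        return cls.from_structures(frames, spacing_ns=spacing_ns)

    @classmethod
    def from_mdanalysis(cls, topology_path: str | Path, trajectory_path: str | Path,
                        spacing_ns: float | None = None) -> "Trajectory":
        """Adapter for binary trajectory formats via MDAnalysis (optional dep)."""
        import MDAnalysis as mda

        u = mda.Universe(str(topology_path), str(trajectory_path))
        top = read_structure(topology_path)
        frames, times = [], []
        for ts in u.trajectory:
            frames.append(ts.positions.astype(float).copy())
            times.append(ts.time / 1000.0)  # ps -> ns
        frames = np.stack(frames)
        if frames.shape[1] != top.n_atoms:
            raise ValueError("MDAnalysis atom count differs from parsed topology")
        times = np.asarray(times)
        if spacing_ns is not None or not np.all(np.diff(times) > 0):
            times = np.arange(len(frames)) * (spacing_ns or 1.0)
        return cls(top, frames, times)

    def write_multimodel_pdb(self, path: str | Path) -> None:
        st = gemmi.Structure()
        st.name = self.topology.source_id
        for i in range(len(self)):
            gm = to_gemmi(self.frame(i))[0]
            gm.num = i + 1
            st.add_model(gm)
        st.setup_entities()
        st.write_pdb(str(path))
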