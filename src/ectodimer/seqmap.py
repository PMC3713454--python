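"""Pairwise sequence alignment, percent identity and residue equivalence maps.

Residue-level definitions in this package (bend-angle anchors, interface
contact residues, the 240–309 dimerization stretch) are stated in EGFR
numbering; this module transfers them to Her2, Her3 or dEGFR through a
global alignment of the ectodomain sequences.  Alignment itself is done with
Biopython's ``PairwiseAligner``; scoring defaults are BLOSUM62 with gap
open 10 / extend 0.5 and free terminal gaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

_VALID = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYXBZJUO]+$")

GAP = None  #: marker for a residue aligned to a gap


@dataclass
class AlignmentParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    free_end_gaps: bool = True


@dataclass
class AlignmentResult:
    """A pairwise global alignment: gapped strings plus per-column indices."""

    aligned_a: str
    aligned_b: str
    score: float
    #: per column: (index into A or None, index into B or None)
    columns: list[tuple[int | None, int | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")
        if not self.columns:
            self.columns = _columns_from_gapped(self.aligned_a, self.aligned_b)

    @property
    def sequence_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def sequence_b(self) -> str:
        return self.aligned_b.replace("-", "")

    def __len__(self) -> int:
        return len(self.aligned_a)

    def format(self, width: int = 60) -> str:
        """Plain-text columnar dump (match line between the two sequences)."""
        out = []
        marks = "".join("|" if (a == b and a != "-") else " "
                        for a, b in zip(self.aligned_a, self.aligned_b))
        for i in range(0, len(self.aligned_a), width):
            out.append(self.aligned_a[i:i + width])
            out.append(marks[i:i + width])
            out.append(self.aligned_b[i:i + width])
            out.append("")
        return "\n".join(out)


def _columns_from_gapped(ga: str, gb: str) -> list[tuple[int | None, int | None]]:
    cols, ia, ib = [], 0, 0
    for ca, cb in zip(ga, gb):
        a_idx = ia if ca != "-" else None
        b_idx = ib if cb != "-" else None
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        cols.append((a_idx, b_idx))
    return cols


def _check_sequence(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"sequence {label} is empty")
    seq = seq.upper()
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACDEFGHIKLMNPQRSTVWYXBZJUO"))
        raise ValueError(f"sequence {label} has non-amino-acid characters {bad}")
    return seq


def global_align(seq_a: str, seq_b: str,
                 params: AlignmentParams | None = None) -> AlignmentResult:
    """Optimal global alignment of two amino-acid sequences.

    With ``free_end_gaps`` (default) terminal gaps are unpenalized, which is
    the appropriate mode for comparing ectodomain constructs of slightly
    different spans.  Tie-breaking is deterministic (first optimal path of
    the aligner's ordered traceback).
    """
    params = params or AlignmentParams()
    seq_a = _check_sequence(seq_a, "A")
    seq_b = _check_sequence(seq_b, "B")
    matrix = substitution_matrices.load(params.matrix)
    # residues outside the matrix alphabet are treated as X
    alphabet = set(str(matrix.alphabet))
    sa = "".join(c if c in alphabet else "X" for c in seq_a)
    sb = "".join(c if c in alphabet else "X" for c in seq_b)

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if params.free_end_gaps:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Biopython attribute names
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    aligner.mode = "global"
    aln = aligner.align(sa, sb)[0]
    return AlignmentResult(str(aln[0]), str(aln[1]), float(aln.score))


def percent_identity(alignment: AlignmentResult,
                     mode: str = "aligned-columns") -> float:
    """Percent identity of an alignment.

    ``aligned-columns`` (default): identical pairs over the columns of the
    core alignment, i.e. excluding terminal-gap overhangs at either end but
    counting interior gap columns in the denominator.  ``shorter-sequence``:
    identical pairs over the length of the shorter input.
    """
    ga, gb = alignment.aligned_a, alignment.aligned_b
    ident = sum(1 for a, b in zip(ga, gb) if a == b and a != "-")
    if mode == "shorter-sequence":
        denom = min(len(alignment.sequence_a), len(alignment.sequence_b))
    elif mode == "aligned-columns":
        both = [i for i, (a, b) in enumerate(zip(ga, gb)) if a != "-" and b != "-"]
        if not both:
            return 0.0
        denom = both[-1] - both[0] + 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 100.0 * ident / denom


@dataclass
class EquivalenceMap:
    """Residue-number correspondence between two receptors' numbering schemes.

    Built from the non-gap columns of a pairwise alignment; bijective and
    monotone by construction.
    """

    receptor_a: str
    receptor_b: str
    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        a_nums = [p[0] for p in self.pairs]
        b_nums = [p[1] for p in self.pairs]
        if len(set(a_nums)) != len(a_nums) or len(set(b_nums)) != len(b_nums):
            raise ValueError("equivalence map is not bijective")
        if a_nums != sorted(a_nums) or b_nums != sorted(b_nums):
            raise ValueError("equivalence map is not monotone")
        self._ab = dict(self.pairs)
        self._ba = {b: a for a, b in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def invert(self) -> "EquivalenceMap":
        return EquivalenceMap(self.receptor_b, self.receptor_a,
                              [(b, a) for a, b in self.pairs])

    def map_ab(self, number: int) -> int | None:
        return self._ab.get(number)

    def map_ba(self, number: int) -> int | None:
        return self._ba.get(number)

    def to_csv(self, path: str | Path) -> None:
        lines = [f"{self.receptor_a},{self.receptor_b}"]
        lines += [f"{a},{b}" for a, b in self.pairs]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "EquivalenceMap":
        lines = Path(path).read_text().strip().splitlines()
        ra, rb = lines[0].split(",")
        pairs = [tuple(int(x) for x in ln.split(",")) for ln in lines[1:]]
        return cls(ra, rb, pairs)  # type: ignore[arg-type]


def build_equivalence(alignment: AlignmentResult,
                      numbering_a: Sequence[int],
                      numbering_b: Sequence[int],
                      receptor_a: str = "A",
                      receptor_b: str = "B") -> EquivalenceMap:
    """Turn an alignment into a numbering correspondence.

    ``numbering_a``/``numbering_b`` give the author residue numbers of the
    ungapped sequences in order (e.g. ``range(1, n + 1)`` for a mature
    ectodomain).  The map covers exactly the non-gap columns.
    """
    na, nb = list(numbering_a), list(numbering_b)
    if len(na) != len(alignment.sequence_a):
        raise ValueError(f"numbering A has {len(na)} entries for "
                         f"{len(alignment.sequence_a)} residues")
    if len(nb) != len(alignment.sequence_b):
        raise ValueError(f"numbering B has {len(nb)} entries for "
                         f"{len(alignment.sequence_b)} residues")
    pairs = [(na[ia], nb[ib]) for ia, ib in alignment.columns
             if ia is not None and ib is not None]
    return EquivalenceMap(receptor_a, receptor_b, pairs)


def map_residues(emap: EquivalenceMap, refs: Iterable[int],
                 direction: str = "ab") -> list[int | None]:
    """Map residue numbers through an equivalence map.

    Unmapped inputs (aligned to a gap, or outside coverage) come back as
    ``None`` in place — never silently dropped.
    """
    fn = emap.map_ab if direction == "ab" else emap.map_ba
    return [fn(r) for r in refs]


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{record id: sequence}`` (order preserved)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
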