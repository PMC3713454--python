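#!/usr/bin/env python
"""Fetch the crystallographic and sequence inputs (network required).

Downloads the PDB entries used by the crystal-structure analyses and the
UniProt precursor sequences of the human receptors, slices the mature
ectodomains (signal peptide removed, numbering starting at 1, which is the
numbering used for every residue-level definition in this package) and
writes them to ``data/crystal/`` and ``data/sequences/ectodomains.fasta``.

Entries:
  3NJP / 1IVO / 1MOX  2-ligand human EGFR ectodomain dimers
  1NQL / 1YY9         ligand-free EGFR ectodomain monomers
  3BE1 / 1S78 / 2A91  Her2 ectodomain monomers (3BE1 is the modelling source;
                      1S78/2A91 donate residues missing from 3BE1 domains I–III)
  1M6B                tethered Her3 ectodomain monomer
  1HAE                heregulin-alpha EGF-like domain (HRG)
  3LTF                2-ligand (Spitz-bound) asymmetric dEGFR ectodomain dimer
  3I2T                ligand-free dEGFR ectodomain dimer

None of these files is redistributed here; run this script once on a
machine with internet access.
"""

import sys
import urllib.request
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
CRYSTAL = ROOT / "data" / "crystal"
SEQDIR = ROOT / "data" / "sequences"

PDB_ENTRIES = ["3NJP", "1IVO", "1MOX", "1NQL", "1YY9", "3BE1", "1S78",
               "2A91", "1M6B", "1HAE", "3LTF", "3I2T"]

# (uniprot accession, FASTA id, signal-peptide length, mature ectodomain length)
UNIPROT = [("P00533", "EGFR", 24, 620),
           ("P04626", "HER2", 22, 630),
           ("P21860", "HER3", 19, 624)]


def fetch_pdb() -> None:
    CRYSTAL.mkdir(parents=True, exist_ok=True)
    for acc in PDB_ENTRIES:
        dest = CRYSTAL / f"{acc}.pdb"
        if dest.exists():
            print(f"{acc}: cached")
            continue
        url = f"https://files.rcsb.org/download/{acc}.pdb"
        print(f"{acc}: {url}")
        urllib.request.urlretrieve(url, dest)


def fetch_sequences() -> None:
    SEQDIR.mkdir(parents=True, exist_ok=True)
    out = SEQDIR / "ectodomains.fasta"
    records = []
    for acc, name, signal, length in UNIPROT:
        url = f"https://rest.uniprot.org/uniprotkb/{acc}.fasta"
        print(f"{name}: {url}")
        with urllib.request.urlopen(url) as fh:
            lines = fh.read().decode().splitlines()
        seq = "".join(l.strip() for l in lines if not l.startswith(">"))
        mature = seq[signal:signal + length]
        records.append(f">{name} {acc} mature ectodomain 1-{len(mature)}\n"
                       + "\n".join(mature[i:i + 60]
                                   for i in range(0, len(mature), 60)))
    out.write_text("\n".join(records) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    try:
        fetch_pdb()
        fetch_sequences()
    except Exception as exc:
        sys.exit(f"fetch failed ({exc}); this script needs internet access")
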