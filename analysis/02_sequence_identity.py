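#!/usr/bin/env python
"""Ectodomain sequence identities and the EGFR->homolog equivalence maps.

With ``data/sequences/ectodomains.fasta`` present (see
``00_fetch_inputs.py``) this computes, for Her2 and Her3 against EGFR:
the full-ectodomain percent identity (reference values 40% and 41%), the
identity over the dimerization-critical EGFR 240–309 stretch (50% and 46%)
and the residue-equivalence maps used to transfer EGFR-numbered anchors,
writing ``results/identity.csv`` and ``results/equivalence_EGFR_<X>.csv``.
"""

from pathlib import Path

import pandas as pd

from ectodimer.seqmap import read_fasta
from ectodimer.workflows import (EGFR_BEND_ANCHORS, EGFR_DIMERIZATION_RANGE,
                                 ectodomain_equivalence, ectodomain_identity,
                                 region_identity)
from ectodimer.seqmap import map_residues

ROOT = Path(__file__).resolve().parent.parent
SEQS = ROOT / "data" / "sequences" / "ectodomains.fasta"
OUT = ROOT / "results"


def main() -> None:
    if not SEQS.exists():
        print(f"{SEQS} not found - run analysis/00_fetch_inputs.py first "
              "(network required); nothing to do offline.")
        return
    OUT.mkdir(parents=True, exist_ok=True)
    seqs = read_fasta(SEQS)
    rows = []
    for other in ("HER2", "HER3"):
        full = ectodomain_identity(seqs["EGFR"], seqs[other])
        region = region_identity(seqs["EGFR"], seqs[other],
                                 EGFR_DIMERIZATION_RANGE)
        rows.append({"pair": f"EGFR-{other}",
                     "ectodomain_identity_pct": round(full, 2),
                     "region_240_309_identity_pct": round(region, 2)})
        print(f"EGFR vs {other}: ectodomain identity {full:5.2f}%, "
              f"240-309 region {region:5.2f}%")
        emap = ectodomain_equivalence(seqs["EGFR"], seqs[other], other)
        emap.to_csv(OUT / f"equivalence_EGFR_{other}.csv")
        anchors = map_residues(emap, EGFR_BEND_ANCHORS)
        print(f"  bend anchors EGFR {EGFR_BEND_ANCHORS} -> {other} {anchors}")
    pd.DataFrame(rows).to_csv(OUT / "identity.csv", index=False)
    print(f"wrote {OUT / 'identity.csv'}")


if __name__ == "__main__":
    main()
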