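# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic generators do and do not emulate, and the
known limitations.

## Coordinate model and numbering

Structures are ordered hierarchies of chains → residues → atoms in
Cartesian Å, parsed from PDB/mmCIF with gemmi and written back as PDB
(coordinates preserved to the format's 0.001 Å). Author numbering of the
deposited entries is kept throughout — it is the numbering in which all
residue-level definitions are stated (EGFR 194/239/296 bend anchors, the
240–309 dimerization stretch, Her2 213/215/243/291, EGF 26–46) — and no
renumbering is ever applied on input. Waters are dropped on read; one
alternate location is kept per atom name (highest occupancy by default,
first-encountered on request); hydrogens are retained when present but are
excluded from SASA and contact geometry, since the crystal inputs lack
them and all contact criteria are defined on heavy atoms.

Domain maps assign inclusive author-numbering intervals to ectodomain
domains I–V per receptor and ship as JSON
(`src/ectodimer/data/domain_maps.json`). EGFR (mature numbering) is the
reference: I = 1–165, II = 166–310, III = 311–480, IV = 481–620, chosen so
that the dimerization-critical 240–309 stretch and the three bend anchors
all fall in domain II. The Her2/Her3/dEGFR intervals are alignment-offset
estimates (Her3 numbering tracks EGFR's almost exactly; Her2 runs ~6
residues ahead in domain II; dEGFR ~5 behind, with a fifth domain before
the transmembrane helix). All maps are config-overridable, and the
recommended practice when sequences are available is to regenerate them
through the equivalence maps (`analysis/02_sequence_identity.py` writes
these as CSV).

## Sequence alignment and residue equivalence

Cross-receptor transfer of EGFR-numbered definitions uses a pairwise
global alignment (Biopython `PairwiseAligner`): BLOSUM62, gap open 10,
extend 0.5, terminal gaps free. Free end gaps are the right mode for
ectodomain constructs of slightly different spans; the scoring itself is a
conventional default, and the identity figures it produces should be read
with a ±(2–3) percentage-point method sensitivity, which is why the
acceptance checks on identities carry a ±3-point band. Percent identity
uses identical pairs over the core alignment columns (terminal-gap
overhangs excluded, interior gap columns counted); a shorter-sequence
denominator is available. Equivalence maps keep exactly the non-gap
columns, are bijective and monotone by construction, and report unmapped
residues explicitly rather than dropping them. Alignment scores are
validated against an independent Gotoh three-matrix dynamic-programming
oracle in the test suite.

## Rigid-body geometry

Superposition is the Kabsch SVD solution with reflections rejected
(determinant correction); inputs with fewer than three points or collinear
point sets raise a degenerate-input error rather than returning one of the
infinitely many minimizers. The bend angle θ is the interior Cα–Cα–Cα
angle at the hinge anchor, in (0°, 180°] — the plain reading of a
three-point bend measure; no midpoint-vector variant is used. Clash
detection enumerates heavy-atom pairs across two disjoint selections below
a cutoff (default 2.5 Å — "minor clash" territory for heavy atoms),
sorted by distance, via a KD-tree and verified against an all-pairs oracle
in tests.

Side-chain χ angles follow the standard heavy-atom topology (χ1–χ4
quadruples per residue type; proline excluded as a ring). Rotations move
exactly the atoms distal to the χ bond via Rodrigues rotation about the
bond axis, preserving bond lengths and angles to 1e-6 Å; the dihedral
convention is the usual signed IUPAC one (trans = 180°).

## Model building

`replace_subunit` places a homologous donor monomer onto one subunit of a
template dimer by superposing Cα atoms over an anchor range given in
template numbering (translated to donor numbering by an equivalence map),
requiring ≥80% anchor coverage. Placement depends only on the anchor fit,
so it is invariant to the donor's initial pose; the anchor RMSD of every
superposition is recorded in the model's provenance. `segmented_replace`
places the donor as several independent rigid segments — the treatment a
bent domain II needs on a straight template — and linearly blends listed
junction residues between the two flanking rigid placements (a 50/50
coordinate average) to restore connectivity; no minimization is applied,
and the blend is reported. Residues outside all segments are dropped and
reported. `graft_ligand` superposes an incoming ligand onto a
template-bound ligand over a shared anchor region and takes over its chain
id; `merge_missing_residues` fills unresolved ranges from a sister entry
after anchoring on flanking residues.

`resolve_clashes` is a deliberately minimal rotamer search: for each
residue whose side chain clashes with the partner subunit, a χ1×χ2 grid in
30° steps is scanned for the rotamer minimizing the inter-subunit clash
count, ties broken by least deviation from the input; the backbone never
moves, intra-chain strain is not scored, and clashes involving only
backbone atoms are reported as unresolvable rather than "fixed". This is
a geometric cleanup step, not an energy model.

The template for heterodimer building is whatever two-subunit structure
the user supplies — the 2-ligand EGFR crystal dimer directly, or a relaxed
1-ligand template if one is available. Producing a relaxed template by
molecular dynamics is explicitly out of scope; consequently a build
straight from the symmetric crystal template leaves the replaced (bent)
subunit's anchor RMSD at homology-limited levels, which the provenance
records rather than hides.

## SASA and buried interface area

SASA is Shrake–Rupley quadrature: each heavy atom's sphere (van der Waals
radius + 1.4 Å probe) is sampled with a deterministic Fibonacci point set
(default 960 points; quadrature error on an isolated sphere is well below
1%, and doubling the point count moves cluster totals by <0.5%), and a
point is accessible when outside every neighbour's expanded sphere. Radii
are the Bondi element values shipped as JSON, overridable per atom; an
atom whose element is unknown and whose radius is unset is an error, not a
silent default. The implementation is cross-checked in the tests against
analytic one- and two-sphere closed forms and against biotite's
independent implementation.

Buried interface area is total ΔSASA — SASA(A alone) + SASA(B alone) −
SASA(A∪B) — with the per-atom burial summed only over atoms of ectodomain
domains I–III of either subunit (half-burial-per-subunit conventions
differ by bookkeeping, not substance; the ±15% acceptance band on crystal
areas absorbs convention and radius-set sensitivity). Ligands are excluded
by default: the metric tracks the receptor–receptor interface, so grafting
or removing a ligand leaves it unchanged unless `include_ligands` is set.

Trajectory series evaluate a metric per frame and smooth with a centered
boxcar mean whose window (default 200 ns) truncates at the edges — edge
handling is a package choice, as is the window's position convention.
Dimerization-arm drift superposes each frame on the reference frame over
the *partner* subunit's domain II and then reports the unfitted Cα RMSD of
the arm, so it measures motion of the arm within the partner's binding
pocket, not global tumbling. Contact criteria are conventional heavy-atom
defaults, config-overridable: hydrogen bond = minimum N/O–N/O distance ≤
3.5 Å; salt bridge = minimum charged-group N/O distance ≤ 4.0 Å; cation–π
= cation nitrogen to aromatic ring centroid ≤ 6.0 Å.

## Synthetic study conditions

The generators produce the geometry the analysis assumes, at desk scale:

- **Toy arm** — a Cα polyline (3.8 Å spacing) bent at its central hinge to
  a requested angle; the three bend anchors (first, hinge, last residue)
  realize the requested angle *exactly* at zero noise. A small alternating
  z offset (±0.25 Å, zero at the anchors) keeps every sub-segment
  non-collinear so segment-wise superposition is well-posed. Residues are
  alanine-like: a Cα plus, on the interface-forming N-terminal half, one
  pseudo side-chain sphere (radius 1.9 Å) giving SASA and clash machinery
  volume to act on. Non-physical by design.
- **Toy dimer** — two facing arms 7 Å apart (sphere columns 4 Å apart:
  buried but clash-free when closed). The gap parameter shears the
  N-terminal half of one subunit away from the interface, linearly from
  the hinge to the tip, producing the V-shaped opening; buried area is
  strictly decreasing in the gap and reaches zero by ~50 Å. Bend and gap
  are geometrically coupled (as in the real system): the requested bends
  are recovered exactly at zero gap, while a nonzero gap perturbs the
  sheared subunit's apparent bend.
- **Pseudo-trajectory** — linear coordinate interpolation between two
  dimer states plus i.i.d. Gaussian noise, seeded and bitwise
  reproducible; default spacing 20 ns so ten frames span one 200-ns
  window. Defaults emulate a closed (bend 170°, gap 0) → open (bend 150°,
  gap 10 Å) transition.

What passing on these fixtures shows — and does not. The toys validate the
*metrics and machinery*: closure (requested bend and gap are recovered by
the measurement layer), invariances, and the qualitative signature that
opening the interface gap collapses the windowed buried-area series. They
do not emulate protein energetics, realistic interface areas (tens of Å²
rather than thousands), solvent, or genuine dynamics; microsecond-scale
observations (spontaneous gap opening, θ drift of ligand-free subunits,
~2600 vs ~3500 Å² simulation areas) require long-timescale molecular
dynamics and are outside what this package computes. Crystal-structure
measurements (Her2 θ ≈ 156°, dEGFR areas ≈ 3400/2300 Å², the 4.0 Å
1IVO/1MOX RMSD, the 40/41/50/46% identities) are desk-scale and are
reproduced by the analysis drivers once the public entries are fetched;
they are exercised by `tests/test_acceptance.py`, which names any missing
input explicitly.

## Problem sizes and determinism

Synthetic conditions are 30 residues per subunit, 21-frame trajectories,
960 quadrature points (240 in the quickest checks) — sizes chosen so the
full suite and the acceptance script complete in seconds while still
exercising every code path, including the 200-ns windowing at its intended
frames-per-window ratio. All randomness flows through explicit
`numpy.random.default_rng` seeds; the pipeline's JSON summary is
byte-identical across runs with the same config and seed.

## Known limitations

- No energetics anywhere: no force field, minimization, solvation or
  affinity estimation; clash resolution is combinatorial, not physical.
- Junction regularization is a linear blend, which can leave locally
  non-ideal backbone geometry at segment borders (reported, not repaired).
- Domain maps for Her2/Her3/dEGFR are offset estimates until regenerated
  from alignments; crystal-area figures inherit radius-set and
  domain-boundary sensitivity within the stated ±15%.
- The alignment protocol behind the published identity figures is not
  uniquely determined; values are method-sensitive at the ±2–3 point
  level.
- Loop building is limited to copying resolved residues from sister
  entries; no ab initio modelling (Her2 domain IV beyond residue 608 can
  only be copied from a template or omitted).
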