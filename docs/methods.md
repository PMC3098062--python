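# Methods notes

This note records the model assumptions, the numerical choices, and the
places where the design was genuinely open, so a maintainer can tell which
behavior is principled and which is convention.

## Model and assumptions

The central assumption is a **fixed backbone**: conformational variability
of the binding site is modelled purely as side-chain rotamer exchange.
Structures whose Cα rmsd to the template after superposition exceeds a
threshold (default 1.0 Å, `superpose_rmsd_max`) are dropped as backbone
outliers rather than force-fitted, because every downstream stage assumes
all side chains are rebuilt on the template backbone. Superposition
matches residues by (chain, residue number) identity — the tool targets
multiple crystal forms of the *same* protein; no sequence alignment is
attempted.

The second assumption is that **pocket shape is a sufficient statistic**
for clustering conformers: two conformers whose side chains differ but
whose lattice contact patterns agree are treated as identical. The lattice
spacing (1.0 Å) and the contact padding CPD (0.5 Å) jointly set this
resolution; coarsening either merges more conformers.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `spacing` | 1.0 Å | lattice granularity; bit count scales ∝ spacing⁻³ |
| `flr_cutoff` | 5.0 Å | first layer: distance from the ligand ensemble |
| `slr_cutoff` | 3.0 Å | second layer: distance from FLR-contact points |
| `trim_cutoff` | 6.0 Å | lattice trimmed beyond this from site/ligand atoms |
| `ctd` | 1.0 Å | clash tolerance: clash iff d < r₁ + r₂ − CTD |
| `cpd` | 0.5 Å | contact padding: contact iff d < r_vdw + CPD |
| `merge_threshold` | 5 bits | strict Hamming threshold for string merging |
| `cluster_k` | "auto" | PAM k, silhouette-selected over 2..15 |
| `psp_min_directions` | 4 of 7 | buriedness: blocked scan directions required |
| `psp_range` | 8.0 Å | buriedness: maximum ray length |

Both distance tests are **strict** inequalities, so a point exactly on a
padded sphere is *not* in contact and atoms exactly at the softened vdW
sum do *not* clash. The merge threshold is likewise strict (< 5 bits).
vdW radii are a Bondi-style element table shipped as
`data/vdw_radii.tsv` and overridable per run.

## Numerical and algorithmic choices

**Cavity test.** Classic grid-scan pocket detectors differ in internals;
here a candidate point is "buried" when, along at least
`psp_min_directions` of the 7 lattice scan directions (3 axes, 4 body
diagonals), a protein atom is hit within `psp_range` in *both* senses
(a protein–solvent–protein event). This gives one interpretable knob for
buriedness. Ray sampling steps at the lattice spacing and tests the 12
nearest atoms per sample (several atoms of different radii can overlap a
sample; checking only the nearest under-detects hits).

**Trim reference set.** "Binding-site residues" for the 6 Å trim means
the FLR set, and distances are measured to atom centers; both choices are
config-visible (the alternative — all residues, or vdW surfaces — mostly
changes the pocket rim).

**Bit order.** Lattice points are identified by integer triples ordered
lexicographically; the conditional subset inherits that order. Any fixed
order works — this one is reproducible across runs and platforms.

**Side-chain construction.** Side chains are rebuilt beyond Cβ by
sequential internal-coordinate (NeRF) placement from an ideal-geometry
table (Engh/Huber-style bond lengths/angles, ideal ±120°/180° branch
offsets); the Cβ of the template is kept when present and rebuilt at
ideal tetrahedral geometry when absent. Measured chi dihedrals of a
placement reproduce the inputs to numerical precision. Aromatic rings are
built around the tree and closed implicitly; ring-closure bonds are not
re-idealized. Intra-residue atom pairs within three bonds are exempt from
the clash test (1-2/1-3/1-4 exclusions) — without this every rotamer
would clash with its own backbone. Own-backbone bumping is checked at the
pre-filter stage only; the pairwise stage checks side-chain/side-chain
contacts between different residues.

**Enumeration.** The interaction graph stores a boolean compatibility
matrix per residue pair that clashes for at least one rotamer pair.
Enumeration decomposes into connected components, solves each by
backtracking with forward checking (pruning rotamers left with no
compatible partner), and takes the Cartesian product across components.
Because there is no energy term, pruning is purely logical and the output
is provably the exact set of clash-free assignments — the brute-force
equivalence is asserted on random instances in the test suite. Ordering
(residues by key, rotamers by library index, components by smallest
member) makes conformer ids stable across runs.

**Merging.** The published rule — merge strings differing by fewer than
5 bits — does not determine an algorithm (no ordering, representative, or
transitivity rule). The default is a greedy single pass in a canonical
order (descending conformer count, ties by bit pattern): each string
joins the first group whose *founding* string is within the threshold,
else founds a group. This is deterministic and order-canonical; a
single-linkage (transitive-closure) variant is available behind
`transitive=True`. The two can differ — greedy keeps groups no wider than
twice the threshold, single linkage can chain.

**Clustering.** The reference procedure picked cluster counts by visual
inspection of an interactive MDS plot; a headless artifact needs a
deterministic replacement. `assign_clusters` is a hand-written PAM
(scikit-learn ships no k-medoids): greedy BUILD seeding, best-improvement
SWAP, nearest-medoid assignment with medoids pinned to their own clusters
and ties broken toward lower indices. `"auto"` maximizes the mean
silhouette over a configured range. Classical MDS fixes each axis's sign
so the largest-magnitude loading is positive. Degenerate inputs (all
strings identical) collapse to a zero embedding with a warning.

**Key-residue attribution.** The reference identifies influential
residues by coloring MDS plots by rotamer state and inspecting them. The
programmatic equivalent reports, per residue, η² (the between-rotamer-
group variance fraction) of each principal coordinate and the normalized
mutual information between rotamer state and cluster label, ranking by
the maximum. A residue observed in one state scores zero. A string's
state is taken from its representative conformer (lowest id) — states
can differ within a merged group; the representative convention keeps the
report deterministic.

**Ligand scoring.** Ligand volumes use the identical lattice and contact
rule as pocket encoding (the alternative — bare vdW radii without CPD —
is a config change, not a code change). Ligand points on always-contact
lattice positions count as incompatible in every conformer, which follows
from the partition semantics. The score is a point count; multiply by
`spacing³` for Å³.

## The synthetic system

`fixtures.make_toy_system` builds a spherical-shell cup (radius
`pocket_depth`, default 7 Å, opening half-angle 40°) of rigid Gly
pseudo-residue blobs, seats `n_flexible_residues` Leu residues on the rim
with Cβ directed into the cavity, and places small all-carbon ligands
near the cavity axis, azimuthally distributed so every flexible residue
has a ligand atom within the first-layer cutoff. All flexible positions
share one construction rotated about z, so the mini library's chi values
behave identically at every position; the default library holds rotamers
verified clash-free in this geometry with ≥ 0.25 Å margin. The seeded RNG
only jitters wall atoms (±0.05 Å) and ligand azimuths (±0.15 rad), so
every stage count is stable across seeds and the whole construction is
byte-reproducible from (spec, seed).

What the toy system does *not* emulate: real packing density (walls are
idealized blobs), chemical diversity (one flexible residue type, carbon
ligands), backbone strain, or crystallographic noise. Passing tests
demonstrate algorithmic correctness — exact enumeration, conservation of
the conformer↔string mapping, metric behavior of the dissimilarity,
cluster recovery under planted structure — not predictive accuracy on
real proteins, which additionally depends on the rotamer library used.

At the default sizes (4 residues × 3 rotamers, ~430 lattice points) the
full pipeline runs in ~2 s; the planted-cluster benchmark in the
acceptance script uses 200 strings × 120 bits, sized so the whole script
completes in seconds while still stressing BUILD/SWAP and the silhouette
path.

## Apo-template mode

With no holo structure the ligand ensemble is empty and first-layer
selection has no reference; the user supplies the residue list instead,
and the pocket is not maximally expanded (no Ala substitution of a layer
that was never selected). Second-layer selection then proceeds
identically. The pipeline driver requires at least one holo input; apo
mode is available through the library API.

## Known limitations

- Rotamer probabilities are parsed but unused (no energy model by
  design); enumeration order is library order, not likelihood.
- Proline is Ala-substitutable but has no build topology (ring), so it
  cannot be a flexible residue.
- The greedy merge is order-canonical but not symmetric under threshold
  composition: merging at 3 then 5 bits is not the same as merging at 5.
- PAM is O(k·n²) per sweep; beyond ~10⁴ strings merge first or subsample.
- NMR multi-model files contribute model 1 only; altlocs collapse to the
  highest-occupancy copy.
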