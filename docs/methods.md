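# Methods

`ddgboost` predicts the change in folding or binding free energy (ΔΔG,
kcal/mol; positive = destabilizing) caused by a single amino-acid
substitution, from descriptors computed on a wild-type and a mutant
structure, using stochastic gradient boosting of regression trees.  This
note documents the models, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Structure model and mutant construction

Structures are flat ordered atom lists (author residue numbering, PDB
fixed-column I/O, altlocs resolved to highest occupancy with first-wins
ties, first NMR model only).  For self-contained testing, toy folds are
ideal α-helices built from internal coordinates (φ = −57°, ψ = −47°,
ω = 180°, Engh–Huber-like bond geometry) in which each side chain is a
single pseudo-atom ("SC") placed along the Cβ direction at a
residue-specific distance (1.5 Å for Ala up to 4.1 Å for Arg) with a
residue-specific effective radius and an element carrying the side chain's
dominant chemistry (Lys/Arg → N and positively charged, Asp/Glu → O and
negatively charged, Ser/Thr/Asn/Gln → O, Cys/Met → S, hydrophobics → C).
A 0.02 Å seeded coordinate jitter breaks helical symmetry so per-residue
descriptors vary.

The mutant builder swaps the side-chain representation rigidly: backbone
atoms are untouched, the pseudo-atom is rebuilt for the new residue type
from the local backbone frame.  No relaxation of the environment is
attempted; real mutant structures produced by a modelling tool can be
supplied through the PDB reader instead.  A consequence worth knowing: a
large residue introduced into a packed site produces steric clashes that a
physics-based builder would relieve, so clash-derived descriptors are more
variable here than they would be on relaxed structures.

## Descriptors

*Contacts.*  Atom pairs are classified with precedence electrostatic >
hydrophilic > hydrophobic: opposite formal charges within 4 Å; hydrogen-bond
donor (N, S) to acceptor (O, S) within 4 Å; carbon–carbon within 5 Å.
Counts are taken between the mutated residue and everything outside it
(sequence neighbours included), split into same-chain and opposite-chain
partners, for wild type and mutant, plus differences.

*SASA.*  Shrake–Rupley with a probe of 1.4 Å, a deterministic golden-spiral
point set (default 960 points per atom) and van der Waals radii C 1.70,
N 1.55, O 1.52, S 1.80, H 1.20 Å; pseudo-atoms use their residue-specific
radii.  Points whose distance to the nearest occluder surface falls within
one lattice-cell width are re-estimated on a deterministic 13-point tangent
sub-grid; this boundary refinement brings the worst-case error on small
atom clusters from ~0.6 % to ~0.14 % relative to a 10,000-point reference
at unchanged point count.  Results are memoized on a digest of coordinates
and radii.

*Context.*  A residue is core when its side-chain SASA is strictly below
10 Å² (glycine uses its Cα SASA as proxy, because an empty side chain would
otherwise always read as buried); it is interface when any of its atoms is
within 5 Å of the partner chain.  Interface takes precedence over core.
Interface burial is SASA(A) + SASA(B) − SASA(AB), split into hydrophobic
(carbon) and hydrophilic (N/O/S) parts.

*Sequence.*  Domain length; BLOSUM80 substitution score (the 1/3-bit-unit
matrix shipped with Biopython); and a conservation score in [0, 1]: the
pseudo-count-smoothed frequency of the mutant residue in the alignment
column, normalized by the column's most frequent residue (gaps excluded,
pseudo-count α = 1).

*Energy.*  A pluggable backend over a fixed 17-term vocabulary (torsional,
disulfide, electrostatics, ionization, main-/side-chain entropy, helix
dipole, covalent, salt bridge, hydrogen bond, cysteine bond, water bridge,
van der Waals, clashes, apolar/polar solvation, total).  Externally
computed term tables are ingested from TSV.  The built-in simplified
potential fills the terms it can derive from geometry:

| term | formula | weight |
|------|---------|--------|
| vdW | −w · hydrophobic contact count | 0.10 |
| hb | −w · donor–acceptor pairs ≤ 4 Å | 0.60 |
| E | −w·(opposite-charge pairs) + w′·(like-charge pairs) ≤ 4 Å | 1.00 / 0.50 |
| clashes | +w · non-bonded heavy pairs < 0.6·(r₁+r₂) | 4.00 |
| solv_ap | −w · buried apolar area (Å²) | 0.025 |
| solv_po | +w · buried polar area (Å²) | 0.010 |

Buried area is measured against the fully solvated atom (Σ 4π(r+probe)²
minus actual SASA), so that a packed monomer has nonzero solvation terms
and the binding decomposition terms(AB) − terms(A) − terms(B) isolates the
interface burial.  Weights are fixed constants chosen to give kcal/mol-scale
outputs; they carry no claim of physical accuracy.  Terms with no geometric
stand-in stay 0.  Remaining terms are deterministic and rigid-motion
invariant (solvation to SASA-lattice resolution).  "Bonded" for the clash
term means same residue or backbone atoms of residues adjacent in author
numbering.

Interface-only descriptors are masked for core/surface mutations: stored as
0 with a companion `is_interface` indicator, written as `NA` in TSV tables,
applied identically at train and predict time.  The ΔΔG-energy feature
appears once (`ddg_energy`); per-term differences exclude the total to keep
the registry free of exact duplicates.

## Regressor

Least-squares stochastic gradient boosting.  F₀ is the training-target
mean; iteration m draws ⌈f·n⌉ rows without replacement from an RNG seeded
`seed + m`, fits a CART tree (exhaustive scan over midpoints of consecutive
sorted unique values; leaves predict means; ties resolved to the lowest
feature index, then the lowest threshold, with near-ties within 1e−9
relative treated as ties so float noise cannot flip a deterministic choice)
to the current residuals, and updates F ← F + ν·tree.  Defaults: 300 trees,
ν = 0.1, subsample 0.8, depth 3, min leaf 1.  Feature importance is the sum
over splits of SSE reduction, rescaled so the top feature reads 100.  Grid
search evaluates a Cartesian grid by mean cross-validated Pearson r with
ties to fewer trees then shallower depth.  Models serialize to JSON.

## Curation and validation

Redundancy reduction is greedy identity clustering in the CD-HIT style:
items sorted by total length descending (lexicographic on ties), each
joining the first representative at ≥ 90 % identity — identity from a
global alignment (match +1, mismatch 0, gap −10/−0.5, free end gaps)
normalized by the shorter sequence, averaged over both chains for
complexes.  One representative per cluster is kept: the member with the
most mutations, ties lexicographic.  Cross-validation: repeated k-fold
(default 20 × 50, σ reported as the standard deviation of repetition-level
mean r) or leave-one-family-out (σ across folds), the latter for
homology-model inputs where family-level redundancy would otherwise leak.
Homology-model quality gating keeps records with wild-type model energy
≤ 30 kcal/mol and normalized DOPE ≤ 1; boundary values are kept and every
rejection is logged with the rule that fired.

## Synthetic benchmark: what it shows

The generator emits families of toy proteins (alternating monomers and
antiparallel two-helix dimers; by default 5 families × 4 proteins ×
100 mutations = 2000 rows, half the proteins within a family ≥ 90 %
identical to a family mate), runs the real feature/energy modules, and
labels each mutation with

ΔΔG = 1.5·z(ΔΔG_energy) + 0.8·z(Δ hydrophobic contacts) − 0.6·z(conservation)
      + 0.5·z(ΔΔG_energy)·1[core] + N(0, σ),  σ = 0.5 kcal/mol,

with z the within-dataset standardization.  Dimer mutations are drawn from
interface residues; monomer mutations from all residues, because the
loosely packed toy helices contain no residues below the strict 10 Å²
side-chain burial threshold — core contexts are therefore rare-to-absent
and the interaction term is mostly inactive.  The benchmark demonstrates
end-to-end signal recovery, determinism, and redundancy handling; it does
not emulate real thermodynamics, experimental error structure, or packed
protein cores.

Two emergent properties of this harness matter when reading results.
First, the two structural signal features are strongly anticorrelated
(ρ ≈ −0.8: a mutation that loses contacts also loses buried apolar area,
and both feed ΔΔG_energy), which cancels part of the intended signal — the
correlation ceiling at σ = 0.5 is ≈ 0.91, and the default model reaches
≈ 0.91 held-out; at σ = 0 it reaches ≈ 0.998.  Second, importance spreads
onto features that are components of ΔΔG_energy: the mutant clash count in
particular carries genuine shared signal (clashes enter the total at
4 kcal/mol each on rigid mutants) and can outrank the weakest designated
informative feature in the relative-importance ranking.

Problem sizes used by the test suite and the acceptance script (n = 2000
benchmark, 144-point SASA inside the generator, 240-point default in
feature assembly, 960-point for classification-grade SASA) were chosen as
the smallest sizes at which the statistical properties above are stable.

## Known limitations

Single-model PDB parsing only; no mmCIF.  The simplified potential is a
stand-in with documented arbitrary weights, not a force field.  The coarse
mutant builder does not relax the environment.  Conservation is a
column-frequency score, not a phylogeny-aware estimate.  Toy folds cannot
produce sub-10 Å² buried side chains, so the core branch is exercised via
constructed occlusion fixtures rather than the generator.
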