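# Methods

## The analysis in brief

Ensemble docking evaluates a candidate binding site by the *distribution* of
docking scores obtained when a ligand library is docked against many receptor
conformations, rather than by any single pose. For each (site, system) pair —
here five candidate corrector sites on wild-type (WT) and F508del-mutant (MT)
CFTR — every (ligand, snapshot) run contributes its top-pose Vina affinity
ΔG_bind (kcal/mol) to one pooled distribution. The summary statistics are:

- **mode** — centre of the maximum-probability histogram bin;
- **p(mode)** — that bin's probability mass;
- **best** — the minimum pooled score;
- **fraction negative** — share of runs with ΔG_bind < 0.

A site is *viable* iff its mode is strictly negative: a favourable best score
observed once in 22,000 runs is treated as statistically insignificant,
whereas a negative mode means most of the library binds favourably. The
fraction of negative scores is reported as secondary evidence ("predominantly
favorable" at ≥ 0.5) and, pooled across sites, ranks ligand series.

## Numerical choices

**Histogramming.** Bins are aligned to integer multiples of the bin width
(default 0.2 kcal/mol, configurable); a score on an edge belongs to the bin
on its right; mode ties break toward the lower (more favourable) score. The
0.2 kcal/mol default matches the 0.1 kcal/mol precision at which modes are
conventionally reported; published curves are typically smoothed, so
mode agreement should be judged to within one bin width.

**Top-pose policy.** A run's score is the minimum affinity over its parsed
poses (Vina rank 1). Positive affinities are kept verbatim — pooled ensemble
distributions legitimately extend far above zero when a pocket cannot
accommodate a ligand — so no sanity clamp is applied anywhere.

**Superposition.** Kabsch via SVD with a determinant correction, so the
rotation is always proper. Point sets with fewer than 3 points or rank < 2
(collinear) are rejected because the optimal rotation is underdetermined.

**B-factors.** Frames are superposed onto the first frame's selection
(backbone by default), MSF is taken per atom about its ensemble-mean
position, and B = (8π²/3) × mean MSF over the residue's selected atoms.
Backbone-only is the default because sidechain inclusion is a convention
choice, not a requirement; the selection is a parameter everywhere.

**Pairwise RMSF.** The second structure is superposed on the first over the
*whole* subset, then each residue's value is the RMS of its atoms'
displacements — localized differences are measured in a common frame.

**Junction regularization.** Deleting residue *i* leaves C(i−1)⋯N(i+1)
separated by a distorted gap. The regularizer runs fixed-step steepest
descent (numerical central-difference gradient, step halving on any energy
increase, so the accepted-energy trace is non-increasing by construction) on
a local harmonic energy: a C–N bond term toward 1.33 Å (ideal trans peptide
bond) plus CA–C–N and C–N–CA angle terms toward the Engh–Huber sp2 ideals
(116.2°, 121.7°). Only atoms of the two junction residues move. This is a
deliberate desk-scale substitute for a full force-field minimization: the
target is the ideal bond length, not any particular minimization outcome,
and a relaxed bond anywhere in [1.2, 1.5] Å is considered chemically
plausible. Non-convergence is reported (`converged=False`), never raised;
atoms closer than 0.1 Å abort.

**Grid boxes.** "10 Å" grid boxes are cubes of edge 10 Å centred on the
unweighted heavy-atom centroid of the site's residue list (hydrogens and
mass weighting excluded as convention choices). Centres can be recomputed
per snapshot so the box tracks pocket drift; site residue lists are user
input — no pocket detection is attempted.

**Interaction profiling.** Hydrogen bonds use a hydrogen-free, element-typed
criterion: protein N/O/S vs ligand N/O/F with donor–acceptor distance in
(1.90, 3.35] Å. Fluorine is admitted as a weak acceptor because fluorinated
corrector ends demonstrably hydrogen-bond in these pockets. Contacts are
residue-level heavy-atom approaches in (1.90, 3.90] Å excluding pairs already
reported as hydrogen bonds; pairs at ≤ 1.90 Å are clash artifacts (the
spurious "covalent bonds" interaction diagrams draw for jammed poses). The
three classes are disjoint at the atom-pair level. A residue *bridges* when
it forms ≥ 2 hydrogen bonds to ligand atoms ≥ 8 Å apart (the
backbone-plus-sidechain lysine motif). All four cutoffs are conventional
LIGPLOT-style stand-ins, exposed in `InteractionParams`.

## The synthetic generators

The generators produce inputs with exactly the structure the analysis
assumes, at the study's nominal dimensions, and nothing more:

- `synth_chain` / `synth_ensemble` — backbone-only chains with idealized
  geometry and isotropic per-residue Gaussian jitter (frame 0 is the base
  structure; default frame spacing 10 ns, the snapshot interval of a 1 μs
  trajectory sampled 100 times). They emulate fluctuation *magnitudes* only:
  no correlated motions, no secondary-structure physics, no solvent.
- `synth_scores` — per-(site, system) Gaussian mixtures over the default
  220 ligands × 100 snapshots. The default spec has five sites × two systems
  with the study's qualitative shapes: a narrow negative mode at MSD1 (≈ 80 %
  negative scores in WT, broader and weaker in MT), a sharp negative mode at
  NBD1_alt in the mutant only, and wide, predominantly positive
  distributions elsewhere. Ligand series offsets (−1.5, −0.5, +0.5, +1.5
  kcal/mol for the VX-809, ABBV-2222, thiazole and ARN classes) plant the
  series ranking. Signs and orderings are the emulated content; the synthetic
  numbers are never presented as real docking data.
- `synth_docked_pose` — planted interactions placed strictly inside their
  detection windows, 30 Å apart so nothing else registers.
- `synth_junction` — two flanking residues with an exact requested C⋯N gap
  and deliberately strained angles.

Because the score generator draws i.i.d. from mixtures, passing tests show
that the *statistics and bookkeeping* are correct — they say nothing about
Vina's scoring function, receptor preparation, or pose quality on real data.

## Problem sizes

Tests and the acceptance script run at the study's nominal statistical sizes
where those are cheap (22,000 scores per site/system; 220,000 records for
the full synthetic table; 500-frame ensembles for B-factor recovery) and at
small structural sizes (10–50 residue backbone chains), which the estimators
are insensitive to. The full synthetic pipeline completes in seconds.

## Known limitations

- The junction regularizer is local and harmonic; it will not resolve
  sidechain clashes or propagate strain beyond the two junction residues.
- PDB support only (no mmCIF, no binary trajectories); multi-frame input is
  a multi-model PDB or a per-frame directory with a manifest.
- Hydrogen-bond detection is distance-only (no angles, no π-stacking or
  halogen typology); cutoffs are convention, not fitted values.
- Snapshot stripping beyond HETATM/water exclusion is left to the caller.
- Completeness of a docking batch is reported, never imputed: missing runs
  stay missing.
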