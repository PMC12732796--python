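# Methods

This document describes the algorithms, parameter defaults, and numerical
choices in `gik`, and what the synthetic generators do and do not emulate.

## Generic numbering

Receptor residues use Ballesteros–Weinstein (BW) labels `T.xx` for
transmembrane helices 1–8 and `34.5x` for ICL2; Gα residues use CGN labels
such as `H5.20` or `S3.01` (an optional `G.` prefix is accepted on input;
the short form is emitted).  `gik.numbering.load_reference` loads packaged
residue-number → label tables; `annotate` maps an arbitrary structure's
numbering onto a reference by global alignment (Biopython
`PairwiseAligner`, BLOSUM62, gap open −10 / extend −0.5) and refuses to
annotate below 90 % sequence identity (`AlignmentError`), since silent
misannotation is worse than failure.

The packaged tables are synthetic scaffolds pinned at published anchor
assignments (CB1: 218→3.54, 214→3.50, 222→34.51, 341→6.33; Gαs:
H5.x = 368+x, so 388→H5.20, 393→H5.25; Gαi1: H5.x = 328+x).  Only the
anchors and segment boundaries carry meaning; inter-anchor sequence is
generated.

## Contact criteria

All cutoffs are inclusive and operate on coordinates in Å:

| Criterion | Default | Rationale |
| --- | --- | --- |
| heavy-atom contact | min inter-residue heavy-atom distance ≤ 4.5 | standard interface-contact cutoff |
| polar contact | side-chain N/O to side-chain N/O ≤ 4.0 | tighter cutoff appropriate for polar pairs |
| hydrogen bond | donor–acceptor ≤ 3.0 and D–H…A deviation from linear ≤ 20° | geometric H-bond definition; requires explicit hydrogens (`AtomMissingError` otherwise) |

Pair search uses a `scipy.spatial.cKDTree` over one group queried by the
other; tests verify it against a brute-force double loop.

`occupancy_map` reports, per residue pair, the exact fraction of analysed
frames in which the criterion holds.  By default the first
`discard_fraction = 0.5` of each replicate is discarded (equilibration) and
pairs below `min_occupancy = 0.05` are suppressed; both are per-call
parameters.  For speed, the per-frame evaluation precomputes per-residue
centroid trajectories and radii and evaluates exact atom–atom distances
only on frames where centroid distance ≤ cutoff + radii; this prefilter is
exact (triangle inequality), not approximate.

## Restraint-selection funnel

`conservation.select_restraints` implements the three-stage funnel:

1. **Conserved H5 positions** — columns of the Gα H5 alignment with a
   single residue type across all families (the packaged alignment yields
   H5.01, H5.03, H5.07, H5.08, H5.13, H5.20, H5.25).
2. **Shared interface positions** — positions in receptor contact
   (heavy-atom, `contact_cutoff = 4.5` Å) in at least
   `conservation_min = 0.77` of complexes, in *both* the Gi-coupled and
   Gs-coupled sets.
3. **TM-partner filter** — positions whose modal receptor partner is a
   transmembrane BW position (loop labels like 34.5x are excluded); ties in
   the modal partner are broken lexicographically and reported.

Each surviving position becomes a distance restraint to its modal partner
with `max_distance = 5.0` Å, exported as TSV and as a ClusPro-style JSON
attraction group.  The docking score helper uses the published ClusPro
balanced weights `E = 0.40·E_rep − 0.40·E_att + 600·E_elect + 1.00·E_dars`.

`check_model_contacts` partitions a reference pair list into
preserved / missing / unmappable against a model — never silently dropping
pairs whose labels cannot be mapped.

## Helix geometry

Helix axes are the dominant right-singular vector of centred Cα
coordinates (sign-fixed along the N→C direction); this is equivariant
under rigid motion to numerical precision and needs ≥ 4 points.
`tm_distance` measures Cα–Cα distances between generic labels and is
rigid-motion invariant.  `orientation_compare` and `nearest_family` reason
about H5 axis orientation relative to reference cones.

## Ensemble statistics

**RMSD** — superposed RMSD delegates to `MDAnalysis.analysis.rms.rmsd`;
positional (no-fit) RMSD is computed directly.

**GROMOS clustering** — iteratively pick the frame with the most
neighbours within `cutoff = 1.5` Å RMSD, remove it and its neighbours as a
cluster, repeat.  Ties are broken toward the lowest frame index, making
results deterministic; a brute-force reimplementation serves as the test
oracle.  The full pairwise positional-RMSD matrix is computed in float32
via the Gram trick (‖a−b‖² = ‖a‖² + ‖b‖² − 2a·b), which keeps 3750×3750
matrices fast and small.

A deliberate design point: the workflow clusters the *position* of the H5
helix in the receptor frame.  Frames are first superposed on a separate
fit selection (receptor Cα, `fit_idx`), then clustered on positional RMSD
of the analysis selection (H5 Cα) **without** per-pair superposition —
superposing on the helix itself would cancel exactly the rigid-body motion
being clustered.  A `superpose=True` path exists for shape clustering.

**Block averaging** — each replicate's series is cut into blocks of
`block_size = 50` frames (partial trailing blocks dropped), block means
give a per-replicate mean and SEM, and the across-replicate estimate is
mean ± SD(replicate means, ddof = 1)/√R.  Applied to the 12 published
replicate means this yields 2.28 ± 0.07 Å.

**Population arithmetic** — `population_percentages` infers the total
frame count from one (count, percent) anchor and reports all clusters as
percentages; with counts 3525/1162/1117 and anchor 1162 = 15.5 % it gives
a 7497-frame total and 47.0 / 15.5 / 14.9 %.

## Synthetic planted-truth data

`gik.synthetic_data` builds a toy complex: seven straight-Cα TM helices on
a 13 Å circle plus ICL2 and H8 for the receptor (chain R), and a 26-residue
ideal H5 helix entering the bundle from below for the Gα (chain G).
Residue names default to the packaged reference tables so
alignment-based annotation works on synthetic structures.  It emulates the
*topology and bookkeeping* of a GPCR–Gα complex — residue numbering,
labels, interface geometry — not molecular energetics: helices are ideal,
side chains are single pseudo-atoms (`SC`), and dynamics are rigid-body
basin hopping plus isotropic Gaussian noise, not physics.

**Contact planting** — a planted contact places one extra `SC` pseudo-atom
on each residue along the Cα–Cα segment so their separation equals
`contact_distance` (default 3.0 Å); an OFF contact points the arms away.
Planting fails loudly (`GenerationError` naming the pair) if the Cα–Cα
span would need arms > 10 Å.  `make_complex(verify=True)` re-detects the
contact map and confirms it equals the planted set.

**Ensembles** — frames are assigned to basins by seeded multinomial draw
(defaults: 47 % native, 15.5 % displaced +x/+30°, 14.9 % displaced
−x/−30°, remainder diffuse), the Gα is rigidly transformed per basin,
per-frame Bernoulli draws realise probabilistic contacts, and Gaussian
noise (σ = 0.5 Å) is added to all atoms.  Everything derives from one
`numpy.random.default_rng(seed)` stream; same spec ⇒ bit-identical
ensemble.  Basin displacements were chosen so displaced basins do not
collide with other receptor helices (verified: the recovered occupancy map
contains exactly the planted pairs).

**Recovery tests** — the acceptance tests regenerate full-size ensembles
(12 × 625 frames) over many seeds and check that clustering recovers the
planted basin fractions (MAE < 0.02) and that contact occupancy recovers
the planted Bernoulli probabilities.  Occupancy is tested *pooled* across
seeds against a 3σ binomial bound: per-seed 3σ tests would be intrinsically
flaky (~0.3 % per trial, ~10 % across 40 trials) by construction, whereas
the pooled estimator tests the same property at far higher power.  For
these tests `contact_distance = 2.0` Å, so σ = 0.5 Å coordinate noise
cannot push a planted ON pair past the 4.5 Å cutoff — a correctness
precondition for recoverability (truth must be recoverable in principle),
not a tuning of the analysis.

## Pipelines and reproducibility

`gik run <config.yaml>` drives two workflows.  `restraints` runs the
funnel on the packaged alignment and synthetic complex sets;
`ensemble` generates a seeded synthetic ensemble and writes clustering,
occupancy and block-statistics tables plus `report.json` and `run.log`.
All outputs use sorted JSON keys and fixed float formats with no
timestamps; reruns with the same config are byte-identical (tested).
Seeds must be < 2³¹.

## Limitations

- The packaged numbering tables and H5 alignment are synthetic scaffolds;
  real analyses should substitute database exports (same TSV schema).
- The `ensemble` workflow currently operates on synthetic ensembles only;
  feeding externally produced trajectory files through the pipeline would
  require annotated numbering maps for the topology and is not wired in
  (the underlying library functions accept arbitrary coordinate arrays).
- Checks against deposited experimental structures and public trajectory
  repositories require network access and are out of scope for the test
  suite; the code paths they would use are unit-tested on synthetic data.
- H-bond detection requires explicit hydrogens; no hydrogens are inferred.
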