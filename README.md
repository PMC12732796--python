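# gik — G-protein Interface Kit

Tools for analysing how a G protein's α5 (H5) helix engages a GPCR's
intracellular cavity: generic residue numbering, interface contact maps,
cross-complex conservation, restraint selection for docking, helix geometry,
and ensemble statistics (GROMOS clustering, block averaging, contact
occupancy).  A synthetic-data module generates complexes and trajectory
ensembles with *planted* ground truth so every analysis can be validated
against known answers without downloading anything.

The scientific workflow implemented here is the restraint-selection funnel
used in modelling a cannabinoid-receptor–Gαs complex:

1. Find H5 positions conserved across Gα families in a sequence alignment
   (7 positions: H5.01, H5.03, H5.07, H5.08, H5.13, H5.20, H5.25).
2. Keep those that sit in the receptor interface in ≥ 77 % of both
   Gi-coupled and Gs-coupled experimental complexes (4 positions).
3. Keep those whose receptor partner is a transmembrane (not loop) residue
   with a single modal Ballesteros–Weinstein position (2 restraints:
   H5.20–3.54 and H5.25–6.33; for CB1·Gαs these are I218–L388 and
   L341–L393).

The resulting distance restraints are exported as TSV and as a
ClusPro-style JSON attraction group.  Downstream, ensembles of the docked
complex are clustered on the position of the H5 helix after receptor
superposition, and contact occupancies and block-averaged RMSD statistics
are reported.

## Packaged reference data

`src/gik/data/` ships small reference tables mapping residue numbers to
generic labels (CB1 → Ballesteros–Weinstein, Gαs/Gαi1 → CGN) and a 5-family
H5 alignment.  **These are synthetic stand-ins** (hence the
`*.synthetic.tsv` suffix): the anchor positions that matter for the
workflow (e.g. CB1 I218 = 3.54, L341 = 6.33; Gαs L388 = H5.20,
L393 = H5.25; H5.x = residue 368+x) are real published assignments, but the
connecting sequence is a generated scaffold, not a database snapshot.  For
production use, replace them with exports from GPCRdb/Gproteindb in the
same three-column format (`ref_seq_index`, `ref_aa`, `generic_label`, plus
`segment`).

## Quick start (CLI)

Generate a synthetic receptor–Gα complex with two planted interface
contacts, then analyse it:

```
$ gik synth --seed 3 --out cx.pdb
wrote cx.pdb

$ gik contacts cx.pdb --group-a "chain R" --group-b "chain G"
R:ILE218	G:LEU388	3.00
R:LEU341	G:LEU393	3.00

$ gik tm-dist cx.pdb          # Cα distance between labels 6.33 and 2.39
25.74
```

Run the full restraint-selection workflow from a YAML config:

```
$ cat cfg.yaml
workflow: restraints
seed: 5

$ gik run cfg.yaml --out-dir out
{
  ...
  "stage_counts": [7, 4, 2],
  "partners": {"H5.20": "3.54", "H5.25": "6.33"},
  ...
}

$ cat out/restraints.tsv
# cutoff=4.50 conservation_min=0.77 max_distance=5.00
receptor_label	receptor_residue	galpha_label	galpha_residue	max_distance
3.54	R:ILE218	H5.20	G:LEU388	5.0
6.33	R:LEU341	H5.25	G:LEU393	5.0
```

`workflow: ensemble` instead generates a seeded multi-replicate synthetic
trajectory, discards the first half of each replicate, and writes
`clusters.tsv` (GROMOS clusters of H5 position), `occupancy.tsv` (contact
occupancies), `rmsd_blocks.tsv` (block-averaged statistics) and
`report.json`.  Reruns with the same config are byte-identical.

Other commands: `gik info`, `gik convert` (PDB ↔ mmCIF), `gik annotate`
(assign generic labels to a chain by alignment against a packaged
reference), `gik cluster`, `gik score` (ClusPro weighted sum), `gik synth
--what ensemble`.

## Library overview

| Module | Contents |
| --- | --- |
| `gik.structure_io` | PDB/mmCIF read/write (gemmi), atom/residue records, selection grammar (`chain R and resnum 218 341`, `bw 3.54`, …), trajectory ensembles |
| `gik.numbering` | BW/CGN label parsing, reference tables, alignment-based annotation of arbitrary numbering (Biopython, BLOSUM62) |
| `gik.contacts` | heavy-atom (≤ 4.5 Å), polar (≤ 4.0 Å) and H-bond (≤ 3.0 Å, ≤ 20° off-linear) contact detection; per-frame occupancy maps |
| `gik.conservation` | cross-complex contact conservation tables, the restraint-selection funnel, ClusPro export, model-vs-reference contact checks |
| `gik.helix_geometry` | least-squares helix axes, inter-helix angles, labelled Cα distances, superposition |
| `gik.ensemble_stats` | RMSD, GROMOS neighbour-count clustering, block averaging with across-replicate SEM, cluster population arithmetic |
| `gik.synthetic_data` | planted-truth generators: ideal helices, 7-TM toy bundles, contact planting, multi-basin ensembles, H-bond geometry probes, alignments, funnel fixtures |
| `gik.pipeline` / `gik.cli` | YAML-configured workflows and the `gik` command line |

All public functions raise subclasses of `gik.GikError` with actionable
messages; the CLI converts them to `error: …` on stderr with exit code 1
(exit code 2 for usage errors).

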