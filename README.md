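# dimerpipe

Analysis pipeline for two-chain peptide (dimer) conformational ensembles,
plus a Monte Carlo pulling (MCP) simulator for force-induced dimer
dissociation and the statistics used to compare simulated rupture data with
experimental force-spectroscopy measurements.

## What it does

* **core_io** — shared data model (`StructureFrame`, `Ensemble`,
  `RuptureDataset`), multi-model PDB reading/writing (internally nm) and
  delimited force/position tables.
* **synthetic** — generators with known ground truth: single-chain backbone
  ensembles sampled from per-residue helix/strand/coil propensities
  (backbone rebuilt from dihedrals with ideal geometry), rigid-body docked
  dimers with a requested inter-chain contact architecture, and
  Gaussian-mixture rupture samples.
* **secondary_structure** — dihedral-box assignment on consecutive residue
  pairs (alpha: −80° ≤ φ ≤ −48°, −59° ≤ ψ ≤ −27°; beta: −150° ≤ φ ≤ −90°,
  90° ≤ ψ ≤ 150°; inclusive bounds), windowed secondary-structure fraction
  time series, and a reduced hydrogen-bond (Kabsch–Sander energy) H/E/C
  assignment.
* **ensemble_analysis** — Kabsch superposition, pairwise backbone RMSD
  matrices, greedy neighbour-count (GROMOS-style) clustering,
  Cα contact-probability maps (intra/inter/difference) and shape
  descriptors (mass-weighted Rg, convex-hull volume, Shrake–Rupley SASA).
* **dpca** — PCA on sin/cos-transformed backbone dihedrals, free-energy
  landscapes ΔG = −ln(P/P_max) on the first two components, minima
  detection with representative frames, and pooled (concatenate + refit)
  landscapes.
* **mcp** — Metropolis Monte Carlo pulling on a Gō-type Cα model built from
  a reference dimer conformation (12-10 native-contact wells, harmonic
  pseudo-bonds, excluded volume).  Virtual springs on the two chain
  N-terminal Cα anchors recede along the initial anchor–anchor axis; the
  spring term is (k/2)[L(x) − L0 − v·t]² with t advancing once per sweep.
  Traces record distance, spring tension and inter-chain contact count;
  rupture is the peak smoothed force before sustained contact loss.
* **force_stats** — contour-length normalization of rupture positions,
  Gaussian-mixture peak fitting (EM + BIC), peak-pattern extraction mapped
  to N-terminal/central/C-terminal thirds, two-sample Kolmogorov–Smirnov
  comparisons and a ranked validation report against a reference dataset.

## CLI

All stages are exposed under one entry point:

```bash
# synthetic inputs
dimerpipe synth ensemble --config profile.yaml --frames 50 --seed 1 --out ens.pdb
dimerpipe synth dimer    --config dimer.yaml   --frames 20 --seed 1 --out dimer.pdb
dimerpipe synth ruptures --component 1.0,56.6,20.5,0.5,0.1 --n 500 --seed 1 --out exp.tsv

# analyses
dimerpipe ss assign     --in ens.pdb --out ss.tsv --method dihedral
dimerpipe ss timeseries --in ens.pdb --out ts.tsv --window 1.0
dimerpipe ss perres     --in dimer.pdb --out perres.tsv --method hbond
dimerpipe cluster  --in dimer.pdb --cutoff 0.45 --out clusters.tsv --rep-dir reps/
dimerpipe contacts --in dimer.pdb --chains A,B --cutoff 0.8 --out inter.tsv
dimerpipe shape    --in dimer.pdb --out shape.tsv
dimerpipe dpca     --in run1.pdb --in run2.pdb --bins 64 --out landscape.tsv

# pulling + validation
dimerpipe pull --structure dimer.pdb --k 35 --v 1000 --seeds 20 \
               --epsilon-inter 4 --out sim.tsv
dimerpipe forcestats normalize --in sim.tsv --contour-length 16.4 --out simn.tsv
dimerpipe forcestats report --candidate simn.tsv --reference exp.tsv --alpha 0.05
```

Example YAML configs: `{n_residues: 41, p_alpha: 0.3, p_beta: 0.2}` for a
chain profile; a dimer config adds `chain_a`, `chain_b`, `contacts:
[[i, j], ...]` and `contact_distance`.

## Conventions

Lengths in nm, forces in pN, energies in kT.  Residue indices are 0-based
internally; `core_io.to_peptide_numbering` converts to 1-based peptide
numbering that excludes an N-terminal anchor residue.
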