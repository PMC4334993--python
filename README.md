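# kirdock

Desk-scale toolkit for virtual screening of peptide-toxin block of
inwardly rectifying K+ (Kir) channels:

- **structio** — PDB/FASTA I/O, author-numbering addressing, segment
  extraction, Kabsch superposition.
- **grafting** — "limited" homology chimeras: splice a replacement outer
  vestibule sequence into a template subunit and thread it onto the *fixed*
  template backbone (idealized-rotamer side chains, clash-minimized), plus a
  Ramachandran sanity report.
- **symmetry** — derive C4 operators from a template tetramer and assemble
  homo-/hetero-tetramers.
- **dockengine** — rigid-body docking via FFT grid correlation (surface
  complementarity, core penalty, grid electrostatics) plus a coarse contact
  pair potential; deterministic ranked pose lists.
- **ensembles** — dock every conformer of an NMR-style bundle, ranked
  score-profile curves, top-k means, dominance + Mann-Whitney profile
  comparison.
- **posecluster** — greedy clustering of top poses by ligand CA RMSD.
- **interface** — Shrake-Rupley SASA, four-class residue footprint,
  hydrogen bonds, salt bridges, and contact-ring geometry of a z-aligned
  tetramer.
- **mutagenesis** — in silico site-directed mutagenesis screens: enumerate
  mutation combinations, rebuild, re-dock, rank hotspots.
- **peptools** — per-residue CA mobility across conformer bundles, net
  charge vs pH (Henderson-Hasselbalch), disulfide detection, basic-residue
  counts.
- **fixtures** — deterministic synthetic structures (a C4 toy channel with
  tunable charged rings and a basic-tailed toy peptide) so the whole
  pipeline is testable offline.

## CLI

The console script `kirdock` chains the stages; every command writes a JSON
config snapshot next to its outputs so artifacts are reproducible.

```sh
kirdock fixtures --out work                      # synthetic channel + peptide
kirdock dock --receptor work/channel.pdb --ligand work/peptide.pdb \
    --out work/poses.tsv
kirdock cluster --poses work/poses.tsv --ligand work/peptide.pdb \
    --out work/clusters.tsv
kirdock interface --receptor work/channel.pdb --ligand work/peptide.pdb \
    --poses work/poses.tsv --rings work/rings.json --out-prefix work/iface
kirdock scan --template work/channel.pdb --chain A --start 1 --end 9 \
    --singles D2S,E6K --combine-up-to 2 \
    --ligand work/peptide.pdb --out work/scan.tsv
kirdock peptide --sequence ALCNCNRIIIPHMCWKKCGKK --out work/pep.json
```

Other subcommands: `graft` (chimera threading), `assemble` (tetramer
assembly), `bundle-dock` (per-conformer profiles). Global flags: `--seed`,
`--log-level`, `--config <yaml>`.

## Notes

- Docking scores are dimensionless and only meaningful as within-run,
  relative comparisons; weights and sampling density are configuration.
- The default desk-scale settings (1.2 A grid, 18 deg rotation sampling,
  top-2000 poses, 9 A / top-1000 clustering, top-5 means) complete the
  end-to-end synthetic pipeline in well under a minute on one CPU.
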