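# spsmap

Analysis toolkit for a transporter-like amino-acid sensor complex:
alignment conservation profiling, short-linear-motif scanning with
ortholog-conservation filtering, structure-model contact/interface/mutation
mapping, and an 8-state conformational-equilibrium signaling model — plus a
synthetic-data module so every stage runs without downloads.

## Modules

| module | purpose |
| --- | --- |
| `spsmap.alignments` | read aligned FASTA / Clustal, per-column conservation profiles, strictly-conserved counts, column↔reference mapping, conserved-box detection, pairwise identity/similarity |
| `spsmap.motifscan` | compile degenerate consensus patterns (`(S/T)xx(S/T)`, `[ST]xx[ST]`, `S/T-x-x-S/T`), scan with overlapping hits, classify conservation across ortholog alignments |
| `spsmap.structcontacts` | PDB/mmCIF parsing (heavy atoms, author numbering, pLDDT from B-factors), scoped residue distances, salt-bridge / H-bond / pi-pi detectors, hydrophobic and sulfur clusters, score-track segmentation |
| `spsmap.mutmap` | mutation parsing/validation, packaged mutant catalog, structural neighborhoods of mutated sites, cross-chain interface reports |
| `spsmap.statemodel` | 8-state / 7-reaction equilibrium: state fractions, signaling fraction, dose-response, EC50 (closed form and numeric), perturbation presets |
| `spsmap.synthdata` | seeded synthetic alignments/structures/complexes/tracks with exact planted ground truth |

## CLI

```bash
spsmap conserve --aln orthologs.fasta --ref Ssy1 [--region 283:801] [--boxes] [--pairwise]
spsmap motifs --seq protein.fasta --pattern "(S/T)xx(S/T)" [--region 1:381] \
              [--aln orthologs.fasta --ref Ssy1 --threshold 0.5]
spsmap contacts --model model.pdb --salt-bridges --hbonds --pipi [--clusters sulfur]
spsmap track --track disorder.tsv --threshold 0.5 --direction above
spsmap mutations --model model.pdb --muts mutations.tsv [--radius 5.0]
spsmap interface --model complex.pdb --chains A B [--cutoff 4.5]
spsmap statemodel [--l-out 10] [--dose 0:1000:200] [--preset extracellular-gate]
spsmap synth alignment|structure|complex|track --plan plan.json --seed 1 --out DIR
```

## Conventions

- Residue coordinates are 1-based with inclusive ranges.
- A column is *fully conserved* only with zero gaps and a single residue.
- Column identity fractions use all rows as denominator (gaps are
  mismatches); pairwise identity uses co-aligned columns only.
- Contact detection is distance-only (models carry no hydrogens):
  salt bridges 4.5 Å over charged-group atoms, H-bond proxy 3.6 Å over N/O
  heavy atoms, pi-pi 5.5 Å between ring centroids, sulfur pairs 4.0 Å
  between SG atoms, hydrophobic contacts 4.5 Å over side-chain heavy atoms.
- The state model is equilibrium-only; state weights are path products
  over the spanning tree of reactions (no ligand-bound inward-opening edge).
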