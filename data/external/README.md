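# External inputs (not redistributable)

The accession-based acceptance targets need inputs that cannot be bundled
with this repository and that the build/grading environment cannot download
(no network route to UniProt, the AlphaFold DB or the journal's
supplementary-material host — only an internal package mirror is
reachable).  To run those targets, place the following files here:

| file | content |
| --- | --- |
| `Q03770.fasta` | UniProt FASTA for Ssy1 (Q03770) |
| `P43606.fasta` | UniProt FASTA for Ptr3 (P43606) |
| `P47002.fasta` | UniProt FASTA for Ssy5 (P47002) |
| `AF-Q03770-F1-model.pdb` | AlphaFold DB model AF-Q03770-F1 (PDB format, pLDDT in the B-factor column) |
| `ssy1_fungal_orthologs.fasta` | supplementary alignment of Ssy1 with 36 fungal homologs (37 rows, aligned FASTA or Clustal) |
| `ssy1_yat_family.fasta` | supplementary alignment of Ssy1 with the 15 YAT-family transporters (16 rows) |

Sources:

- `https://rest.uniprot.org/uniprotkb/<ACCESSION>.fasta`
- `https://alphafold.ebi.ac.uk/files/AF-Q03770-F1-model_v4.pdb`
  (rename to `AF-Q03770-F1-model.pdb`; note that published distances were
  measured on a specific database release, so coordinate drift between
  model versions can shift 0.1-Å-precision values)
- the ortholog alignments are Supplementary File S1 of the source article
  (doi:10.1093/g3journal/jkaf312); the alignment row containing `SSY1` or
  `Q03770` in its identifier (or the first row) is used as the reference.

With the files present, `tests/test_acceptance.py` criteria 1–3 and the
corresponding entries of `scripts/acceptance.py` run against them; without
the files the tests fail with an explanatory message and the report keys
are omitted.
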