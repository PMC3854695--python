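# Reference study fixture

A curated matrix of per-sample allele-specific expression calls for the
panel of 18 MEG and 6 PEG candidate genes assessed by RT-PCR and Sanger
sequencing in reciprocal Col-0 × Ler hybrid *Arabidopsis* material.  It is
the package's worked example: running the confirmation pipeline over these
tables reproduces the survey's headline tallies (11 confirmed MEGs — 7
fully and 4 partially confirmed under the 6×-wash control — and 1 confirmed
early PEG).

Files (all TSV):

- `samples.tsv` — sample sheet: 8 wild-type 1×-washed embryo libraries
  (2 cross directions × 2 stages × 2 replicates), 2 stringently (6×) washed
  2–4 cell libraries, 4 mutant-cross embryo libraries (maternal and paternal
  *fie*/*FIE*, paternal *met1-3*/*MET1*), 2 reciprocal F1 seedling
  libraries, and a combined seed-coat/endosperm positive-control sample.
- `candidates.tsv` — the 24 candidate genes with their candidate class.
- `embryo_calls.tsv` — calls in the wild-type 1× embryo libraries.
- `wash_calls.tsv` — calls in the 6×-washed control libraries.
- `mutant_calls.tsv` — calls in the mutant-cross libraries (confirmed genes).
- `seedling_calls.tsv` — calls in the F1 seedling libraries.
- `markers.tsv` — purity RT-PCR panel: embryo quality markers (ACT11, WOX9)
  and seed-coat/endosperm contamination markers (TT10, AT5G42530, FWA,
  AGL46, AGL62) per library.
- `concordance_labels.tsv` — published parent-of-origin categories of the
  12 confirmed genes in two external embryo datasets (early Col-0 × Cvi and
  torpedo-stage Col-0 × Ler), with the verbatim printed label alongside the
  package's category vocabulary ("Ler bias" → `accession_bias`,
  "early PEG" → `paternal`).
- `gamete_presence.tsv` — egg/sperm microarray presence calls for the
  confirmed genes (AT2G47115 is absent: not represented on the arrays).

Synthetic placeholders: the four MEG candidates that never amplified and
the three PEG candidates never detected in embryo libraries have no
published locus identifiers; they appear here under the synthetic IDs
`MEGC13`–`MEGC16` and `PEGC04`–`PEGC06`.
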