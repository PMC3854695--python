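# imprintcall

Detection and confirmation of genomic imprinting in the *Arabidopsis*
embryo from reciprocal-cross allele-specific expression data.

## The problem

Genomic imprinting is parent-of-origin-dependent, monoallelic expression:
the two alleles are genetically identical but epigenetically distinct. In
flowering plants it was long considered a peculiarity of the endosperm;
demonstrating it in the embryo requires separating true imprinting from
three confounders that also produce maternal-looking signals —

1. **maternal transcript deposition**: mRNA stored in the egg cell before
   fertilization decays as zygotic transcription proceeds, giving a
   maternal bias without imprinting;
2. **maternal sporophytic contamination**: seed-coat (and endosperm)
   debris carried along with isolated embryos contributes purely maternal
   reads;
3. **accession effects**: a *cis* difference between accessions biases
   both cross directions toward the same allele, not the same parent.

`imprintcall` implements the computational side of a confirmation workflow
for this problem, aimed at researchers analyzing reciprocal-cross embryo
transcriptomes and targeted allele-specific RT-PCR/Sanger assays.

## The method

For a gene with `m` maternal and `p` paternal allele-assignable reads, the
**maternal index** is `mi = m/(m+p)` and `pi = 1 − mi` (the female parent
is written first in all cross notation, so orientation follows the sample
sheet). The pipeline stages are:

- **candidate calling** (`candidate_caller`): a gene is a MEG candidate
  when `mi > 0.8` in all detected run-1 samples, in the 2–4 cell samples
  only, or in the globular sample only (PEGs mirror with `pi`); candidates
  are kept only if a second replicate sequencing run shows reads from one
  parent only, and dropped when deregulated in a *kyp* mutant library;
  survivors are ranked by expression with egg/sperm presence flags.
- **Sanger quantification** (`sanger_quant`): chromatogram peak heights at
  the assay SNP estimate the allele fraction `h_a/(h_a+h_b)`; heterozygous
  genomic-DNA controls validate amplification neutrality, a genomic-DNA
  dilution series (9:1, 3:1, 1:1, 1:3, 1:9) calibrates the readout, and a
  biased assay (`f′ = f/(f + b(1−f))`) is corrected by the closed-form
  inverse `f = b·f′/(1 − f′ + b·f′)`. Fractions become categorical calls:
  monoallelic, biased, biallelic, or not detected.
- **classification** (`imprint_classifier`): per-gene verdicts from calls
  across reciprocal directions, stages and replicates; a stringent 6×-wash
  control re-grades confirmed MEGs (confirmed / partially confirmed / lost
  in wash / excluded); marker RT-PCR panels (ACT11, WOX9 vs TT10,
  AT5G42530, FWA, AGL46, AGL62) audit sample quality and purity;
  heterozygous *fie* (PRC2) and *met1* crosses are screened for silent-
  allele derepression; F1 seedling calls test imprint erasure.
- **concordance** (`concordance`): external count datasets are categorized
  per gene (maternal / maternal bias / biallelic / accession bias / not
  expressed / no SNP coverage) using an exact two-sided binomial test
  against the dosage-expected maternal fraction (1/2 embryo, 2/3
  endosperm), and category selections are aggregated across datasets.
- **synthetic data** (`synthetic_data`): a generator emulating all of the
  above — truth classes, negative-binomial depth with dropout, binomial
  allele splits, deposition decay, seed-coat contamination, and noisy
  two-peak chromatogram signals — so every stage is testable end to end.

## Worked example

The package bundles a curated reference study: per-sample allele calls for
a panel of 18 MEG and 6 PEG candidates in reciprocal Col-0 × Ler hybrid
embryos, plus wash controls, mutant crosses, seedlings, the purity marker
panel and external-dataset categories (see
`src/imprintcall/data/reference_study/README.md`).

```sh
imprintcall classify --out out/
# confirmed 11 MEGs (7 full + 4 partial) and 1 early PEG(s)
```

`out/summary.tsv` then contains (among others):

```
confirmed_megs_full      7
confirmed_megs_partial   4
confirmed_megs           11
confirmed_early_pegs     1
meg_share_pct            91.67
megs_derepressed         2
megs_unchanged           9
seedling_biallelic_megs  9
```

Reading: 11 MEGs and 1 early PEG survive every confirmation rule; under
the stringent 6×-wash control 7 MEGs are detected monoallelically in both
cross directions and 4 in one direction only; 91.7% of the confirmed
imprinted genes are maternally expressed; a maternal PRC2 (*fie*) mutation
derepresses the silent paternal allele of 2 MEGs while 9 MEGs are
unaffected by any mutant cross; and 9 MEGs are biallelic in F1 seedlings,
i.e. the embryonic imprint is erased or ineffective by the seedling stage.

The other subcommands (`simulate`, `call-candidates`, `quantify-sanger`,
`concordance`, `report`) chain through TSV files; `imprintcall --help`
lists them.

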