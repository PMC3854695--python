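# Methods

## Model and procedure

The pipeline treats imprinting detection as a cascade of categorical
decision rules over allele-resolved measurements, not as a single
statistical model. Two measurement types feed it:

- **allele-specific read counts** per gene and library, already assigned
  to one of two parental accessions via fixed SNPs. Orientation to
  maternal/paternal follows the sample sheet (female parent first); the
  maternal index is the raw ratio `mi = m/(m+p)`, with `pi = 1 − mi`.
  A zero-read gene carries an explicit undefined flag instead of NaN so
  that "not detected" is a first-class state in every downstream rule.
- **Sanger chromatogram peak heights** at the assay SNP. The measured
  fraction `h_a/(h_a+h_b)` is scale-invariant; an assay amplifying the
  counter-allele `b`-fold more efficiently measures
  `f′ = f/(f + b(1−f))`, inverted in closed form by
  `f = b·f′/(1 − f′ + b·f′)`. A straight-line fit of measured on true
  fraction over the five-mix genomic-DNA dilution series summarizes
  linearity (`r²`); bias correction uses the closed-form inverse with `b`
  estimated as the median of per-point estimates
  `b_i = f(1−f′)/(f′(1−f))`, which is exact on noiseless series and
  robust to one noisy mix. Higher-order calibration curves are
  deliberately out of scope: the dilution design has five points and the
  bias model captures the only mechanism (differential amplification
  efficiency) the assay is known for.

### Candidate calling

A gene is a MEG candidate when `mi >` threshold (strict inequality,
default 0.8) in every *detected* run-1 sample, in the 2–4 cell samples
only, or in the globular sample only; PEG candidates mirror with `pi`.
"Detected" means at least `min_informative_reads` (default 1) assignable
reads. Two consistency filters follow:

- **replicate run**: every detected sample of the second sequencing run
  must carry reads from the calling parent only (`index == 1.0`). The
  check spans all detected run-2 samples regardless of stage. A gene with
  no run-2 detection is dropped, except when it was sequenced in run-1
  globular material only (no run-1 2–4 cell detection either) — that
  detection-based acceptance path mirrors how low-coverage
  globular-specific candidates were retained in the source workflow, and
  keeping it detection-based (rather than support-based) makes the whole
  cascade monotone in the index threshold: raising the threshold can
  never add a candidate, which is enforced by property tests.
  A consequence worth knowing: an early-only PEG that is genuinely
  biallelic at the globular stage fails the run-2 check whenever the
  second run contains a detected globular library. The synthetic-study
  recovery targets therefore concern MEGs; PEG recall under this design
  is documented as low by construction.
- **kyp library**: KYP (CHG-context histone methyltransferase) shapes
  parental contributions genome-wide rather than locus-specific
  imprinting, so a candidate whose monoallelic bias collapses in the
  kyp-heterozygous library is suspect. Two interpretations of
  "deregulated" are provided: the default `threshold` mode requires the
  index itself to clear the calling threshold in the kyp library (where
  detected; undetected counts as consistent); a `relative` mode instead
  flags indices falling more than `kyp_margin` (default 0.2) below the
  wild-type mean. The default is the stricter, self-contained reading.

Prioritization ranks candidates by embryo expression (a rank, not a hard
floor — "highly expressed" has no published cutoff) and flags egg/sperm
presence (`absent` / `present` / `not_on_array`); filtering to
gamete-absent genes is opt-in, since a gamete-expressed gene can still be
imprinted in the embryo.

### Categorical allele calls and confirmation

A calibrated, maternally oriented fraction becomes a call via two knobs:
`detection_threshold` τ (default 0.1) — a minor-allele fraction below τ
reads as monoallelic, tolerating baseline chromatogram noise — and
`bias_band` (default ±0.15 around 0.5) for "biallelic"; fractions between
the band edge and the monoallelic edge become bias calls. Neither value
is published for this assay class; both are configurable and swept in
tests, and the reference-study verdicts consume transcribed categorical
calls, so they do not depend on these defaults.

Confirmation (MEG): every detected wild-type embryo call must be
maternal-only with at least one detection per cross direction; any
paternal-containing or biallelic call excludes the gene. Bias calls count
as conflicting by default (a visible minor peak is a visible second
allele) — a switch relaxes this. The PEG rule applies the mirror logic to
2–4 cell samples only, because the early PEG pattern dissolves at the
globular stage by construction. The 6×-wash control then re-grades
confirmed MEGs: monoallelic in both stringently washed directions keeps
the gene confirmed, one direction (other undetected) gives partial
confirmation, loss in both gives `lost_in_stringent_wash`, and any
contradicting allele excludes. The wash rule applies to MEGs only —
paternal expression cannot come from maternal sporophytic contamination
in the first place.

Purity QC marks a library `contaminated` when any seed-coat/endosperm
marker amplifies, `low_quality` when the embryo quality markers fail, and
annotates rather than auto-excludes (the strict mode that does exclude is
opt-in), because a low-quality library can still contribute interpretable
monoallelic calls.

Mutant effects are computed per (gene, cross) against a confirmed
baseline. Priority: full switch to the formerly silent parent →
`inverted_parent_of_origin`; no product where wild type had one →
`lost_expression`; any silent-parent signal (biallelic or either bias) →
`derepressed_silent_allele`; identical monoallelic pattern → `unchanged`.
`lost_expression` is observational, not mechanistic — for a heterozygous
paternal cross half the embryos inherit a wild-type allele, so loss may
simply mean the residual transcript sits below the detection limit.

### Concordance categories

External datasets are categorized per gene from oriented counts in both
directions: below `min_total_reads` (default 4) everywhere →
`not_expressed`; fraction ≥ `monoallelic_fraction` (default 0.95) in all
expressed directions → `maternal`/`paternal`; otherwise an exact
two-sided binomial test (minimum-likelihood form; scipy's `binomtest`,
cross-checked against direct pmf enumeration) against the dosage-expected
maternal fraction — 1/2 for the diploid embryo, 2/3 for the triploid
endosperm — drives the bias categories. Accession bias (the same
accession dominant in both parental roles) is checked *before* parental
bias, because a consistent cis effect would otherwise masquerade as
opposite parental biases in the two directions. Benjamini–Hochberg
adjustment across a dataset is optional (default off: the external tables
being reproduced print categories, not p-values). These cutoffs are this
package's defaults; the bundled reference categories store the published
labels verbatim, so label-based aggregation is threshold-independent.

## Synthetic data: what it emulates, and what it does not

`SimConfig` defaults define the study conditions used by the tests and
the acceptance script:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | genes in the discovery study |
| `status_proportions` | MEG 5%, early PEG 1%, biallelic 74%, deposited 10%, silent 10% | truth mixture |
| `mean_expression`, `expression_sigma` | 80, 0.8 | log-normal read-depth scale across genes |
| `dispersion` | 0.3 | negative-binomial overdispersion α (var = μ + αμ²); amplified single-embryo libraries are overdispersed, 0 recovers Poisson |
| `dropout_threshold` | 5 | totals below this emit zero counts / failed RT-PCR |
| `deposition_weight` | 0.8 | maternal carry-over share of a deposited gene's pool at 2–4 cell |
| `deposition_decay` | 0.5 | fraction of that carry-over remaining at globular |
| `contamination_fraction` | 0.0 | seed-coat read admixture (purely maternal), applied to seed-coat-expressed genes |
| `chromatogram_noise_sd` | 0.05 | multiplicative peak noise |
| `allele_bias` | 1.0 | paternal-peak amplification factor |

Deposited genes sit at maternal fraction `1 − 0.5(1−w)` (0.9 at 2–4 cell,
0.7 at globular under the defaults): above the calling threshold early
but carrying real paternal reads, so the replicate run's
one-parent-only rule — not the threshold — is what rejects them. This is
the intended false-positive mechanism and the reason the caller's FDR
stays low without any contamination. Contamination mixes observed
fractions as `f_obs = (1−c)f + c` for seed-coat-expressed genes;
with `c > 0` and deposition on, FDR rises — explored in tests as
documentation, not asserted. No published estimates exist for realistic
`c` or the deposition decay; the defaults are round values in the range a
single-embryo isolation protocol plausibly spans, chosen once.

Not emulated: sequence-level reads and quality scores, trace files,
multi-SNP genes, the genome-wide siRNA mechanism behind delayed paternal
activation, endosperm imprinting mechanisms, and biological correlations
between genes (each gene is independent). Passing synthetic tests
therefore demonstrates the decision logic and its statistical behaviour
under the stated generative model — not performance on any real library,
where dropout, amplification bias and contamination are gene-dependent.

## Numerical choices

- Strict inequalities at the calling threshold (`mi > 0.8`), strict `<` at
  the Sanger detection threshold, inclusive band edge for "biallelic";
  boundary cases are unit-tested.
- Undefined quantities (zero-read indices, precision of an empty call
  set, MEG share with nothing confirmed) are `None`-flagged, never NaN.
- Binomial p-values are exact (minimum-likelihood two-sided); BH
  adjustment, when enabled, uses the largest rejected raw p-value as the
  effective cut so single-gene and table-level paths agree.
- All generators are driven by `numpy.random.default_rng` seeded from
  `SimConfig.seed` through distinct `SeedSequence` spawn keys per stage,
  so adding a stage never perturbs another stage's stream; identical
  seeds give byte-identical TSV output.
- Problem sizes: the acceptance script uses the 2,000-gene discovery
  study, the bundled 24-gene reference study, a 16-point bias sweep of
  the noiseless calibration and 500 noisy dilution series; the whole run
  completes in a few seconds.

## Known limitations

- The genome-wide candidate lists of the original discovery datasets are
  not reproducible here (raw sequencing data are external); the caller is
  validated against a brute-force rule oracle and simulation truth
  instead.
- PEG recall of the caller is low by design under the run-2 consistency
  rule (see above); the confirmed-PEG path is exercised through the
  Sanger/classification stages.
- One chromatogram per (gene, sample) is assumed; multi-SNP consensus and
  within-trace background subtraction are out of scope (peak heights are
  the input contract).
- The wash-control rule requires exactly the reciprocal 6× design; other
  stringency series would need their own rule.
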