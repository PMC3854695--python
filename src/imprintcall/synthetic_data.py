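"""Synthetic reciprocal-cross study generator.

Emulates the statistical structure that the imprinting analysis assumes:

* per-gene truth classes — imprinted MEG/PEG, biallelic, maternally
  deposited (egg-cell transcript carry-over that decays as zygotic
  transcription proceeds), and embryo-silent genes;
* negative-binomial total read depth per gene and sample (amplified
  single-embryo libraries are overdispersed relative to Poisson), with a
  detection dropout floor;
* binomial allele splits around the class-determined maternal fraction,
  optionally distorted by maternal sporophytic (seed-coat) contamination;
* noisy two-peak chromatogram signals with a configurable assay bias, and
  the genomic-DNA dilution series used to calibrate them.

All generators are deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allele_model import (
    COUNT_COLUMNS,
    Genotype,
    SampleSpec,
    Stage,
    Tissue,
    Wash,
    write_sample_sheet,
)
from .errors import ConfigError

TRUTH_STATUSES = (
    "MEG",
    "early_PEG",
    "biallelic",
    "maternally_deposited",
    "silent_in_embryo",
)

#: Col-0 fraction of the five genomic-DNA mixes (Ler:Col-0 = 1:9 ... 9:1).
DILUTION_FRACTIONS = (0.9, 0.75, 0.5, 0.25, 0.1)


@dataclass(frozen=True)
class GeneTruth:
    """Ground-truth imprinting status of one simulated gene."""

    gene_id: str
    status: str
    base_expression: float
    seedcoat_expressed: bool = False
    fie_derepressed: bool = False
    met1_dependent: bool = False

    def __post_init__(self) -> None:
        if self.status not in TRUTH_STATUSES:
            raise ConfigError(f"unknown truth status {self.status!r}")
        if self.base_expression <= 0:
            raise ConfigError("base_expression must be positive")


def _default_proportions() -> dict[str, float]:
    return {
        "MEG": 0.05,
        "early_PEG": 0.01,
        "biallelic": 0.74,
        "maternally_deposited": 0.10,
        "silent_in_embryo": 0.10,
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    ``deposition_weight`` is the share of a deposited gene's transcript pool
    that is maternal carry-over at the 2-4 cell stage; ``deposition_decay``
    is the fraction of that carry-over remaining at the globular stage.
    ``allele_bias`` multiplies the paternal chromatogram peak (1.0 = an
    unbiased assay).  ``dispersion`` is the negative-binomial overdispersion
    alpha (variance = mu + alpha * mu^2); 0 gives Poisson totals.
    """

    n_genes: int = 2000
    status_proportions: Mapping[str, float] = field(
        default_factory=_default_proportions
    )
    contamination_fraction: float = 0.0
    endosperm_contamination: bool = False
    deposition_weight: float = 0.8
    deposition_decay: float = 0.5
    dropout_threshold: int = 5
    mean_expression: float = 80.0
    expression_sigma: float = 0.8
    dispersion: float = 0.3
    chromatogram_noise_sd: float = 0.05
    allele_bias: float = 1.0
    seedcoat_expressed_prob: float = 0.5
    fie_derepressed_prob: float = 0.3
    met1_dependent_prob: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        props = dict(self.status_proportions)
        unknown = set(props) - set(TRUTH_STATUSES)
        if unknown:
            raise ConfigError(f"unknown statuses in proportions: {sorted(unknown)}")
        if any(v < 0 for v in props.values()):
            raise ConfigError("status proportions must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigError("status proportions must sum to 1")
        if not (0.0 <= self.contamination_fraction < 1.0):
            raise ConfigError("contamination_fraction must be in [0, 1)")
        if not (0.0 <= self.deposition_decay <= 1.0):
            raise ConfigError("deposition_decay must be in [0, 1]")
        if not (0.0 < self.deposition_weight < 1.0):
            raise ConfigError("deposition_weight must be in (0, 1)")
        if self.allele_bias <= 0:
            raise ConfigError("allele_bias must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")


def generate_truth(config: SimConfig) -> pd.DataFrame:
    """Draw a ground-truth gene table; status counts follow the configured
    proportions by largest remainder (each within +/-1 of the exact share)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    props = dict(config.status_proportions)
    statuses = [s for s in TRUTH_STATUSES if props.get(s, 0) > 0]
    exact = {s: props[s] * config.n_genes for s in statuses}
    counts = {s: int(np.floor(exact[s])) for s in statuses}
    leftover = config.n_genes - sum(counts.values())
    by_remainder = sorted(statuses, key=lambda s: exact[s] - counts[s], reverse=True)
    for s in by_remainder[:leftover]:
        counts[s] += 1
    labels = np.repeat(
        [s for s in statuses], [counts[s] for s in statuses]
    )
    rng.shuffle(labels)
    expr = np.exp(
        rng.normal(np.log(config.mean_expression), config.expression_sigma, config.n_genes)
    )
    rows = []
    for i, status in enumerate(labels):
        rows.append(
            {
                "gene_id": f"G{i:05d}",
                "status": status,
                "base_expression": float(expr[i]),
                "seedcoat_expressed": bool(
                    rng.random() < config.seedcoat_expressed_prob
                ),
                "fie_derepressed": bool(
                    status == "MEG" and rng.random() < config.fie_derepressed_prob
                ),
                "met1_dependent": bool(
                    status == "early_PEG" and rng.random() < config.met1_dependent_prob
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "status",
            "base_expression",
            "seedcoat_expressed",
            "fie_derepressed",
            "met1_dependent",
        ],
    )


def _deposited_weight(config: SimConfig, stage: Stage) -> float:
    if stage is Stage.TWO_FOUR_CELL:
        return config.deposition_weight
    return config.deposition_weight * config.deposition_decay


def expected_maternal_fraction(
    truth: GeneTruth, sample: SampleSpec, config: SimConfig
) -> float | None:
    """Expected maternal read fraction of a gene in a sample.

    Returns None for genes absent from the sampled tissue (silent-in-embryo
    genes; all genes give None nowhere else).  Seedlings have erased
    imprints (0.5 for every expressed class) and no contamination.
    Embryo samples mix in purely maternal contaminant reads for
    seed-coat-expressed genes: f_obs = (1 - c) * f + c.
    """
    if sample.tissue not in (Tissue.EMBRYO, Tissue.SEEDLING):
        raise ConfigError("expected_maternal_fraction models embryo/seedling samples")
    if truth.status == "silent_in_embryo":
        return None
    if sample.tissue is Tissue.SEEDLING:
        return 0.5

    if truth.status == "MEG":
        f = 1.0
    elif truth.status == "early_PEG":
        f = 0.0 if sample.stage is Stage.TWO_FOUR_CELL else 0.5
    elif truth.status == "biallelic":
        f = 0.5
    else:  # maternally_deposited: carry-over weight on top of biallelic zygotic
        w = _deposited_weight(config, sample.stage)
        f = 1.0 - 0.5 * (1.0 - w)

    # mutant-cross distortions
    if (
        truth.status == "MEG"
        and truth.fie_derepressed
        and sample.maternal_genotype is Genotype.FIE_HET
    ):
        f = 0.7  # silent paternal allele partially derepressed

    c = config.contamination_fraction
    if c > 0 and truth.seedcoat_expressed:
        f = (1.0 - c) * f + c
    return f


def _draw_totals(rng: np.random.Generator, mu: float, config: SimConfig, size: int):
    if config.dispersion == 0:
        return rng.poisson(mu, size)
    n = 1.0 / config.dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p, size)


def simulate_counts(
    truth_table: pd.DataFrame, samples: Sequence[SampleSpec], config: SimConfig
) -> pd.DataFrame:
    """Simulate an accession-keyed count table for the given samples.

    Totals are negative-binomial around ``base_expression``; totals below
    ``dropout_threshold`` are emitted as zero counts (detection dropout).
    A paternal met1 cross knocks met1-dependent PEGs below the dropout
    floor.  Accession columns are emitted in sorted label order so that
    downstream orientation logic is genuinely exercised.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    for rec in truth_table.itertuples(index=False):
        truth = GeneTruth(
            gene_id=rec.gene_id,
            status=rec.status,
            base_expression=rec.base_expression,
            seedcoat_expressed=bool(rec.seedcoat_expressed),
            fie_derepressed=bool(rec.fie_derepressed),
            met1_dependent=bool(rec.met1_dependent),
        )
        for sample in samples:
            acc_a, acc_b = sorted(sample.accession_pair)
            f = expected_maternal_fraction(truth, sample, config)
            if f is None:
                total = 0
            elif (
                truth.status == "early_PEG"
                and truth.met1_dependent
                and sample.paternal_genotype is Genotype.MET1_HET
            ):
                total = 0
            else:
                total = int(_draw_totals(rng, truth.base_expression, config, 1)[0])
            if total < config.dropout_threshold:
                maternal = paternal = 0
            else:
                maternal = int(rng.binomial(total, f))
                paternal = total - maternal
            reads = {sample.maternal_accession: maternal, sample.paternal_accession: paternal}
            rows.append(
                {
                    "gene_id": truth.gene_id,
                    "sample_id": sample.sample_id,
                    "acc_a_label": acc_a,
                    "acc_b_label": acc_b,
                    "reads_acc_a": reads[acc_a],
                    "reads_acc_b": reads[acc_b],
                }
            )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def simulate_chromatogram(
    maternal_fraction: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    scale: float = 1000.0,
) -> tuple[float, float]:
    """Two-peak chromatogram heights (maternal, paternal) for a known
    maternal fraction.

    The paternal peak is multiplied by ``allele_bias`` (an assay that
    amplifies the paternal allele more efficiently than the maternal one
    when bias > 1); both peaks get independent multiplicative Gaussian
    noise, truncated at zero.
    """
    if not (0.0 <= maternal_fraction <= 1.0):
        raise ConfigError("maternal_fraction must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    sd = config.chromatogram_noise_sd
    h_m = maternal_fraction * (1.0 + rng.normal(0.0, sd)) if sd > 0 else maternal_fraction
    h_p = config.allele_bias * (1.0 - maternal_fraction)
    if sd > 0:
        h_p *= 1.0 + rng.normal(0.0, sd)
    return max(h_m, 0.0) * scale, max(h_p, 0.0) * scale


def simulate_dilution_series(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[tuple[float, tuple[float, float]]]:
    """The five-mix genomic-DNA calibration series.

    Returns (true maternal fraction, (peak_m, peak_p)) for Col-0 fractions
    0.9, 0.75, 0.5, 0.25, 0.1 — the 9:1, 3:1, 1:1, 1:3, 1:9 mixes with the
    Col-0 allele read as "maternal".
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    return [
        (f, simulate_chromatogram(f, config, rng=rng)) for f in DILUTION_FRACTIONS
    ]


# ---------------------------------------------------------------------------
# Study designs
# ---------------------------------------------------------------------------


def discovery_sample_sheet() -> list[SampleSpec]:
    """Sequencing design for genome-wide candidate calling.

    Run 1 carries the three library types the caller requires (wild-type
    2-4 cell, kyp-heterozygous 2-4 cell, wild-type globular, all Ler
    mothers); run 2 is an independent replicate run of the wild-type
    libraries used for the reads-from-one-parent-only consistency check.
    """
    mk = lambda sid, stage, geno, run, rep: SampleSpec(  # noqa: E731
        sample_id=sid,
        maternal_accession="Ler",
        paternal_accession="Col-0",
        maternal_genotype=geno,
        stage=stage,
        replicate=rep,
        run_batch=run,
    )
    return [
        mk("r1_24_LxC", Stage.TWO_FOUR_CELL, Genotype.WT, "run1", 1),
        mk("r1_24_kypxC", Stage.TWO_FOUR_CELL, Genotype.KYP_HET, "run1", 1),
        mk("r1_gl_LxC", Stage.GLOBULAR, Genotype.WT, "run1", 1),
        mk("r2_24_LxC", Stage.TWO_FOUR_CELL, Genotype.WT, "run2", 2),
        mk("r2_gl_LxC", Stage.GLOBULAR, Genotype.WT, "run2", 2),
    ]


def confirmation_sample_sheet() -> list[SampleSpec]:
    """Reciprocal-cross confirmation design: 2 directions x 2 stages x 2
    replicates of wild-type embryo libraries."""
    samples = []
    for stage, tag in ((Stage.TWO_FOUR_CELL, "24"), (Stage.GLOBULAR, "gl")):
        for mat, pat, xdir in (("Col-0", "Ler", "CxL"), ("Ler", "Col-0", "LxC")):
            for rep in (1, 2):
                samples.append(
                    SampleSpec(
                        sample_id=f"{xdir}_{tag}_r{rep}",
                        maternal_accession=mat,
                        paternal_accession=pat,
                        stage=stage,
                        replicate=rep,
                    )
                )
    return samples


def simulate_signals(
    truth_table: pd.DataFrame,
    samples: Sequence[SampleSpec],
    config: SimConfig,
) -> pd.DataFrame:
    """Chromatogram signal table for the given samples.

    Peaks are keyed by sorted accession labels (the Sanger stage re-orients
    them by cross direction).  Genes with no expected expression in the
    tissue, and genes whose simulated transcript amount falls below the
    dropout floor in a sample, are emitted as non-amplified records,
    mirroring failed RT-PCRs.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    rows = []
    for rec in truth_table.itertuples(index=False):
        truth = GeneTruth(
            gene_id=rec.gene_id,
            status=rec.status,
            base_expression=rec.base_expression,
            seedcoat_expressed=bool(rec.seedcoat_expressed),
            fie_derepressed=bool(rec.fie_derepressed),
            met1_dependent=bool(rec.met1_dependent),
        )
        for sample in samples:
            acc_a, acc_b = sorted(sample.accession_pair)
            f = expected_maternal_fraction(truth, sample, config)
            amplified = f is not None
            if amplified:
                total = int(_draw_totals(rng, truth.base_expression, config, 1)[0])
                amplified = total >= config.dropout_threshold
            if amplified:
                peak_m, peak_p = simulate_chromatogram(f, config, rng=rng)
                peaks = {
                    sample.maternal_accession: peak_m,
                    sample.paternal_accession: peak_p,
                }
                peak_a, peak_b = peaks[acc_a], peaks[acc_b]
            else:
                peak_a = peak_b = 0.0
            rows.append(
                {
                    "gene_id": truth.gene_id,
                    "sample_id": sample.sample_id,
                    "acc_a_label": acc_a,
                    "acc_b_label": acc_b,
                    "peak_a": round(peak_a, 4),
                    "peak_b": round(peak_b, 4),
                    "amplified": amplified,
                    "true_fraction": "" if f is None else f,
                }
            )
    return pd.DataFrame(rows)


def write_fixture(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete toy study (sample sheet, counts, signals, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(config)
    disc = discovery_sample_sheet()
    conf = confirmation_sample_sheet()
    counts = simulate_counts(truth, disc + conf, config)
    signals = simulate_signals(truth, conf, config)
    paths = {
        "samples": outdir / "samples.tsv",
        "counts": outdir / "counts.tsv",
        "signals": outdir / "signals.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_sample_sheet(disc + conf, paths["samples"])
    counts.to_csv(paths["counts"], sep="\t", index=False)
    signals.to_csv(paths["signals"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
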