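"""Parent-of-origin categorization of read-count datasets from other
stages and accessions, and category aggregation.

Given oriented maternal/paternal read counts of a gene in both directions
of a reciprocal cross, the gene is placed in exactly one category:
monoallelic (maternal/paternal), parentally biased (an exact binomial test
against the tissue's expected maternal fraction — 1/2 in the diploid
embryo, 2/3 in the triploid endosperm), accession-biased (the same
accession dominates in both parental roles, e.g. a Ler-specific cis
effect), biallelic, not expressed, or without SNP coverage.  Aggregating a
selector of categories over a dataset reproduces cross-study concordance
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ContractError

CATEGORIES = (
    "maternal",
    "maternal_bias",
    "paternal",
    "paternal_bias",
    "biallelic",
    "accession_bias",
    "not_expressed",
    "no_snp_coverage",
)

#: Expected maternal read fraction of an unbiased gene, by genome dosage.
EXPECTED_MATERNAL_EMBRYO = 0.5
EXPECTED_MATERNAL_ENDOSPERM = 2.0 / 3.0


@dataclass(frozen=True)
class CategoryThresholds:
    """Categorization knobs.

    The source tables print category labels, not cutoffs, so these are this
    package's defaults: a gene is monoallelic at >= 95% of reads from one
    parent in both directions, detected at >= 4 reads, and biased when the
    exact binomial test rejects the dosage-expected fraction at alpha
    (optionally Benjamini-Hochberg adjusted across a dataset).
    """

    min_total_reads: int = 4
    monoallelic_fraction: float = 0.95
    bias_alpha: float = 0.05
    multiple_testing: str = "none"  # none | BH
    expected_maternal: float = EXPECTED_MATERNAL_EMBRYO

    def __post_init__(self) -> None:
        if not (0.5 < self.monoallelic_fraction <= 1.0):
            raise ConfigError("monoallelic_fraction must lie in (0.5, 1]")
        if not (0.0 < self.bias_alpha < 1.0):
            raise ConfigError("bias_alpha must lie in (0, 1)")
        if self.multiple_testing not in ("none", "BH"):
            raise ConfigError("multiple_testing must be 'none' or 'BH'")
        if not (0.0 < self.expected_maternal < 1.0):
            raise ConfigError("expected_maternal must lie in (0, 1)")


@dataclass(frozen=True)
class DirectionCounts:
    """Oriented counts of one gene in one cross direction."""

    maternal_reads: int
    paternal_reads: int
    maternal_accession: str

    @property
    def total(self) -> int:
        return self.maternal_reads + self.paternal_reads

    @property
    def maternal_fraction(self) -> float | None:
        return self.maternal_reads / self.total if self.total else None

    def accession_reads(self, accession: str, other: str) -> int:
        if accession == self.maternal_accession:
            return self.maternal_reads
        if other == self.maternal_accession:
            return self.paternal_reads
        raise ContractError(f"accession {accession!r} not in this direction")


def binomial_bias_test(
    maternal_reads: int, paternal_reads: int, expected_maternal: float = 0.5
) -> float:
    """Exact two-sided binomial p-value for allelic bias.

    Two-sided in the minimum-likelihood sense: the sum over all outcomes
    whose probability does not exceed the observed outcome's.
    """
    total = maternal_reads + paternal_reads
    if total <= 0:
        raise ContractError("binomial bias test needs at least one read")
    if not (0.0 < expected_maternal < 1.0):
        raise ContractError("expected_maternal must lie in (0, 1)")
    return float(
        stats.binomtest(maternal_reads, total, expected_maternal).pvalue
    )


def _direction_state(d: DirectionCounts, thr: CategoryThresholds):
    """(expressed, fraction, p_maternal_bias) for one direction."""
    if d.total < thr.min_total_reads:
        return False, None, None
    f = d.maternal_fraction
    p = binomial_bias_test(d.maternal_reads, d.paternal_reads, thr.expected_maternal)
    return True, f, p


def categorize(
    directions: Sequence[DirectionCounts | None],
    thresholds: CategoryThresholds | None = None,
    snp_covered: bool = True,
    adjusted_alpha: float | None = None,
) -> tuple[str, bool]:
    """Category of one gene from oriented counts in both cross directions.

    ``directions`` holds one entry per direction; None marks a direction
    with no data, and the category is then computed from the remaining
    direction with a one-direction caveat (second element of the returned
    tuple).  ``snp_covered=False`` short-circuits to no_snp_coverage.

    Cascade: no SNP coverage -> below the read floor in every direction
    (not_expressed) -> monoallelic in all expressed directions ->
    accession bias (same accession significantly dominant in both parental
    roles) -> parental bias (significant same-parent bias in all expressed
    directions) -> biallelic.
    """
    thr = thresholds or CategoryThresholds()
    alpha = thr.bias_alpha if adjusted_alpha is None else adjusted_alpha
    if not snp_covered:
        return "no_snp_coverage", False
    present = [d for d in directions if d is not None]
    if not present:
        return "no_snp_coverage", True
    one_direction = len(present) < 2

    states = [_direction_state(d, thr) for d in present]
    expressed = [
        (d, f, p) for d, (ok, f, p) in zip(present, states) if ok
    ]
    if not expressed:
        return "not_expressed", one_direction
    caveat = one_direction or len(expressed) < 2

    fractions = [f for _, f, _ in expressed]
    if all(f >= thr.monoallelic_fraction for f in fractions):
        return "maternal", caveat
    if all(f <= 1.0 - thr.monoallelic_fraction for f in fractions):
        return "paternal", caveat

    # accession bias: the same accession dominates in both parental roles.
    if len(expressed) >= 2:
        accessions = {d.maternal_accession for d, _, _ in expressed}
        if len(accessions) == 2:
            acc_a, acc_b = sorted(accessions)
            for acc, other in ((acc_a, acc_b), (acc_b, acc_a)):
                biased = []
                for d, f, p in expressed:
                    acc_frac = d.accession_reads(acc, other) / d.total
                    biased.append(acc_frac > 0.5 and p <= alpha)
                if all(biased):
                    return "accession_bias", caveat

    sig = [p <= alpha for _, _, p in expressed]
    if all(sig) and all(f > thr.expected_maternal for f in fractions):
        return "maternal_bias", caveat
    if all(sig) and all(f < thr.expected_maternal for f in fractions):
        return "paternal_bias", caveat
    return "biallelic", caveat


def categorize_table(
    counts: pd.DataFrame,
    thresholds: CategoryThresholds | None = None,
    dataset_id: str = "dataset",
) -> pd.DataFrame:
    """Categorize every gene of one dataset.

    ``counts`` columns: gene_id, direction (1/2), maternal_reads,
    paternal_reads, maternal_accession, and optionally snp_covered.  With
    ``multiple_testing='BH'`` the per-direction binomial p-values are
    Benjamini-Hochberg adjusted across the dataset and bias calls use the
    adjusted values at bias_alpha.
    """
    thr = thresholds or CategoryThresholds()
    gene_dirs: dict[str, dict] = {}
    for rec in counts.itertuples(index=False):
        entry = gene_dirs.setdefault(
            rec.gene_id, {"directions": {}, "snp_covered": True}
        )
        if hasattr(rec, "snp_covered"):
            entry["snp_covered"] = entry["snp_covered"] and bool(rec.snp_covered)
        entry["directions"][int(rec.direction)] = DirectionCounts(
            maternal_reads=int(rec.maternal_reads),
            paternal_reads=int(rec.paternal_reads),
            maternal_accession=str(rec.maternal_accession),
        )

    adjusted_alpha = None
    if thr.multiple_testing == "BH":
        pvals = []
        for entry in gene_dirs.values():
            if not entry["snp_covered"]:
                continue
            for d in entry["directions"].values():
                ok, _, p = _direction_state(d, thr)
                if ok:
                    pvals.append(p)
        if pvals:
            reject, _, _, _ = multipletests(pvals, alpha=thr.bias_alpha, method="fdr_bh")
            # the largest raw p-value still rejected defines the adjusted cut
            rejected = [p for p, r in zip(pvals, reject) if r]
            adjusted_alpha = max(rejected) if rejected else -1.0

    rows = []
    for gene_id in sorted(gene_dirs):
        entry = gene_dirs[gene_id]
        dirs = [entry["directions"].get(1), entry["directions"].get(2)]
        category, caveat = categorize(
            dirs, thr, snp_covered=entry["snp_covered"], adjusted_alpha=adjusted_alpha
        )
        rows.append(
            {
                "gene_id": gene_id,
                "dataset_id": dataset_id,
                "category": category,
                "one_direction_caveat": caveat,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "dataset_id", "category", "one_direction_caveat"]
    )


def aggregate_categories(
    categories: pd.DataFrame,
    selector: Iterable[str],
    dataset_id: str | None = None,
    gene_ids: Iterable[str] | None = None,
) -> int:
    """Count genes of one dataset whose category is in ``selector``."""
    selector = set(selector)
    unknown = selector - set(CATEGORIES)
    if unknown:
        raise ContractError(f"unknown categories in selector: {sorted(unknown)}")
    df = categories
    if dataset_id is not None:
        df = df[df["dataset_id"] == dataset_id]
    if gene_ids is not None:
        df = df[df["gene_id"].isin(set(gene_ids))]
    return int(df["category"].isin(selector).sum())
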