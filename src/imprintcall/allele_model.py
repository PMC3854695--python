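"""Core domain types for reciprocal-cross allele-specific expression.

A *reciprocal cross* mates two inbred accessions in both directions
(A x B and B x A, female parent written first).  Reads of an F1 sample are
assigned to one of the two parental accessions via fixed SNPs; orienting the
accession-keyed counts by the cross direction yields maternal and paternal
read counts, from which the maternal index ``mi = m / (m + p)`` (and
``pi = 1 - mi``) is computed.  Parent-of-origin effects show the same
parental bias in both cross directions, whereas accession effects follow
the accession and flip.

Counts arrive already keyed by accession; SNP/strand bookkeeping happens
upstream of this package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import LoadError, OrientationError, ParseError, ContractError


class Genotype(str, enum.Enum):
    WT = "WT"
    FIE_HET = "fie_het"
    MET1_HET = "met1_het"
    KYP_HET = "kyp_het"


class Stage(str, enum.Enum):
    TWO_FOUR_CELL = "two_four_cell"
    GLOBULAR = "globular"
    TORPEDO = "torpedo"
    SEEDLING = "seedling"
    ENDOSPERM = "endosperm"


class Wash(str, enum.Enum):
    X1 = "x1"
    X6 = "x6"
    NA = "n/a"


class Tissue(str, enum.Enum):
    EMBRYO = "embryo"
    SEEDLING = "seedling"
    ENDOSPERM = "endosperm"
    SEEDCOAT_ENDOSPERM = "seedcoat_endosperm"
    GENOMIC_DNA = "genomic_dna"


#: Embryonic stages, in developmental order.
EMBRYO_STAGES = (Stage.TWO_FOUR_CELL, Stage.GLOBULAR, Stage.TORPEDO)


@dataclass(frozen=True)
class SampleSpec:
    """Metadata of one cDNA library (one cross direction, stage, replicate).

    The female (seed) parent is always ``maternal_accession``; cross
    direction is therefore fully determined by the two accession fields.
    """

    sample_id: str
    maternal_accession: str
    paternal_accession: str
    maternal_genotype: Genotype = Genotype.WT
    paternal_genotype: Genotype = Genotype.WT
    stage: Stage = Stage.TWO_FOUR_CELL
    replicate: int = 1
    wash: Wash = Wash.X1
    tissue: Tissue = Tissue.EMBRYO
    run_batch: str = "run1"

    def __post_init__(self) -> None:
        if self.maternal_accession == self.paternal_accession:
            raise ContractError(
                f"sample {self.sample_id!r}: hybrid samples need two distinct "
                f"parental accessions, got {self.maternal_accession!r} twice"
            )
        if self.replicate < 1:
            raise ContractError(f"sample {self.sample_id!r}: replicate must be >= 1")
        if self.wash is not Wash.NA and self.tissue is not Tissue.EMBRYO:
            raise ContractError(
                f"sample {self.sample_id!r}: wash regime applies to embryo tissue only"
            )

    @property
    def cross_label(self) -> str:
        return f"{self.maternal_accession} x {self.paternal_accession}"

    @property
    def is_mutant_cross(self) -> bool:
        return (
            self.maternal_genotype is not Genotype.WT
            or self.paternal_genotype is not Genotype.WT
        )

    @property
    def accession_pair(self) -> frozenset[str]:
        return frozenset((self.maternal_accession, self.paternal_accession))


@dataclass(frozen=True)
class AlleleCounts:
    """Accession-resolved read counts for one gene in one sample."""

    gene_id: str
    sample_id: str
    acc_a_label: str
    acc_b_label: str
    reads_acc_a: int
    reads_acc_b: int

    def __post_init__(self) -> None:
        if self.reads_acc_a < 0 or self.reads_acc_b < 0:
            raise ContractError(
                f"{self.gene_id}/{self.sample_id}: read counts must be non-negative"
            )


@dataclass(frozen=True)
class ParentalIndex:
    """Maternal/paternal index of one gene in one sample.

    ``mi + pi == 1`` whenever any allele-assignable read was observed;
    with zero informative reads the index is undefined and ``defined``
    is False (no NaN arithmetic downstream).
    """

    mi: float
    pi: float
    n_informative: int

    @property
    def defined(self) -> bool:
        return self.n_informative > 0


def parental_index(maternal_reads: int, paternal_reads: int) -> ParentalIndex:
    """Compute the maternal index from oriented read counts.

    Zero-total input yields an undefined-flagged index rather than an error.
    """
    if maternal_reads < 0 or paternal_reads < 0:
        raise ContractError("read counts must be non-negative")
    total = maternal_reads + paternal_reads
    if total == 0:
        return ParentalIndex(mi=0.0, pi=0.0, n_informative=0)
    mi = maternal_reads / total
    return ParentalIndex(mi=mi, pi=1.0 - mi, n_informative=total)


def orient_counts(counts: AlleleCounts, sample: SampleSpec) -> tuple[int, int]:
    """Map accession-keyed counts to (maternal_reads, paternal_reads).

    The sample's female parent decides which accession column is maternal.
    """
    labels = {counts.acc_a_label, counts.acc_b_label}
    if labels != set(sample.accession_pair):
        raise OrientationError(
            f"{counts.gene_id}/{counts.sample_id}: count labels {sorted(labels)} "
            f"do not match sample parents {sorted(sample.accession_pair)}"
        )
    if counts.acc_a_label == sample.maternal_accession:
        return counts.reads_acc_a, counts.reads_acc_b
    return counts.reads_acc_b, counts.reads_acc_a


# ---------------------------------------------------------------------------
# Tabular I/O.  Counts: TSV with columns gene_id, sample_id, acc_a_label,
# acc_b_label, reads_acc_a, reads_acc_b.  Sample sheet: one row per sample
# with the SampleSpec fields.
# ---------------------------------------------------------------------------

COUNT_COLUMNS = [
    "gene_id",
    "sample_id",
    "acc_a_label",
    "acc_b_label",
    "reads_acc_a",
    "reads_acc_b",
]

SHEET_COLUMNS = [
    "sample_id",
    "maternal_accession",
    "paternal_accession",
    "maternal_genotype",
    "paternal_genotype",
    "stage",
    "replicate",
    "wash",
    "tissue",
    "run_batch",
]


def read_sample_sheet(path: str | Path) -> dict[str, SampleSpec]:
    """Load a sample sheet TSV into a sample_id -> SampleSpec mapping."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"sample sheet not found: {path}")
    # keep_default_na: the wash column legitimately holds the string "n/a"
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"sample sheet {path} lacks columns: {missing}")
    samples: dict[str, SampleSpec] = {}
    for i, row in df.iterrows():
        try:
            spec = SampleSpec(
                sample_id=row["sample_id"],
                maternal_accession=row["maternal_accession"],
                paternal_accession=row["paternal_accession"],
                maternal_genotype=Genotype(row["maternal_genotype"]),
                paternal_genotype=Genotype(row["paternal_genotype"]),
                stage=Stage(row["stage"]),
                replicate=int(row["replicate"]),
                wash=Wash(row["wash"]),
                tissue=Tissue(row["tissue"]),
                run_batch=row["run_batch"],
            )
        except ValueError as exc:
            raise ParseError(f"sample sheet {path}, line {i + 2}: {exc}") from exc
        if spec.sample_id in samples:
            raise LoadError(f"duplicate sample_id {spec.sample_id!r} in {path}")
        samples[spec.sample_id] = spec
    return samples


def write_sample_sheet(samples: Iterable[SampleSpec], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "maternal_accession": s.maternal_accession,
            "paternal_accession": s.paternal_accession,
            "maternal_genotype": s.maternal_genotype.value,
            "paternal_genotype": s.paternal_genotype.value,
            "stage": s.stage.value,
            "replicate": s.replicate,
            "wash": s.wash.value,
            "tissue": s.tissue.value,
            "run_batch": s.run_batch,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, sample_sheet: str | Path) -> pd.DataFrame:
    """Load a count table and join it to its sample sheet.

    Every sample_id in the counts file must appear in the sheet; negative
    or non-numeric counts are rejected with the offending line number.
    Returns one row per (gene, sample) with the SampleSpec columns attached
    and a ``spec`` column holding the SampleSpec objects.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"counts file not found: {path}")
    samples = read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"counts file {path} lacks columns: {missing}")
    for col in ("reads_acc_a", "reads_acc_b"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() | (parsed % 1 != 0)
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ParseError(f"counts file {path}, line {line}: malformed {col}")
        if (parsed < 0).any():
            line = int((parsed < 0).idxmax()) + 2
            raise ParseError(f"counts file {path}, line {line}: negative {col}")
        df[col] = parsed.astype(int)
    unknown = sorted(set(df["sample_id"]) - set(samples))
    if unknown:
        raise LoadError(f"counts file {path}: samples missing from sheet: {unknown}")
    df = df[COUNT_COLUMNS].copy()
    df["spec"] = df["sample_id"].map(samples)
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def build_index_table(
    counts: pd.DataFrame, samples: Mapping[str, SampleSpec] | None = None
) -> pd.DataFrame:
    """Orient counts and compute per-(gene, sample) parental indices.

    ``counts`` is a joined frame from :func:`read_counts` (or any frame with
    the count columns plus either a ``spec`` column or an external
    ``samples`` mapping).  Output columns: gene_id, sample_id, mi, pi,
    n_informative.  Undefined indices (zero reads) carry mi = pi = 0 and
    n_informative = 0.
    """
    rows = []
    for rec in counts.itertuples(index=False):
        spec = samples[rec.sample_id] if samples is not None else rec.spec
        m, p = orient_counts(
            AlleleCounts(
                gene_id=rec.gene_id,
                sample_id=rec.sample_id,
                acc_a_label=rec.acc_a_label,
                acc_b_label=rec.acc_b_label,
                reads_acc_a=int(rec.reads_acc_a),
                reads_acc_b=int(rec.reads_acc_b),
            ),
            spec,
        )
        idx = parental_index(m, p)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "sample_id": rec.sample_id,
                "mi": idx.mi,
                "pi": idx.pi,
                "n_informative": idx.n_informative,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "mi", "pi", "n_informative"]
    )
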