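"""Per-gene imprinting verdicts from per-sample allele calls.

Aggregates categorical Sanger calls across reciprocal crosses, stages and
replicates into a final status per candidate gene, then layers on:

* the stringent 6x-wash control, which rules out maternal sporophytic
  (seed-coat) and endosperm contamination as the source of maternal-only
  signals — a confirmed MEG must stay maternal-only in the stringently
  washed reciprocal libraries;
* sample purity QC via marker RT-PCRs (embryo quality markers present,
  seed-coat/endosperm markers absent);
* F1 seedling calls, which test whether the embryonic imprint persists or
  is erased (biallelic) in vegetative tissue;
* heterozygous mutant crosses (fie = PRC2 disabled, met1 = CG-maintenance
  methylation disabled), which probe derepression of the silent allele.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .allele_model import Genotype, SampleSpec, Tissue, Wash
from .errors import ContractError

STATUS_LEVELS = (
    "confirmed_MEG",
    "partially_confirmed_MEG",
    "excluded_biallelic",
    "not_detected_in_embryo",
    "lost_in_stringent_wash",
    "confirmed_early_PEG",
    "not_confirmed",
)

CONFIRMED_STATUSES = (
    "confirmed_MEG",
    "partially_confirmed_MEG",
    "confirmed_early_PEG",
)

EFFECT_LEVELS = (
    "derepressed_silent_allele",
    "inverted_parent_of_origin",
    "lost_expression",
    "unchanged",
    "not_determined",
)

#: Embryo-quality markers (must amplify) and seed-coat/endosperm
#: contamination markers (must not amplify) of the purity RT-PCR panel.
QUALITY_MARKERS = ("ACT11", "WOX9")
CONTAMINATION_MARKERS = ("TT10", "AT5G42530", "FWA", "AGL46", "AGL62")


@dataclass(frozen=True)
class ConfirmationStatus:
    gene_id: str
    status: str
    evidence: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.status not in STATUS_LEVELS:
            raise ContractError(f"unknown confirmation status {self.status!r}")

    @property
    def confirmed(self) -> bool:
        return self.status in CONFIRMED_STATUSES


@dataclass(frozen=True)
class MutantEffect:
    gene_id: str
    cross_id: str
    effect: str

    def __post_init__(self) -> None:
        if self.effect not in EFFECT_LEVELS:
            raise ContractError(f"unknown mutant effect {self.effect!r}")


@dataclass(frozen=True)
class PurityReport:
    sample_id: str
    quality_ok: bool | None
    contamination_free: bool | None
    verdict: str  # pass | low_quality | contaminated | not_determined


def qc_sample_purity(
    marker_matrix: pd.DataFrame, sample_id: str | None = None
) -> list[PurityReport]:
    """Purity verdicts from a per-sample marker detection matrix.

    ``marker_matrix`` columns: sample_id, marker, detected (0/1).  A marker
    missing from a sample's rows leaves the corresponding component
    undetermined.  Verdict: contaminated if any contamination marker
    amplified; otherwise low_quality if either quality marker failed;
    pass when both components are clean; not_determined when a needed
    marker is missing and nothing positive was seen.
    """
    reports = []
    sample_ids = (
        [sample_id] if sample_id is not None else list(dict.fromkeys(marker_matrix["sample_id"]))
    )
    for sid in sample_ids:
        sub = marker_matrix[marker_matrix["sample_id"] == sid]
        seen = {r.marker: bool(int(r.detected)) for r in sub.itertuples(index=False)}
        quality_ok: bool | None
        if all(m in seen for m in QUALITY_MARKERS):
            quality_ok = all(seen[m] for m in QUALITY_MARKERS)
        elif any(m in seen and not seen[m] for m in QUALITY_MARKERS):
            quality_ok = False
        else:
            quality_ok = None
        contamination_free: bool | None
        if any(seen.get(m, False) for m in CONTAMINATION_MARKERS):
            contamination_free = False
        elif all(m in seen for m in CONTAMINATION_MARKERS):
            contamination_free = True
        else:
            contamination_free = None
        if contamination_free is False:
            verdict = "contaminated"
        elif quality_ok is False:
            verdict = "low_quality"
        elif quality_ok and contamination_free:
            verdict = "pass"
        else:
            verdict = "not_determined"
        reports.append(PurityReport(sid, quality_ok, contamination_free, verdict))
    return reports


# ---------------------------------------------------------------------------
# Confirmation of candidates in wild-type embryo samples
# ---------------------------------------------------------------------------

_MONOALLELIC = {"maternal_only", "paternal_only"}


def _check_embryo_samples(calls, samples):
    for sample_id, _ in calls:
        spec = samples[sample_id]
        if spec.tissue is not Tissue.EMBRYO:
            raise ContractError(
                f"classification takes embryo calls only, got tissue "
                f"{spec.tissue.value!r} for sample {sample_id!r}"
            )


def _directions_detected(calls, samples) -> set[str]:
    return {
        samples[sid].cross_label
        for sid, call in calls
        if call != "not_detected"
    }


def classify_gene(
    gene_id: str,
    calls: Sequence[tuple[str, str]],
    samples: Mapping[str, SampleSpec],
    candidate_class: str,
    min_detected_per_direction: int = 1,
    strict_bias: bool = True,
) -> ConfirmationStatus:
    """Final verdict from wild-type embryo calls (both directions, both
    stages, replicates; absences allowed).

    MEG: every detected call maternal_only, with at least
    ``min_detected_per_direction`` detections per cross direction ->
    confirmed_MEG; any biallelic or paternal-containing call ->
    excluded_biallelic; nothing detected -> not_detected_in_embryo.
    PEG: paternal_only in all detected 2-4 cell samples (one per
    direction) -> confirmed_early_PEG regardless of globular calls;
    biallelic at 2-4 cell -> not_confirmed.

    ``strict_bias`` treats bias calls as conflicting with "only one
    allele" (a visible minor peak is a visible second allele); relaxing it
    lets maternal_bias count as maternal evidence for MEGs.
    """
    calls = list(calls)
    _check_embryo_samples(calls, samples)
    evidence = tuple(calls)
    detected = [(sid, c) for sid, c in calls if c != "not_detected"]
    if not detected:
        return ConfirmationStatus(gene_id, "not_detected_in_embryo", evidence)
    directions = {samples[sid].cross_label for sid, _ in calls}

    if candidate_class == "MEG":
        conflicting = {"biallelic", "paternal_only", "paternal_bias"}
        if strict_bias:
            conflicting = conflicting | {"maternal_bias"}
        if any(c in conflicting for _, c in detected):
            return ConfirmationStatus(gene_id, "excluded_biallelic", evidence)
        ok_calls = {"maternal_only"} if strict_bias else {"maternal_only", "maternal_bias"}
        if all(c in ok_calls for _, c in detected):
            per_dir = Counter(samples[sid].cross_label for sid, _ in detected)
            if all(
                per_dir.get(d, 0) >= min_detected_per_direction for d in directions
            ):
                return ConfirmationStatus(gene_id, "confirmed_MEG", evidence)
        return ConfirmationStatus(gene_id, "not_confirmed", evidence)

    if candidate_class == "PEG":
        early = [
            (sid, c)
            for sid, c in detected
            if samples[sid].stage.value == "two_four_cell"
        ]
        if not early:
            return ConfirmationStatus(gene_id, "not_confirmed", evidence)
        conflicting = {"biallelic", "maternal_only", "maternal_bias"}
        if strict_bias:
            conflicting = conflicting | {"paternal_bias"}
        if any(c in conflicting for _, c in early):
            return ConfirmationStatus(gene_id, "not_confirmed", evidence)
        early_dirs = {samples[sid].cross_label for sid, _ in calls
                      if samples[sid].stage.value == "two_four_cell"}
        per_dir = Counter(samples[sid].cross_label for sid, _ in early)
        if all(per_dir.get(d, 0) >= min_detected_per_direction for d in early_dirs):
            return ConfirmationStatus(gene_id, "confirmed_early_PEG", evidence)
        return ConfirmationStatus(gene_id, "not_confirmed", evidence)

    raise ContractError(f"candidate_class must be 'MEG' or 'PEG', got {candidate_class!r}")


def apply_wash_control(
    status: ConfirmationStatus,
    wash_calls: Sequence[tuple[str, str]],
    samples: Mapping[str, SampleSpec],
) -> ConfirmationStatus:
    """Re-grade a confirmed MEG against the stringently washed (6x)
    reciprocal libraries.

    maternal_only in both 6x directions -> stays confirmed_MEG;
    maternal_only in one direction and undetected in the other ->
    partially_confirmed_MEG; undetected in both -> lost_in_stringent_wash;
    any contradicting allele -> excluded_biallelic.  Non-MEG statuses pass
    through unchanged.
    """
    wash_calls = list(wash_calls)
    for sid, _ in wash_calls:
        spec = samples[sid]
        if spec.wash is not Wash.X6:
            raise ContractError(
                f"wash control takes 6x-washed samples only, got wash "
                f"{spec.wash.value!r} for sample {sid!r}"
            )
    if status.status != "confirmed_MEG" or not wash_calls:
        return status
    evidence = status.evidence + tuple(wash_calls)
    detected = [(sid, c) for sid, c in wash_calls if c != "not_detected"]
    if any(c != "maternal_only" for _, c in detected):
        return ConfirmationStatus(status.gene_id, "excluded_biallelic", evidence)
    if not detected:
        return ConfirmationStatus(status.gene_id, "lost_in_stringent_wash", evidence)
    dirs_all = {samples[sid].cross_label for sid, _ in wash_calls}
    dirs_mat = {samples[sid].cross_label for sid, _ in detected}
    if dirs_mat == dirs_all:
        return ConfirmationStatus(status.gene_id, "confirmed_MEG", evidence)
    return ConfirmationStatus(status.gene_id, "partially_confirmed_MEG", evidence)


def classify_seedling(
    calls: Sequence[tuple[str, str]], samples: Mapping[str, SampleSpec]
) -> str:
    """Imprint fate in reciprocal F1 seedlings.

    biallelic in all detected samples -> erased_biallelic; nothing
    amplified -> not_detected_in_seedling; any monoallelic or biased call
    -> retained_imprint (a bias still carries parent-of-origin memory).
    """
    for sid, _ in calls:
        if samples[sid].tissue is not Tissue.SEEDLING:
            raise ContractError(
                f"seedling classification takes seedling samples only ({sid!r})"
            )
    detected = [c for _, c in calls if c != "not_detected"]
    if not detected:
        return "not_detected_in_seedling"
    if all(c == "biallelic" for c in detected):
        return "erased_biallelic"
    return "retained_imprint"


def _cross_id(spec: SampleSpec) -> str:
    if spec.maternal_genotype is not Genotype.WT:
        return f"{spec.maternal_genotype.value}_maternal"
    if spec.paternal_genotype is not Genotype.WT:
        return f"{spec.paternal_genotype.value}_paternal"
    return "wild_type"


def detect_mutant_effect(
    wt_baseline: ConfirmationStatus,
    mutant_calls: Sequence[tuple[str, str]],
    samples: Mapping[str, SampleSpec],
    cross_id: str,
) -> MutantEffect:
    """Effect of one mutant cross on a confirmed imprinted gene.

    The silent parent is paternal for MEGs, maternal for the early PEG.
    Full switch to the formerly silent parent -> inverted_parent_of_origin;
    any silent-allele signal (biallelic or either bias) -> derepressed;
    no product where wild type had one -> lost_expression; same monoallelic
    pattern -> unchanged; no mutant sample -> not_determined.
    """
    if not wt_baseline.confirmed:
        raise ContractError(
            f"{wt_baseline.gene_id}: mutant effects are computed for confirmed "
            f"genes only (baseline {wt_baseline.status})"
        )
    if not mutant_calls:
        return MutantEffect(wt_baseline.gene_id, cross_id, "not_determined")
    expressed_call = (
        "maternal_only" if wt_baseline.status != "confirmed_early_PEG" else "paternal_only"
    )
    silent_call = (
        "paternal_only" if expressed_call == "maternal_only" else "maternal_only"
    )
    detected = [c for _, c in mutant_calls if c != "not_detected"]
    if not detected:
        return MutantEffect(wt_baseline.gene_id, cross_id, "lost_expression")
    if all(c == silent_call for c in detected):
        return MutantEffect(wt_baseline.gene_id, cross_id, "inverted_parent_of_origin")
    if all(c == expressed_call for c in detected):
        return MutantEffect(wt_baseline.gene_id, cross_id, "unchanged")
    return MutantEffect(wt_baseline.gene_id, cross_id, "derepressed_silent_allele")


def summarize_verdicts(
    statuses: Iterable[ConfirmationStatus],
    effects: Iterable[MutantEffect] = (),
    seedling_classes: Mapping[str, str] | None = None,
    candidate_classes: Mapping[str, str] | None = None,
) -> dict:
    """Tallies over statuses, mutant effects, and seedling classes.

    Reports both the granular wash-control split (fully vs partially
    confirmed MEGs) and the merged MEG count, plus the MEG share of all
    confirmed imprinted genes.  Mutant effects are aggregated per gene
    across crosses: a gene counts as derepressed if any cross derepressed
    its silent allele, and as unchanged if every determined cross left it
    unchanged.
    """
    statuses = list(statuses)
    status_counts = Counter(s.status for s in statuses)
    confirmed_megs_full = status_counts.get("confirmed_MEG", 0)
    confirmed_megs_partial = status_counts.get("partially_confirmed_MEG", 0)
    confirmed_megs = confirmed_megs_full + confirmed_megs_partial
    confirmed_pegs = status_counts.get("confirmed_early_PEG", 0)
    confirmed_total = confirmed_megs + confirmed_pegs
    meg_share = 100.0 * confirmed_megs / confirmed_total if confirmed_total else None

    by_gene: dict[str, list[str]] = {}
    for e in effects:
        by_gene.setdefault(e.gene_id, []).append(e.effect)
    meg_ids = {
        s.gene_id
        for s in statuses
        if s.status in ("confirmed_MEG", "partially_confirmed_MEG")
    }
    effect_counts = Counter()
    megs_derepressed = megs_unchanged = 0
    for gene_id, effs in by_gene.items():
        determined = [e for e in effs if e != "not_determined"]
        for e in effs:
            effect_counts[e] += 1
        if gene_id in meg_ids and determined:
            if "derepressed_silent_allele" in determined or (
                "inverted_parent_of_origin" in determined
            ):
                megs_derepressed += 1
            elif all(e == "unchanged" for e in determined):
                megs_unchanged += 1

    seedling_counts = Counter()
    seedling_biallelic_megs = 0
    if seedling_classes:
        for gene_id, cls in seedling_classes.items():
            seedling_counts[cls] += 1
            if cls == "erased_biallelic" and gene_id in meg_ids:
                seedling_biallelic_megs += 1

    return {
        "status_counts": dict(status_counts),
        "confirmed_megs_full": confirmed_megs_full,
        "confirmed_megs_partial": confirmed_megs_partial,
        "confirmed_megs": confirmed_megs,
        "confirmed_early_pegs": confirmed_pegs,
        "confirmed_imprinted": confirmed_total,
        "meg_share_pct": meg_share,
        "effect_counts": dict(effect_counts),
        "megs_derepressed": megs_derepressed,
        "megs_unchanged": megs_unchanged,
        "seedling_counts": dict(seedling_counts),
        "seedling_biallelic_megs": seedling_biallelic_megs,
    }
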