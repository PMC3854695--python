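"""End-to-end confirmation pipeline over a study in the fixture layout.

Ties the per-gene stages together: wild-type embryo classification, the
6x-wash control re-grade, mutant-cross effect detection, seedling erasure
classification, purity QC, and the summary tallies.  The command-line
``classify`` subcommand is a thin wrapper around :func:`classify_study`.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .allele_model import SampleSpec
from .imprint_classifier import (
    ConfirmationStatus,
    MutantEffect,
    _cross_id,
    apply_wash_control,
    classify_gene,
    classify_seedling,
    detect_mutant_effect,
    qc_sample_purity,
    summarize_verdicts,
)


def _pairs(df: pd.DataFrame, gene_id: str) -> list[tuple[str, str]]:
    sub = df[df["gene_id"] == gene_id]
    return list(zip(sub["sample_id"], sub["call"]))


def classify_study(
    candidates: pd.DataFrame,
    embryo_calls: pd.DataFrame,
    samples: Mapping[str, SampleSpec],
    wash_calls: pd.DataFrame | None = None,
    mutant_calls: pd.DataFrame | None = None,
    seedling_calls: pd.DataFrame | None = None,
    markers: pd.DataFrame | None = None,
    strict_qc: bool = False,
    min_detected_per_direction: int = 1,
) -> dict:
    """Run the full verdict pipeline for every candidate gene.

    ``candidates`` columns: gene_id, candidate_class (MEG|PEG).  Call
    tables carry gene_id, sample_id, call.  With ``strict_qc`` the calls of
    samples whose purity verdict is ``contaminated`` (and, for quality,
    ``low_quality``) are excluded before classification; by default purity
    reports only annotate.

    Returns statuses (gene_id -> ConfirmationStatus), effects (list of
    MutantEffect), seedling (gene_id -> class), purity (list of
    PurityReport), excluded_samples, and the summary dict.
    """
    purity = qc_sample_purity(markers) if markers is not None else []
    excluded = set()
    if strict_qc:
        excluded = {
            r.sample_id for r in purity if r.verdict in ("contaminated", "low_quality")
        }

    def drop_excluded(df: pd.DataFrame | None) -> pd.DataFrame | None:
        if df is None or not excluded:
            return df
        return df[~df["sample_id"].isin(excluded)]

    embryo_calls = drop_excluded(embryo_calls)
    wash_calls = drop_excluded(wash_calls)
    mutant_calls = drop_excluded(mutant_calls)
    seedling_calls = drop_excluded(seedling_calls)

    statuses: dict[str, ConfirmationStatus] = {}
    for rec in candidates.itertuples(index=False):
        status = classify_gene(
            rec.gene_id,
            _pairs(embryo_calls, rec.gene_id),
            samples,
            rec.candidate_class,
            min_detected_per_direction=min_detected_per_direction,
        )
        if wash_calls is not None:
            status = apply_wash_control(
                status, _pairs(wash_calls, rec.gene_id), samples
            )
        statuses[rec.gene_id] = status

    effects: list[MutantEffect] = []
    if mutant_calls is not None:
        crosses: dict[str, list[str]] = {}
        for sid in dict.fromkeys(mutant_calls["sample_id"]):
            crosses.setdefault(_cross_id(samples[sid]), []).append(sid)
        for gene_id, status in statuses.items():
            if not status.confirmed:
                continue
            gene_calls = mutant_calls[mutant_calls["gene_id"] == gene_id]
            for cross_id, sids in sorted(crosses.items()):
                sub = gene_calls[gene_calls["sample_id"].isin(sids)]
                effects.append(
                    detect_mutant_effect(
                        status,
                        list(zip(sub["sample_id"], sub["call"])),
                        samples,
                        cross_id,
                    )
                )

    seedling: dict[str, str] = {}
    if seedling_calls is not None:
        for gene_id in dict.fromkeys(seedling_calls["gene_id"]):
            seedling[gene_id] = classify_seedling(
                _pairs(seedling_calls, gene_id), samples
            )

    summary = summarize_verdicts(
        statuses.values(), effects, seedling or None
    )
    return {
        "statuses": statuses,
        "effects": effects,
        "seedling": seedling,
        "purity": purity,
        "excluded_samples": sorted(excluded),
        "summary": summary,
    }


def statuses_frame(statuses: Mapping[str, ConfirmationStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": g, "status": s.status} for g, s in statuses.items()],
        columns=["gene_id", "status"],
    )


def effects_frame(effects: Sequence[MutantEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene_id": e.gene_id, "cross_id": e.cross_id, "effect": e.effect}
            for e in effects
        ],
        columns=["gene_id", "cross_id", "effect"],
    )


def render_report(result: dict) -> str:
    """Human-readable per-gene rule trace plus the summary tallies."""
    lines = ["# Imprinting confirmation report", ""]
    lines.append("## Per-gene verdicts")
    for gene_id, status in sorted(result["statuses"].items()):
        n_ev = len(status.evidence)
        lines.append(f"- {gene_id}: {status.status} ({n_ev} calls weighed)")
    if result["effects"]:
        lines.append("")
        lines.append("## Mutant-cross effects")
        for e in result["effects"]:
            lines.append(f"- {e.gene_id} [{e.cross_id}]: {e.effect}")
    if result["seedling"]:
        lines.append("")
        lines.append("## Seedling fate")
        for gene_id, cls in sorted(result["seedling"].items()):
            lines.append(f"- {gene_id}: {cls}")
    if result["purity"]:
        lines.append("")
        lines.append("## Sample purity")
        for r in result["purity"]:
            lines.append(
                f"- {r.sample_id}: {r.verdict} "
                f"(quality_ok={r.quality_ok}, contamination_free={r.contamination_free})"
            )
        if result["excluded_samples"]:
            lines.append(
                "- excluded by strict QC: " + ", ".join(result["excluded_samples"])
            )
    s = result["summary"]
    lines += [
        "",
        "## Summary",
        f"- confirmed MEGs: {s['confirmed_megs']} "
        f"({s['confirmed_megs_full']} fully + {s['confirmed_megs_partial']} partially confirmed)",
        f"- confirmed early PEGs: {s['confirmed_early_pegs']}",
        f"- MEG share of confirmed imprinted genes: "
        + (f"{s['meg_share_pct']:.1f}%" if s["meg_share_pct"] is not None else "n/a"),
        f"- MEGs with a derepressed silent allele in mutant crosses: {s['megs_derepressed']}",
        f"- MEGs unchanged across mutant crosses: {s['megs_unchanged']}",
        f"- MEGs biallelic in seedlings: {s['seedling_biallelic_megs']}",
    ]
    return "\n".join(lines) + "\n"
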