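"""Genome-wide candidate calling from staged, replicated parental indices.

A gene is a MEG candidate when its maternal index exceeds the threshold
(strict ``mi > 0.8`` by default) in all detected run-1 samples, in the
2-4 cell run-1 samples only, or in the run-1 globular sample only; PEGs
mirror with the paternal index.  Candidates are then checked against the
second replicate run (reads from one parent only, restricted to the stages
that support the call), with an explicit acceptance path for genes seen in
run-1 globular material but absent from run 2.  Genes deregulated in the
kyp-heterozygous library are dropped: KYP shapes parental contributions
genome-wide rather than locus-specific imprinting, so a candidate whose
monoallelic bias collapses in that library is suspect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .allele_model import Genotype, SampleSpec, Stage
from .errors import ConfigError

SUPPORT_CLASSES = ("all_samples", "early_only", "globular_only")


@dataclass(frozen=True)
class CallerThresholds:
    """Tunable knobs of the candidate caller.

    ``index_threshold`` is strict (a gene at exactly the threshold is not
    called).  ``min_informative_reads`` defines "detected"; amplified
    single-embryo libraries are noisy, so this floor is configurable.
    ``kyp_mode`` selects how "deregulated in the kyp sample" is judged:
    ``"threshold"`` requires the index itself to clear the threshold in the
    kyp library (undetected counts as consistent); ``"relative"`` flags a
    gene only when its kyp index falls ``kyp_margin`` below the mean of the
    detected wild-type run-1 indices.
    """

    index_threshold: float = 0.8
    min_informative_reads: int = 1
    kyp_mode: str = "threshold"
    kyp_margin: float = 0.2

    def __post_init__(self) -> None:
        if not (0.5 < self.index_threshold <= 1.0):
            raise ConfigError("index_threshold must lie in (0.5, 1]")
        if self.min_informative_reads < 1:
            raise ConfigError("min_informative_reads must be >= 1")
        if self.kyp_mode not in ("threshold", "relative"):
            raise ConfigError("kyp_mode must be 'threshold' or 'relative'")


@dataclass(frozen=True)
class CandidateCall:
    """Per-gene outcome of the candidate-calling cascade."""

    gene_id: str
    call: str  # MEG | PEG | none
    support: str | None
    replicate_consistent: bool
    kyp_consistent: bool
    globular_rep1_only_accepted: bool = False


def _group_samples(samples: Mapping[str, SampleSpec]):
    """Split the design into the groups the cascade needs."""
    run1_wt_early, run1_kyp, run1_glob = [], [], []
    run2_early, run2_glob = [], []
    for sid, spec in samples.items():
        is_kyp = (
            spec.maternal_genotype is Genotype.KYP_HET
            or spec.paternal_genotype is Genotype.KYP_HET
        )
        if spec.run_batch == "run1":
            if is_kyp:
                run1_kyp.append(sid)
            elif spec.stage is Stage.TWO_FOUR_CELL:
                run1_wt_early.append(sid)
            elif spec.stage is Stage.GLOBULAR:
                run1_glob.append(sid)
        else:
            if spec.stage is Stage.TWO_FOUR_CELL:
                run2_early.append(sid)
            elif spec.stage is Stage.GLOBULAR:
                run2_glob.append(sid)
    if not run1_wt_early or not run1_glob:
        raise ConfigError(
            "candidate calling needs run-1 wild-type 2-4 cell and globular samples"
        )
    return run1_wt_early, run1_kyp, run1_glob, run2_early, run2_glob


def call_candidates(
    index_table: pd.DataFrame,
    samples: Mapping[str, SampleSpec],
    thresholds: CallerThresholds | None = None,
) -> pd.DataFrame:
    """Run the calling cascade over a per-(gene, sample) index table.

    ``index_table`` columns: gene_id, sample_id, mi, pi, n_informative
    (see :func:`imprintcall.allele_model.build_index_table`).  Returns one
    row per gene with CandidateCall fields.
    """
    thr = thresholds or CallerThresholds()
    groups = _group_samples(samples)
    run1_wt_early, run1_kyp, run1_glob, run2_early, run2_glob = groups

    rows = []
    for gene_id, sub in index_table.groupby("gene_id", sort=True):
        by_sample = {
            r.sample_id: r for r in sub.itertuples(index=False)
        }

        def detected(sid: str) -> bool:
            r = by_sample.get(sid)
            return r is not None and r.n_informative >= thr.min_informative_reads

        def index_of(sid: str, parent: str) -> float:
            r = by_sample[sid]
            return r.mi if parent == "maternal" else r.pi

        best = CandidateCall(
            gene_id=gene_id,
            call="none",
            support=None,
            replicate_consistent=True,
            kyp_consistent=True,
        )
        for call_label, parent in (("MEG", "maternal"), ("PEG", "paternal")):
            early_det = [s for s in run1_wt_early if detected(s)]
            glob_det = [s for s in run1_glob if detected(s)]
            early_ok = bool(early_det) and all(
                index_of(s, parent) > thr.index_threshold for s in early_det
            )
            glob_ok = bool(glob_det) and all(
                index_of(s, parent) > thr.index_threshold for s in glob_det
            )
            if early_ok and glob_ok:
                support = "all_samples"
            elif early_ok:
                support = "early_only"
            elif glob_ok:
                support = "globular_only"
            else:
                continue

            # replicate-run consistency: every detected run-2 sample must
            # carry reads from the calling parent only.
            run2_det = [s for s in run2_early + run2_glob if detected(s)]
            glob_rep1_only = False
            if run2_det:
                replicate_consistent = all(
                    index_of(s, parent) == 1.0 for s in run2_det
                )
            elif not any(detected(s) for s in run1_wt_early + run1_kyp):
                # sequenced in run-1 globular material only and absent from
                # run 2: accepted explicitly (detection-based, so the
                # cascade stays monotone in the index threshold).
                replicate_consistent = True
                glob_rep1_only = True
            else:
                replicate_consistent = False

            # kyp deregulation check (2-4 cell kyp library, where detected)
            kyp_det = [s for s in run1_kyp if detected(s)]
            if not kyp_det:
                kyp_consistent = True
            elif thr.kyp_mode == "threshold":
                kyp_consistent = all(
                    index_of(s, parent) > thr.index_threshold for s in kyp_det
                )
            else:
                wt_det = early_det + glob_det
                if not wt_det:
                    kyp_consistent = True
                else:
                    wt_mean = sum(index_of(s, parent) for s in wt_det) / len(wt_det)
                    kyp_consistent = all(
                        index_of(s, parent) >= wt_mean - thr.kyp_margin
                        for s in kyp_det
                    )

            kept = replicate_consistent and kyp_consistent
            best = CandidateCall(
                gene_id=gene_id,
                call=call_label if kept else "none",
                support=support if kept else None,
                replicate_consistent=replicate_consistent,
                kyp_consistent=kyp_consistent,
                globular_rep1_only_accepted=glob_rep1_only and kept,
            )
            break  # a gene cannot satisfy both MEG and PEG rules at once

        rows.append(
            {
                "gene_id": best.gene_id,
                "call": best.call,
                "support": best.support,
                "replicate_consistent": best.replicate_consistent,
                "kyp_consistent": best.kyp_consistent,
                "globular_rep1_only_accepted": best.globular_rep1_only_accepted,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "call",
            "support",
            "replicate_consistent",
            "kyp_consistent",
            "globular_rep1_only_accepted",
        ],
    )


def prioritize_candidates(
    candidates: pd.DataFrame,
    expression: Mapping[str, float] | pd.Series,
    gamete_presence: pd.DataFrame | None = None,
    absent_only: bool = False,
) -> pd.DataFrame:
    """Rank called candidates by embryo expression, flagging gamete presence.

    ``gamete_presence`` columns: gene_id, egg_present, sperm_present
    (booleans).  Genes absent from the table are flagged ``not_on_array``;
    de-novo-expressed candidates (absent from both gametes) are the most
    interesting, but presence only flags — filtering is opt-in.
    """
    called = candidates[candidates["call"] != "none"].copy()
    expr = pd.Series(expression, dtype=float)
    called["expression"] = called["gene_id"].map(expr)
    if gamete_presence is not None:
        gp = gamete_presence.set_index("gene_id")

        def flag(gene_id: str) -> str:
            if gene_id not in gp.index:
                return "not_on_array"
            row = gp.loc[gene_id]
            return "present" if bool(row["egg_present"]) or bool(row["sperm_present"]) else "absent"

        called["gamete_flag"] = called["gene_id"].map(flag)
    else:
        called["gamete_flag"] = "not_on_array"
    if absent_only:
        called = called[called["gamete_flag"] == "absent"]
    called = called.sort_values(
        ["expression", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    called["rank"] = called.index + 1
    return called


def evaluate_caller(
    truth: pd.DataFrame, calls: pd.DataFrame
) -> dict[str, dict[str, float | None]]:
    """Confusion-matrix metrics per imprinting class.

    Maternally deposited genes count as negatives for MEG calling — the
    caller is supposed to reject carry-over bias.  Precision/FDR are None
    (undefined) when nothing was called in a class.
    """
    merged = truth[["gene_id", "status"]].merge(
        calls[["gene_id", "call"]], on="gene_id", how="inner"
    )
    out: dict[str, dict[str, float | None]] = {}
    for cls, truth_status in (("MEG", "MEG"), ("PEG", "early_PEG")):
        is_true = merged["status"] == truth_status
        is_called = merged["call"] == cls
        tp = int((is_true & is_called).sum())
        fp = int((~is_true & is_called).sum())
        fn = int((is_true & ~is_called).sum())
        sens = tp / (tp + fn) if (tp + fn) else None
        prec = tp / (tp + fp) if (tp + fp) else None
        out[cls] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "sensitivity": sens,
            "precision": prec,
            "fdr": None if prec is None else 1.0 - prec,
        }
    return out
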