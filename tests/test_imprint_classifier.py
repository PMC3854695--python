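"""Confirmation rules, wash control, purity QC, seedling fate, mutant
effects, and the summary tallies."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imprintcall import (
    ConfirmationStatus,
    ContractError,
    classify_gene,
    classify_seedling,
    detect_mutant_effect,
    qc_sample_purity,
    summarize_verdicts,
)
from imprintcall.imprint_classifier import apply_wash_control
from imprintcall.synthetic_data import confirmation_sample_sheet
from imprintcall.allele_model import Genotype, SampleSpec, Stage, Tissue, Wash

WT = {s.sample_id: s for s in confirmation_sample_sheet()}
WT_SIDS = list(WT)

WASH = {
    sid: SampleSpec(
        sample_id=sid, maternal_accession=m, paternal_accession=p, wash=Wash.X6
    )
    for sid, m, p in (
        ("CxL_6x", "Col-0", "Ler"),
        ("LxC_6x", "Ler", "Col-0"),
    )
}
ALL_SAMPLES = {**WT, **WASH}


def confirmed_meg(gene="G"):
    return classify_gene(
        gene, [(sid, "maternal_only") for sid in WT_SIDS], WT, "MEG"
    )


class TestClassifyGene:
    def test_maternal_in_every_sample_confirms_meg(self):
        assert confirmed_meg().status == "confirmed_MEG"

    def test_one_biallelic_replicate_excludes(self):
        calls = [(sid, "maternal_only") for sid in WT_SIDS[1:]]
        calls.append((WT_SIDS[0], "biallelic"))
        st_ = classify_gene("G", calls, WT, "MEG")
        assert st_.status == "excluded_biallelic"

    def test_zero_detections_is_not_detected(self):
        calls = [(sid, "not_detected") for sid in WT_SIDS]
        assert classify_gene("G", calls, WT, "MEG").status == "not_detected_in_embryo"

    def test_fus3_pattern_confirms_early_peg(self):
        """Paternal-only at 2-4 cell in both directions; globular maternal
        in one direction, biallelic in the other, two replicates not
        detected: still a confirmed early PEG."""
        calls = [
            ("CxL_24_r1", "paternal_only"), ("CxL_24_r2", "paternal_only"),
            ("LxC_24_r1", "paternal_only"), ("LxC_24_r2", "paternal_only"),
            ("CxL_gl_r1", "maternal_only"), ("CxL_gl_r2", "not_detected"),
            ("LxC_gl_r1", "biallelic"), ("LxC_gl_r2", "not_detected"),
        ]
        assert classify_gene("FUS3", calls, WT, "PEG").status == "confirmed_early_PEG"

    def test_biallelic_at_two_four_cell_fails_peg(self):
        calls = [(sid, "biallelic") for sid in WT_SIDS]
        assert classify_gene("G", calls, WT, "PEG").status == "not_confirmed"

    def test_detection_needed_in_both_directions(self):
        calls = [
            (sid, "maternal_only" if sid.startswith("CxL") else "not_detected")
            for sid in WT_SIDS
        ]
        assert classify_gene("G", calls, WT, "MEG").status == "not_confirmed"

    def test_non_embryo_calls_rejected(self, seedling_samples):
        samples = {**WT, **seedling_samples}
        calls = [("CxL_sdl", "maternal_only")]
        with pytest.raises(ContractError):
            classify_gene("G", calls, samples, "MEG")

    def test_order_invariance(self):
        calls = [
            ("CxL_24_r1", "biallelic"),
            ("LxC_24_r1", "maternal_only"),
            ("CxL_gl_r1", "not_detected"),
            ("LxC_gl_r2", "maternal_only"),
        ]
        results = {
            classify_gene("G", list(perm), WT, "MEG").status
            for perm in itertools.permutations(calls)
        }
        assert len(results) == 1

    @given(
        base=st.lists(
            st.sampled_from(["maternal_only", "not_detected"]),
            min_size=len(WT_SIDS), max_size=len(WT_SIDS),
        ),
        where=st.integers(0, len(WT_SIDS) - 1),
    )
    @settings(max_examples=100, derandomize=True)
    def test_adding_biallelic_never_improves_the_status(self, base, where):
        """Monotone downgrade: a biallelic observation can only push a gene
        away from confirmation."""
        ranking = {
            "confirmed_MEG": 3,
            "not_confirmed": 2,
            "not_detected_in_embryo": 2,
            "excluded_biallelic": 1,
        }
        calls = list(zip(WT_SIDS, base))
        before = classify_gene("G", calls, WT, "MEG").status
        worse = calls.copy()
        worse[where] = (WT_SIDS[where], "biallelic")
        after = classify_gene("G", worse, WT, "MEG").status
        assert ranking[after] <= ranking[before]


class TestWashControl:
    def test_maternal_in_both_washed_samples_stays_confirmed(self):
        st_ = apply_wash_control(
            confirmed_meg(),
            [("CxL_6x", "maternal_only"), ("LxC_6x", "maternal_only")],
            ALL_SAMPLES,
        )
        assert st_.status == "confirmed_MEG"

    def test_one_direction_only_is_partially_confirmed(self):
        st_ = apply_wash_control(
            confirmed_meg(),
            [("CxL_6x", "maternal_only"), ("LxC_6x", "not_detected")],
            ALL_SAMPLES,
        )
        assert st_.status == "partially_confirmed_MEG"

    def test_lost_in_both_washed_samples(self):
        st_ = apply_wash_control(
            confirmed_meg(),
            [("CxL_6x", "not_detected"), ("LxC_6x", "not_detected")],
            ALL_SAMPLES,
        )
        assert st_.status == "lost_in_stringent_wash"

    def test_contradicting_allele_excludes(self):
        st_ = apply_wash_control(
            confirmed_meg(),
            [("CxL_6x", "biallelic"), ("LxC_6x", "maternal_only")],
            ALL_SAMPLES,
        )
        assert st_.status == "excluded_biallelic"

    def test_one_times_washed_samples_rejected(self):
        with pytest.raises(ContractError):
            apply_wash_control(
                confirmed_meg(), [("CxL_24_r1", "maternal_only")], ALL_SAMPLES
            )

    def test_non_meg_statuses_pass_through(self):
        peg = ConfirmationStatus("FUS3", "confirmed_early_PEG")
        out = apply_wash_control(
            peg, [("CxL_6x", "paternal_only")], ALL_SAMPLES
        )
        assert out.status == "confirmed_early_PEG"


class TestPurityQC:
    def _matrix(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "marker", "detected"])

    def test_clean_embryo_library_passes(self):
        rows = [("S", m, 1) for m in ("ACT11", "WOX9")]
        rows += [("S", m, 0) for m in ("TT10", "AT5G42530", "FWA", "AGL46", "AGL62")]
        (report,) = qc_sample_purity(self._matrix(rows))
        assert report.verdict == "pass"
        assert report.quality_ok and report.contamination_free

    def test_seedcoat_marker_means_contaminated(self):
        rows = [("S", m, 1) for m in ("ACT11", "WOX9", "TT10")]
        rows += [("S", m, 0) for m in ("AT5G42530", "FWA", "AGL46", "AGL62")]
        (report,) = qc_sample_purity(self._matrix(rows))
        assert report.verdict == "contaminated"

    def test_weak_quality_markers_mean_low_quality(self):
        # the 6x-washed Ler x Col-0 library pattern
        rows = [("S", m, 0) for m in ("ACT11", "WOX9")]
        rows += [("S", m, 0) for m in ("TT10", "AT5G42530", "FWA", "AGL46", "AGL62")]
        (report,) = qc_sample_purity(self._matrix(rows))
        assert report.verdict == "low_quality"

    def test_missing_marker_leaves_verdict_undetermined(self):
        rows = [("S", "ACT11", 1), ("S", "WOX9", 1), ("S", "TT10", 0)]
        (report,) = qc_sample_purity(self._matrix(rows))
        assert report.contamination_free is None
        assert report.verdict == "not_determined"


class TestSeedling:
    def test_biallelic_both_directions_is_erased(self, seedling_samples):
        calls = [("CxL_sdl", "biallelic"), ("LxC_sdl", "biallelic")]
        assert classify_seedling(calls, seedling_samples) == "erased_biallelic"

    def test_no_amplification_anywhere(self, seedling_samples):
        calls = [("CxL_sdl", "not_detected"), ("LxC_sdl", "not_detected")]
        assert classify_seedling(calls, seedling_samples) == "not_detected_in_seedling"

    def test_monoallelic_seedling_call_retains_imprint(self, seedling_samples):
        calls = [("CxL_sdl", "maternal_only"), ("LxC_sdl", "biallelic")]
        assert classify_seedling(calls, seedling_samples) == "retained_imprint"

    def test_embryo_samples_rejected(self, seedling_samples):
        samples = {**WT, **seedling_samples}
        with pytest.raises(ContractError):
            classify_seedling([("CxL_24_r1", "biallelic")], samples)


class TestMutantEffects:
    FIE_MAT = {
        "fieCxL_24": SampleSpec(
            sample_id="fieCxL_24", maternal_accession="Col-0",
            paternal_accession="Ler", maternal_genotype=Genotype.FIE_HET,
        ),
        "fieCxL_gl": SampleSpec(
            sample_id="fieCxL_gl", maternal_accession="Col-0",
            paternal_accession="Ler", maternal_genotype=Genotype.FIE_HET,
            stage=Stage.GLOBULAR,
        ),
    }

    def test_biallelic_under_maternal_fie_is_derepression(self):
        eff = detect_mutant_effect(
            confirmed_meg("AT1G29660"),
            [("fieCxL_24", "maternal_bias"), ("fieCxL_gl", "biallelic")],
            self.FIE_MAT, "fie_het_maternal",
        )
        assert eff.effect == "derepressed_silent_allele"

    def test_peg_switching_to_maternal_is_inversion(self):
        peg = ConfirmationStatus("FUS3", "confirmed_early_PEG")
        eff = detect_mutant_effect(
            peg, [("fieCxL_24", "maternal_only")], self.FIE_MAT, "fie_het_paternal"
        )
        assert eff.effect == "inverted_parent_of_origin"

    def test_no_product_where_wild_type_had_one_is_lost(self):
        peg = ConfirmationStatus("FUS3", "confirmed_early_PEG")
        eff = detect_mutant_effect(
            peg, [("fieCxL_24", "not_detected")], self.FIE_MAT, "met1_het_paternal"
        )
        assert eff.effect == "lost_expression"

    def test_same_pattern_as_wild_type_is_unchanged(self):
        eff = detect_mutant_effect(
            confirmed_meg(),
            [("fieCxL_24", "maternal_only"), ("fieCxL_gl", "maternal_only")],
            self.FIE_MAT, "fie_het_maternal",
        )
        assert eff.effect == "unchanged"

    def test_no_mutant_sample_is_not_determined(self):
        eff = detect_mutant_effect(confirmed_meg(), [], self.FIE_MAT, "x")
        assert eff.effect == "not_determined"

    def test_unconfirmed_baseline_rejected(self):
        bad = ConfirmationStatus("G", "excluded_biallelic")
        with pytest.raises(ContractError):
            detect_mutant_effect(bad, [("fieCxL_24", "biallelic")], self.FIE_MAT, "x")


class TestSummary:
    def test_empty_input_gives_zero_summary(self):
        s = summarize_verdicts([])
        assert s["confirmed_megs"] == 0
        assert s["confirmed_imprinted"] == 0
        assert s["meg_share_pct"] is None

    def test_merged_and_granular_meg_counts(self):
        statuses = [
            ConfirmationStatus(f"G{i}", "confirmed_MEG") for i in range(7)
        ] + [
            ConfirmationStatus(f"P{i}", "partially_confirmed_MEG") for i in range(4)
        ] + [ConfirmationStatus("FUS3", "confirmed_early_PEG")]
        s = summarize_verdicts(statuses)
        assert s["confirmed_megs_full"] == 7
        assert s["confirmed_megs_partial"] == 4
        assert s["confirmed_megs"] == 11
        assert s["confirmed_early_pegs"] == 1
        assert s["meg_share_pct"] == pytest.approx(100 * 11 / 12)
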