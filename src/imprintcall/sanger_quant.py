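"""Quantitative allele-fraction estimation from Sanger chromatogram peaks.

At a SNP distinguishing the two parental accessions, the two base peaks of a
chromatogram are approximately proportional to the allele amounts in the
PCR product, so ``peak_a / (peak_a + peak_b)`` estimates the accession-A
allele fraction.  Two controls make the readout quantitative:

* an assay-bias check on heterozygous F1 genomic DNA (true fraction 0.5 in
  both cross directions) verifies that the assay amplifies both alleles
  with equal efficiency;
* a genomic-DNA dilution series (known mixture fractions) calibrates the
  measured-versus-true relationship with a straight-line fit.

An assay whose amplification favours one allele by a factor ``b`` measures
``f' = f / (f + b (1 - f))``; the closed-form inverse
``f = b f' / (1 - f' + b f')`` recovers the true fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allele_model import SampleSpec
from .errors import ContractError, FitError, OrientationError, SignalError, ValidationError

CALL_LEVELS = (
    "maternal_only",
    "paternal_only",
    "biallelic",
    "maternal_bias",
    "paternal_bias",
    "not_detected",
)


@dataclass(frozen=True)
class ChromatogramSignal:
    """Two peak heights at the assay SNP, keyed by accession."""

    gene_id: str
    sample_id: str
    peak_a: float
    peak_b: float
    acc_a_label: str
    acc_b_label: str
    amplified: bool = True

    def __post_init__(self) -> None:
        if self.peak_a < 0 or self.peak_b < 0:
            raise SignalError(
                f"{self.gene_id}/{self.sample_id}: peak heights must be >= 0"
            )


@dataclass(frozen=True)
class Calibration:
    """Straight-line calibration of measured vs true allele fraction."""

    assay_id: str
    slope: float
    intercept: float
    r_squared: float
    bias_ok: bool = True

    @classmethod
    def identity(cls, assay_id: str = "identity") -> "Calibration":
        return cls(assay_id=assay_id, slope=1.0, intercept=0.0, r_squared=1.0)

    def correct(self, measured: float) -> float:
        """Invert the fitted line, clipped to [0, 1]."""
        if self.slope <= 0:
            raise FitError(f"assay {self.assay_id}: unusable calibration (slope <= 0)")
        return float(np.clip((measured - self.intercept) / self.slope, 0.0, 1.0))


@dataclass(frozen=True)
class AlleleCall:
    """Categorical per-sample call with the estimated maternal fraction."""

    gene_id: str
    sample_id: str
    call: str
    maternal_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.call not in CALL_LEVELS:
            raise ContractError(f"unknown allele call {self.call!r}")


def measured_fraction(signal: ChromatogramSignal) -> float | None:
    """Accession-A allele fraction from the two peak heights.

    Scale-invariant in the peaks.  Non-amplified signals yield None; a
    signal claiming amplification with two zero peaks is an error.
    """
    if not signal.amplified:
        return None
    total = signal.peak_a + signal.peak_b
    if total <= 0:
        raise SignalError(
            f"{signal.gene_id}/{signal.sample_id}: amplified signal with zero peaks"
        )
    return signal.peak_a / total


def validate_assay_bias(
    het_control_signals: Sequence[ChromatogramSignal], tolerance: float = 0.1
) -> bool:
    """Check amplification neutrality on heterozygous F1 genomic DNA.

    Every control (true fraction 0.5, both cross directions) must measure
    within ``tolerance`` of 0.5.
    """
    signals = [s for s in het_control_signals]
    if not signals:
        raise ValidationError("assay bias validation needs at least one F1 control")
    for s in signals:
        f = measured_fraction(s)
        if f is None:
            raise ValidationError(
                f"{s.gene_id}/{s.sample_id}: non-amplified F1 genomic-DNA control"
            )
        if abs(f - 0.5) > tolerance:
            return False
    return True


def fit_calibration(
    series: Iterable[tuple[float, float]], assay_id: str = "assay", bias_ok: bool = True
) -> Calibration:
    """Least-squares line of measured fraction on true mixture fraction.

    Needs at least three distinct true fractions (the dilution-series
    design provides five).  ``r_squared`` is the squared Pearson
    correlation of the fit; with zero residual variance it is 1.
    """
    pts = [(float(t), float(m)) for t, m in series]
    true_f = np.array([p[0] for p in pts])
    meas_f = np.array([p[1] for p in pts])
    if len(np.unique(true_f)) < 3:
        raise FitError("calibration needs >= 3 distinct true fractions")
    if np.ptp(true_f) == 0:
        raise FitError("calibration needs variance in the true fractions")
    res = stats.linregress(true_f, meas_f)
    return Calibration(
        assay_id=assay_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        bias_ok=bias_ok,
    )


def biased_fraction(true_fraction: float, bias: float) -> float:
    """Measured fraction produced by an assay with amplification bias ``bias``
    on the counter-allele: f' = f / (f + bias * (1 - f))."""
    denom = true_fraction + bias * (1.0 - true_fraction)
    return true_fraction / denom if denom > 0 else 0.0


def invert_bias(measured: float, bias: float) -> float:
    """Closed-form inverse of :func:`biased_fraction`:
    f = bias * f' / (1 - f' + bias * f')."""
    denom = 1.0 - measured + bias * measured
    return float(np.clip(bias * measured / denom, 0.0, 1.0)) if denom > 0 else 1.0


def estimate_bias(series: Iterable[tuple[float, float]]) -> float:
    """Estimate the amplification bias from a dilution series.

    Each informative point (true and measured fractions strictly inside
    (0, 1)) gives a closed-form bias estimate
    b = f (1 - f') / (f' (1 - f)); the median over points is robust to a
    single noisy mix.
    """
    estimates = []
    for t, m in series:
        if 0.0 < t < 1.0 and 0.0 < m < 1.0:
            estimates.append((t * (1.0 - m)) / (m * (1.0 - t)))
    if not estimates:
        raise FitError("no informative points to estimate assay bias")
    return float(np.median(estimates))


def call_allele(
    signal: ChromatogramSignal,
    sample: SampleSpec,
    calibration: Calibration | None,
    detection_threshold: float = 0.1,
    bias_band: float = 0.15,
) -> AlleleCall:
    """Categorical allele call for one signal in one sample.

    Cascade: not amplified -> not_detected; minor-allele fraction below
    ``detection_threshold`` -> monoallelic call; within ``bias_band`` of
    0.5 -> biallelic; otherwise the corresponding bias call.  The measured
    fraction is corrected through the calibration line and oriented to the
    maternal parent using the sample's cross direction.
    """
    if not signal.amplified:
        return AlleleCall(signal.gene_id, signal.sample_id, "not_detected")
    if calibration is None:
        raise ContractError(
            f"{signal.gene_id}/{signal.sample_id}: no calibration for quantitative call"
        )
    if not calibration.bias_ok:
        raise ContractError(
            f"assay {calibration.assay_id}: failed the F1 genomic-DNA bias control; "
            "quantitative calls refused"
        )
    labels = {signal.acc_a_label, signal.acc_b_label}
    if labels != set(sample.accession_pair):
        raise OrientationError(
            f"{signal.gene_id}/{signal.sample_id}: signal labels {sorted(labels)} "
            f"do not match sample parents {sorted(sample.accession_pair)}"
        )
    f_a = calibration.correct(measured_fraction(signal))
    f_m = f_a if signal.acc_a_label == sample.maternal_accession else 1.0 - f_a
    minor = min(f_m, 1.0 - f_m)
    if minor < detection_threshold:
        call = "maternal_only" if f_m > 0.5 else "paternal_only"
    elif abs(f_m - 0.5) <= bias_band:
        call = "biallelic"
    else:
        call = "maternal_bias" if f_m > 0.5 else "paternal_bias"
    return AlleleCall(signal.gene_id, signal.sample_id, call, maternal_fraction=f_m)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

SIGNAL_COLUMNS = [
    "gene_id",
    "sample_id",
    "acc_a_label",
    "acc_b_label",
    "peak_a",
    "peak_b",
    "amplified",
]


def read_signals(path) -> list[ChromatogramSignal]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ContractError(f"signal table {path} lacks columns: {missing}")
    out = []
    for rec in df.itertuples(index=False):
        out.append(
            ChromatogramSignal(
                gene_id=rec.gene_id,
                sample_id=rec.sample_id,
                peak_a=float(rec.peak_a),
                peak_b=float(rec.peak_b),
                acc_a_label=rec.acc_a_label,
                acc_b_label=rec.acc_b_label,
                amplified=bool(rec.amplified),
            )
        )
    return out


def calls_to_frame(calls: Iterable[AlleleCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "sample_id": c.sample_id,
                "call": c.call,
                "maternal_fraction": (
                    "" if c.maternal_fraction is None else c.maternal_fraction
                ),
            }
            for c in calls
        ],
        columns=["gene_id", "sample_id", "call", "maternal_fraction"],
    )
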