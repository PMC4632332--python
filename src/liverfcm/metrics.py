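"""Segmentation-accuracy and LIC-variability statistics.

Tissue segmentation accuracy (TSA) is the Dice coefficient expressed as a
percentage,

    TSA(%) = 2 * N_cs * 100 / (N_ts + N_tr),

where N_cs is the number of pixels correctly assigned to a tissue class and
N_ts, N_tr are the class sizes in the prediction and the reference.  The
combined segmentation error D_TSA is the Euclidean distance of the
(parenchyma, vessel) TSA pair from the perfect point (100, 100):

    D_TSA(%) = sqrt((100 - TSA_parenchyma)^2 + (100 - TSA_vessels)^2).

Pixel-wise LIC distributions are summarised robustly by their median and
interquartile range; the variability measure is the normalised IQR,

    nIQR(%) = (Q3 - Q1) * 100 / median,

and method agreement is quantified by a coefficient of variation built from
the paired differences (1.96 * SD of the differences over the grand mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .fcm import SegmentationMask
from .relaxometry import LICLevel, ScalarMap, classify_lic_level

__all__ = [
    "LICSummary",
    "AccuracyReport",
    "AgreementStats",
    "tsa",
    "d_tsa",
    "accuracy_report",
    "lic_summary",
    "cv_agreement",
]


@dataclass(frozen=True)
class LICSummary:
    """Robust summary of a pixel-wise LIC sample (mg/g dry weight)."""

    median: float
    q1: float
    q3: float
    iqr: float
    niqr_pct: float
    level: LICLevel
    n_pixels: int


@dataclass(frozen=True)
class AccuracyReport:
    """Per-class TSA, combined D_TSA and the underlying confusion counts."""

    tsa_parenchyma_pct: float
    tsa_vessels_pct: float
    d_tsa_pct: float
    confusion: dict


def tsa(pred: np.ndarray, ref: np.ndarray) -> float:
    """Dice coefficient between two boolean class masks, in percent.

    When both masks are empty the classes agree on absence and TSA is 100
    (documented convention; the Dice ratio is 0/0 there).
    """
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    if pred.shape != ref.shape:
        raise InputError(f"mask shapes differ: {pred.shape} vs {ref.shape}")
    n_pred, n_ref = int(pred.sum()), int(ref.sum())
    if n_pred + n_ref == 0:
        return 100.0
    overlap = int((pred & ref).sum())
    return 2.0 * overlap * 100.0 / (n_pred + n_ref)


def d_tsa(tsa_parenchyma: float, tsa_vessels: float) -> float:
    """Distance of the (TSA_parenchyma, TSA_vessels) pair from (100, 100)."""
    for v in (tsa_parenchyma, tsa_vessels):
        if not (0.0 <= v <= 100.0):
            raise InputError(f"TSA must be in [0, 100], got {v}")
    return float(np.hypot(100.0 - tsa_parenchyma, 100.0 - tsa_vessels))


def accuracy_report(pred: SegmentationMask, ref: SegmentationMask) -> AccuracyReport:
    """Score a predicted vessel/parenchyma segmentation against a reference."""
    if pred.labels.shape != ref.labels.shape:
        raise InputError("prediction and reference shapes differ")
    t_par = tsa(pred.parenchyma, ref.parenchyma)
    t_ves = tsa(pred.vessel, ref.vessel)
    confusion = {}
    for name, p, r in (("parenchyma", pred.parenchyma, ref.parenchyma),
                       ("vessel", pred.vessel, ref.vessel)):
        confusion[name] = {
            "TP": int((p & r).sum()), "FP": int((p & ~r).sum()),
            "FN": int((~p & r).sum()), "TN": int((~p & ~r).sum()),
        }
    return AccuracyReport(tsa_parenchyma_pct=t_par, tsa_vessels_pct=t_ves,
                          d_tsa_pct=d_tsa(t_par, t_ves), confusion=confusion)


def lic_summary(lic: ScalarMap, mask: SegmentationMask | np.ndarray,
                klass: str = "parenchyma") -> LICSummary:
    """Median / quartile summary of LIC over a pixel class.

    ``klass`` selects parenchyma pixels only or the whole ROI
    (``"roi-all"``); invalid-fit pixels are excluded.  Quartiles use linear
    interpolation between order statistics.
    """
    if isinstance(mask, SegmentationMask):
        if klass == "parenchyma":
            sel = mask.parenchyma
        elif klass == "roi-all":
            sel = mask.roi
        else:
            raise InputError(f"klass must be 'parenchyma' or 'roi-all', got {klass!r}")
    else:
        sel = np.asarray(mask, dtype=bool)
    values = lic.values[sel & lic.valid_mask]
    if values.size < 4:
        raise InputError(f"need >= 4 valid pixels for a quartile summary, got {values.size}")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    if med == 0:
        raise InputError("nIQR is undefined for zero median LIC")
    return LICSummary(median=float(med), q1=float(q1), q3=float(q3),
                      iqr=float(q3 - q1), niqr_pct=float((q3 - q1) * 100.0 / med),
                      level=classify_lic_level(float(med)), n_pixels=int(values.size))


@dataclass(frozen=True)
class AgreementStats:
    """Agreement between two paired measurement series: bias (mean of the
    differences) and CV = 1.96 * SD(differences) / grand mean * 100."""

    cv_pct: float
    bias: float
    sd_diff: float
    n: int


def cv_agreement(a, b) -> AgreementStats:
    """Coefficient-of-variation agreement between paired measurements.

    CV(%) = 1.96 * SD(a - b) / mean(a and b pooled) * 100, with the sample
    SD (n-1 denominator); the bias mean(a - b) is reported alongside so
    either limits-of-agreement reading is recoverable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("inputs must be 1D arrays of equal length")
    if a.size < 2:
        raise InputError("need at least 2 pairs")
    diff = a - b
    grand = float(np.concatenate([a, b]).mean())
    if grand == 0:
        raise InputError("CV undefined: grand mean is zero")
    sd = float(diff.std(ddof=1))
    return AgreementStats(cv_pct=1.96 * sd / grand * 100.0,
                          bias=float(diff.mean()), sd_diff=sd, n=int(a.size))
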