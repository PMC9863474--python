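"""Empirical ROC analysis and Youden-optimal cutoff selection.

The decision rule is the strict one used throughout the package: a patient is
called WARDEN iff ratio > threshold. Candidate thresholds are the midpoints
between consecutive distinct observed ratios, plus one sentinel below the
minimum (everyone called WARDEN) and one above the maximum (everyone called
PATCH). Midpoints make the strict rule unambiguous: no observed score ever
sits exactly on a reported cutoff.

The optimal cutoff maximises Youden's J = sensitivity + specificity − 1.
Ties are broken first towards higher specificity — over-calling Warden
carries the anticoagulation burden of a caval prosthesis, so the clinically
conservative direction is to demand stronger evidence before predicting
Warden — and then towards the lower threshold.

AUC is the trapezoidal area over (1 − specificity, sensitivity), which for an
empirical ROC equals the Mann–Whitney probability that a random WARDEN ratio
exceeds a random PATCH ratio, ties counted half.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .scoring import BinaryLabel, ScoredPatient, classify

__all__ = [
    "RocResult",
    "ConfusionMatrix",
    "roc_curve",
    "optimal_cutoff",
    "confusion_at",
    "DegenerateRocWarning",
]

#: Margin used to place the sentinel thresholds outside the observed ratios.
_SENTINEL_MARGIN = 0.01


class DegenerateRocWarning(UserWarning):
    """All ratios identical: every threshold has Youden's J = 0."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 counts at a fixed cutoff; WARDEN is the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


@dataclass(frozen=True)
class RocResult:
    """Threshold sweep with the Youden-optimal operating point.

    ``thresholds`` ascend; ``sensitivity`` is non-increasing and
    ``specificity`` non-decreasing along them (strict > rule).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    optimal_cutoff: float
    optimal_sensitivity: float
    optimal_specificity: float
    auc: float
    n_warden: int
    n_patch: int

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0

    def as_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "optimal_cutoff": self.optimal_cutoff,
            "optimal_sensitivity": self.optimal_sensitivity,
            "optimal_specificity": self.optimal_specificity,
            "auc": self.auc,
            "n_warden": self.n_warden,
            "n_patch": self.n_patch,
        }


def _ratios_and_truth(scored: Iterable[ScoredPatient]) -> tuple[np.ndarray, np.ndarray]:
    ratios, truth = [], []
    for p in scored:
        lab = p.actual_binary
        if lab is None:
            raise ValueError(f"patient {p.patient_id!r} has no actual procedure label")
        ratios.append(p.ratio)
        truth.append(lab is BinaryLabel.WARDEN)
    return np.asarray(ratios, dtype=float), np.asarray(truth, dtype=bool)


def _select_youden(
    thresholds: np.ndarray, sens: np.ndarray, spec: np.ndarray
) -> int:
    """Index of the Youden-optimal threshold with the documented tie-breaks."""
    j = sens + spec - 1.0
    best = j.max()
    candidates = np.flatnonzero(np.isclose(j, best, rtol=0.0, atol=1e-12))
    # tie-break 1: higher specificity; tie-break 2: lower threshold
    best_spec = spec[candidates].max()
    candidates = candidates[np.isclose(spec[candidates], best_spec, atol=1e-12)]
    return int(candidates[np.argmin(thresholds[candidates])])


def roc_curve(scored: Sequence[ScoredPatient]) -> RocResult:
    """Build the empirical Warden-vs-patch ROC over midpoint thresholds.

    Requires at least one WARDEN and one PATCH patient with actual labels;
    raises ``ValueError`` naming the absent class otherwise.
    """
    ratios, truth = _ratios_and_truth(scored)
    n_warden = int(truth.sum())
    n_patch = int((~truth).sum())
    if n_warden == 0:
        raise ValueError("no WARDEN patients in cohort: ROC undefined")
    if n_patch == 0:
        raise ValueError("no PATCH patients in cohort: ROC undefined")

    distinct = np.unique(ratios)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(
        [[distinct[0] - _SENTINEL_MARGIN], mids, [distinct[-1] + _SENTINEL_MARGIN]]
    )

    warden_ratios = ratios[truth]
    patch_ratios = ratios[~truth]
    # strict rule: predicted WARDEN iff ratio > t
    sens = (warden_ratios[None, :] > thresholds[:, None]).mean(axis=1)
    spec = (patch_ratios[None, :] <= thresholds[:, None]).mean(axis=1)

    # trapezoid over the ROC staircase; lexicographic (FPR, TPR) order keeps
    # vertical runs intact so the area is the exact empirical AUC
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))

    if distinct.size == 1:
        _warnings.warn(
            "all ratios identical: cutoff selection is degenerate (J = 0 everywhere)",
            DegenerateRocWarning,
            stacklevel=2,
        )
    idx = _select_youden(thresholds, sens, spec)
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        optimal_cutoff=float(thresholds[idx]),
        optimal_sensitivity=float(sens[idx]),
        optimal_specificity=float(spec[idx]),
        auc=auc,
        n_warden=n_warden,
        n_patch=n_patch,
    )


def optimal_cutoff(roc: RocResult) -> tuple[float, float, float]:
    """Re-derive (cutoff, sensitivity, specificity) from a ROC sweep.

    Idempotent with :func:`roc_curve`'s embedded selection; exposed so a
    sweep computed elsewhere can be re-optimised under the same criterion.
    """
    idx = _select_youden(roc.thresholds, roc.sensitivity, roc.specificity)
    return (
        float(roc.thresholds[idx]),
        float(roc.sensitivity[idx]),
        float(roc.specificity[idx]),
    )


def confusion_at(scored: Sequence[ScoredPatient], cutoff: float) -> ConfusionMatrix:
    """Confusion counts at a fixed cutoff under the strict WARDEN-iff-> rule."""
    if len(scored) == 0:
        raise ValueError("empty cohort: confusion matrix undefined")
    ratios, truth = _ratios_and_truth(scored)
    pred = np.array([classify(r, cutoff) is BinaryLabel.WARDEN for r in ratios])
    return ConfusionMatrix(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )
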