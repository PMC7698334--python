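"""Performance statistics and descriptive outputs of the classification.

Covers: confusion counts and accuracy/sensitivity/specificity (positive
class = IDH-mutant, so sensitivity is the mutation detection rate), exact
Clopper-Pearson binomial confidence intervals (the interval family whose
bounds match the study-style printed CIs), ROC AUC as the Mann-Whitney
probability with ties counted 1/2 over pooled outer-fold decision values,
class-averaged spectra on the normalized (pre-log) scale, and annotation of
selected bins with the metabolites whose resonances fall inside them.

Reported percentages round half away from zero to one decimal.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import rankdata

from .errors import InvalidParameterError
from .features import STAGE_NORMALIZED, FeatureMatrix
from .nested_svm import CVResult
from .spectra_io import IDHMUT, IDHWT
from .synthetic import MetaboliteSpec, default_basis


def round_percent(p: float) -> float:
    """Percentage from a proportion, rounded half away from zero, 1 decimal."""
    # the x100 happens in Decimal: 0.9545 * 100 in binary float is 95.4499...,
    # which would misround the half case
    d = (Decimal(str(float(p))) * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with the IDH-mutant class as positive."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise InvalidParameterError("confusion counts must be >= 0")
        if self.total == 0:
            raise InvalidParameterError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        if self.n_positive == 0:
            raise InvalidParameterError("no positive-class samples")
        return self.tp / self.n_positive

    @property
    def specificity(self) -> float:
        if self.n_negative == 0:
            raise InvalidParameterError("no negative-class samples")
        return self.tn / self.n_negative


def confusion_metrics(cv: CVResult) -> ConfusionCounts:
    """Tally outer-fold predictions into confusion counts (positive = IDHmut)."""
    if cv.n_samples == 0:
        raise InvalidParameterError("empty CV result")
    pos = cv.positive_class
    tp = fn = tn = fp = 0
    for true, pred in zip(cv.true_labels, cv.predicted_labels):
        if true == pos:
            tp, fn = (tp + 1, fn) if pred == pos else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if pred != pos else (tn, fp + 1)
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


@dataclass(frozen=True)
class BinomialCI:
    """Exact two-sided binomial confidence interval for a proportion."""

    successes: int
    trials: int
    alpha: float
    lower: float
    upper: float


def clopper_pearson(successes: int, trials: int, alpha: float = 0.05) -> BinomialCI:
    """Exact (Clopper-Pearson) two-sided CI via the beta-quantile formulation.

    ``lower`` solves ``P(X >= successes | p) = alpha/2`` and ``upper``
    solves ``P(X <= successes | p) = alpha/2``; the boundary cases are
    ``lower = 0`` for zero successes and ``upper = 1`` for all successes
    (where ``lower = (alpha/2)**(1/n)``).
    """
    if trials < 1 or not (0 <= successes <= trials):
        raise InvalidParameterError(f"invalid counts: {successes}/{trials}")
    if not (0 < alpha < 1):
        raise InvalidParameterError("alpha must be in (0, 1)")
    x, n = successes, trials
    lower = 0.0 if x == 0 else float(beta_dist.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(beta_dist.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return BinomialCI(successes=x, trials=n, alpha=alpha, lower=lower, upper=upper)


def roc_auc(cv: CVResult) -> float:
    """AUC over pooled outer-fold decision values (Mann-Whitney, ties 1/2)."""
    y = np.asarray(cv.true_labels)
    d = np.asarray(cv.decision_values, dtype=float)
    pos = y == cv.positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidParameterError("both classes must be present to compute AUC")
    ranks = rankdata(d)  # average ranks handle ties with 1/2 credit
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def average_class_spectra(matrix: FeatureMatrix):
    """Class means of normalized (pre-log) features and their difference.

    Returns ``(mean_mut, mean_wt, difference, bin_edges)`` with
    ``difference = mean_mut - mean_wt``.  Expects the matrix on the
    normalized scale — averaging log-transformed intensities would distort
    the spectral shape.
    """
    if matrix.stage != STAGE_NORMALIZED:
        raise InvalidParameterError(
            f"average_class_spectra expects stage 'normalized', got {matrix.stage!r}"
        )
    labels = np.asarray(matrix.labels)
    mut, wt = matrix.values[labels == IDHMUT], matrix.values[labels == IDHWT]
    if len(mut) == 0 or len(wt) == 0:
        raise InvalidParameterError("both classes must be present")
    return mut.mean(axis=0), wt.mean(axis=0), mut.mean(axis=0) - wt.mean(axis=0), list(matrix.bin_edges)


def default_assignment_table(
    basis: list[MetaboliteSpec] | None = None, tolerance_ppm: float = 0.03
) -> list[tuple[float, float, str]]:
    """Metabolite assignment intervals ``(low, high, name)`` from a basis.

    Each resonance covers ``shift +/- tolerance_ppm`` — a bin is annotated
    with a metabolite when the bin interval and the resonance interval
    overlap, reflecting the linewidth-limited precision of in vivo shifts.
    """
    table = []
    for m in basis or default_basis():
        for shift, _amp in m.peaks:
            table.append((shift - tolerance_ppm, shift + tolerance_ppm, m.name))
    return table


def annotate_bin(bin_edge: tuple[float, float], table) -> list[str]:
    """Metabolites whose assignment interval overlaps the bin; else 'unassigned'."""
    hi, lo = bin_edge
    names = sorted({name for (alo, ahi, name) in table if ahi >= lo and alo <= hi})
    return names if names else ["unassigned"]


def annotate_features(
    selection_frequency: np.ndarray,
    bin_edges: list[tuple[float, float]],
    assignment_table=None,
) -> list[dict]:
    """Annotate every bin with selection frequency and metabolite labels."""
    if len(selection_frequency) != len(bin_edges):
        raise InvalidParameterError("selection_frequency and bin_edges length mismatch")
    table = assignment_table if assignment_table is not None else default_assignment_table()
    return [
        {
            "ppm_high": hi,
            "ppm_low": lo,
            "selection_frequency": float(f),
            "metabolites": annotate_bin((hi, lo), table),
        }
        for (hi, lo), f in zip(bin_edges, selection_frequency)
    ]


@dataclass
class PerformanceReport:
    """Everything the pipeline reports about one cross-validated run."""

    confusion: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    sensitivity_ci: BinomialCI
    specificity_ci: BinomialCI
    auc: float
    fold_k: list[int]
    feature_annotations: list[dict] = field(default_factory=list)

    @property
    def mean_k(self) -> float:
        return float(np.mean(self.fold_k))

    def to_dict(self) -> dict:
        d = {
            "confusion": asdict(self.confusion),
            "accuracy_pct": round_percent(self.accuracy),
            "sensitivity_pct": round_percent(self.sensitivity),
            "specificity_pct": round_percent(self.specificity),
            "sensitivity_ci_pct": [
                round_percent(self.sensitivity_ci.lower),
                round_percent(self.sensitivity_ci.upper),
            ],
            "specificity_ci_pct": [
                round_percent(self.specificity_ci.lower),
                round_percent(self.specificity_ci.upper),
            ],
            "auc": round(self.auc, 3),
            "mean_selected_features": self.mean_k,
            "fold_k": list(map(int, self.fold_k)),
            "feature_annotations": self.feature_annotations,
            "auc_construction": "pooled outer-fold decision values, ties 1/2",
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary_text(self) -> str:
        c = self.confusion
        lines = [
            f"samples: {c.total} ({c.n_positive} {IDHMUT}, {c.n_negative} {IDHWT})",
            f"confusion: tp={c.tp} fn={c.fn} tn={c.tn} fp={c.fp}",
            f"accuracy:    {round_percent(self.accuracy):.1f}%",
            f"sensitivity: {round_percent(self.sensitivity):.1f}% "
            f"(95% CI, {round_percent(self.sensitivity_ci.lower):.1f}-"
            f"{round_percent(self.sensitivity_ci.upper):.1f}%)",
            f"specificity: {round_percent(self.specificity):.1f}% "
            f"(95% CI, {round_percent(self.specificity_ci.lower):.1f}-"
            f"{round_percent(self.specificity_ci.upper):.1f}%)",
            f"AUC: {self.auc:.3f}",
            f"mean number of selected features: {self.mean_k:.2f}",
        ]
        top = [
            a for a in sorted(
                self.feature_annotations,
                key=lambda a: -a["selection_frequency"],
            )
            if a["selection_frequency"] > 0
        ][:5]
        if top:
            lines.append("most frequently selected bins:")
            for a in top:
                mets = ", ".join(a["metabolites"])
                lines.append(
                    f"  [{a['ppm_high']:.3f}, {a['ppm_low']:.3f}] ppm  "
                    f"freq={a['selection_frequency']:.2f}  ({mets})"
                )
        return "\n".join(lines)


def build_report(cv: CVResult, alpha: float = 0.05, assignment_table=None) -> PerformanceReport:
    """Assemble the full performance report from a CV result."""
    conf = confusion_metrics(cv)
    annotations = (
        annotate_features(cv.selection_frequency, cv.bin_edges, assignment_table)
        if cv.bin_edges
        else []
    )
    return PerformanceReport(
        confusion=conf,
        accuracy=conf.accuracy,
        sensitivity=conf.sensitivity,
        specificity=conf.specificity,
        sensitivity_ci=clopper_pearson(conf.tp, conf.n_positive, alpha),
        specificity_ci=clopper_pearson(conf.tn, conf.n_negative, alpha),
        auc=roc_auc(cv),
        fold_k=list(cv.fold_k),
        feature_annotations=annotations,
    )
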