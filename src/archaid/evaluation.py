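"""Accuracy and robustness evaluation: PR/ROC curves, jackknife, perturbations.

Per-SNP scores are compared against the true archaic-ancestry indicator of
the tract containing each SNP on each haplotype.  Precision-recall areas
use the Davis-Goadrich interpolation (linear in true-positive/false-positive
count space, which is non-linear in precision-recall space); ROC areas use
the trapezoid rule.  Standard errors come from a delete-one block jackknife
over contiguous genomic blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .demography import DemographyScenario
from .model import ARCHAIC_MIN_FRACTION, NOT_ARCHAIC_MAX_FRACTION, TrainedModel

__all__ = [
    "EvalCurve",
    "pr_roc",
    "haplotype_level_eval",
    "block_jackknife",
    "operating_point",
    "perturbation_experiment",
    "PerturbationResult",
    "sstar_baseline_eval",
]


@dataclass
class EvalCurve:
    """Threshold-indexed confusion counts with derived rates and area.

    Thresholds are the distinct observed scores in decreasing order; an
    example is called positive at threshold ``t`` when its score >= ``t``.
    """

    kind: str  # "pr" or "roc"
    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    area: float
    se: float | None = field(default=None)

    @property
    def precision(self) -> np.ndarray:
        denom = self.tp + self.fp
        return np.divide(self.tp, denom, out=np.ones_like(self.tp, dtype=float), where=denom > 0)

    @property
    def recall(self) -> np.ndarray:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> np.ndarray:
        return self.fp / (self.fp + self.tn)


def _confusion_points(scores: np.ndarray, truth: np.ndarray):
    """Cumulative TP/FP at each distinct score threshold (ties grouped)."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order].astype(np.int64)
    boundaries = np.nonzero(np.diff(s))[0]
    idx = np.append(boundaries, len(s) - 1)
    cum_tp = np.cumsum(t)[idx]
    cum_fp = (idx + 1) - cum_tp
    return s[idx], cum_tp, cum_fp


def davis_goadrich_aupr(tp: np.ndarray, fp: np.ndarray, n_pos: int) -> float:
    """Area under the PR curve via unit-step interpolation in (TP, FP) space.

    Between successive threshold points the false-positive count is
    interpolated linearly at every integer TP value; the area is the mean of
    the interpolated precisions over TP = 1..P (equivalently the integral of
    precision over recall with the Davis-Goadrich interpolation).
    """
    tp = np.concatenate([[0], tp]).astype(np.float64)
    fp = np.concatenate([[0], fp]).astype(np.float64)
    total_tp = int(tp[-1])
    if total_tp == 0:
        return 0.0
    x = np.arange(1, total_tp + 1, dtype=np.float64)
    # Segment containing x: the first point with TP >= x; its predecessor is
    # the last point with TP < x (among duplicate-TP points, the latest one).
    b = np.searchsorted(tp, x, side="left")
    a = b - 1
    slope = (fp[b] - fp[a]) / (tp[b] - tp[a])
    fpx = fp[a] + slope * (x - tp[a])
    precision = x / (x + fpx)
    return float(precision.sum() / n_pos)


def _roc_auc(tp: np.ndarray, fp: np.ndarray, n_pos: int, n_neg: int) -> float:
    tpr = np.concatenate([[0.0], tp / n_pos, [1.0]])
    fpr = np.concatenate([[0.0], fp / n_neg, [1.0]])
    return float(np.trapezoid(tpr, fpr))


def pr_roc(scores, truth) -> tuple[EvalCurve, EvalCurve]:
    """PR and ROC curves over all distinct score thresholds.

    ``truth`` is the per-example archaic indicator.  Raises if only one
    class is present.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth).ravel().astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must be aligned")
    n_pos = int(truth.sum())
    n_neg = int(len(truth) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to draw a curve")
    thr, tp, fp = _confusion_points(scores, truth)
    fn = n_pos - tp
    tn = n_neg - fp
    common = dict(thresholds=thr, tp=tp, fp=fp, tn=tn, fn=fn)
    pr = EvalCurve(kind="pr", area=davis_goadrich_aupr(tp, fp, n_pos), **common)
    roc = EvalCurve(kind="roc", area=_roc_auc(tp, fp, n_pos, n_neg), **common)
    return pr, roc


def haplotype_level_eval(scores, true_fractions) -> tuple[EvalCurve, EvalCurve]:
    """Whole-haplotype evaluation under the 70/30 labeling rule.

    Haplotypes with intermediate true archaic fractions are excluded from
    the comparison, mirroring how the training labels are defined.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    fractions = np.asarray(true_fractions, dtype=np.float64).ravel()
    keep = (fractions >= ARCHAIC_MIN_FRACTION) | (fractions <= NOT_ARCHAIC_MAX_FRACTION)
    if not keep.any():
        raise ValueError("all haplotypes have intermediate ancestry; nothing to evaluate")
    return pr_roc(scores[keep], fractions[keep] >= ARCHAIC_MIN_FRACTION)


def block_jackknife(statistic: Callable, blocks: Sequence) -> tuple[float, float]:
    """Delete-one-block jackknife estimate and standard error.

    ``statistic`` maps a sequence of blocks to a scalar; blocks should be
    contiguous genomic chunks (e.g. 1 Mb replicates) so that local LD stays
    within a block.
    """
    B = len(blocks)
    if B < 2:
        raise ValueError("need at least 2 blocks for a jackknife")
    estimate = float(statistic(blocks))
    loo = np.array(
        [statistic([b for j, b in enumerate(blocks) if j != i]) for i in range(B)],
        dtype=np.float64,
    )
    se = float(np.sqrt((B - 1) / B * np.sum((loo - loo.mean()) ** 2)))
    return estimate, se


def operating_point(curve: EvalCurve, precision_target: float = 0.8) -> tuple[float, float]:
    """Smallest threshold whose precision reaches the target, with its recall."""
    if curve.kind != "pr":
        raise ValueError("operating_point expects a PR curve")
    ok = curve.precision >= precision_target
    if not ok.any():
        raise ValueError(
            f"precision {precision_target} unattainable; max is {curve.precision.max():.3f}"
        )
    idx = np.nonzero(ok)[0]
    best = idx[np.argmin(curve.thresholds[idx])]
    return float(curve.thresholds[best]), float(curve.recall[best])


@dataclass
class PerturbationResult:
    """One cell of the demographic-misspecification grid."""

    param: str
    factor: float
    precision: float
    recall: float
    log10_fold_precision: float
    log10_fold_recall: float


def _precision_recall_at(scores: np.ndarray, truth: np.ndarray, threshold: float):
    called = scores >= threshold
    tp = int((called & truth).sum())
    fp = int((called & ~truth).sum())
    fn = int((~called & truth).sum())
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return precision, recall


def perturbation_experiment(
    model: TrainedModel,
    base_scenario: DemographyScenario,
    param: str,
    factor: float,
    threshold: float,
    baseline_precision: float,
    baseline_recall: float,
    n_replicates: int = 10,
    region_length: int = 1_000_000,
    seed: int = 1,
    window: int = 50_000,
    step: int = 10_000,
) -> PerturbationResult:
    """Test a model trained on the base demography against a perturbed one.

    Simulates fresh test data with one parameter scaled by ``factor``,
    evaluates the *unperturbed* model at the fixed threshold, and reports
    log10 fold changes of precision and recall relative to the supplied
    baseline values.  Raises ``ValueError`` when the perturbed demography is
    not sensible (the caller should skip and log such cells).
    """
    from .pipeline import simulate_test_regions, snp_scores_and_truth

    perturbed = base_scenario.perturb(param, factor).replace(length_bp=region_length)
    regions = simulate_test_regions(perturbed, n_replicates, seed=seed)
    scores, truth = [], []
    for region in regions:
        s, t = snp_scores_and_truth(model, region, window=window, step=step)
        scores.append(s)
        truth.append(t)
    scores = np.concatenate(scores)
    truth = np.concatenate(truth)
    precision, recall = _precision_recall_at(scores, truth, threshold)
    return PerturbationResult(
        param=param,
        factor=factor,
        precision=precision,
        recall=recall,
        log10_fold_precision=float(np.log10(precision / baseline_precision)),
        log10_fold_recall=float(np.log10(recall / baseline_recall)),
    )


def sstar_baseline_eval(
    regions,
    window: int = 50_000,
    step: int = 10_000,
) -> tuple[EvalCurve, EvalCurve]:
    """Evaluate the rank-normalized S* baseline exactly like the model.

    S* is computed per focal haplotype within its target cohort in each
    window, converted to an empirical-CDF rank in [0, 1] against the pooled
    score distribution of the whole evaluation set, averaged per SNP over
    overlapping windows, and scored against the true per-SNP labels.
    """
    from .pipeline import per_snp_truth
    from .windows import _aggregate_per_snp, ecdf_rank, sstar_raw_windows

    per_region = [sstar_raw_windows(region, window, step) for region in regions]
    pool = np.concatenate([raw.ravel() for _, raw in per_region])
    scores, truth = [], []
    for region, (tiles, raw) in zip(regions, per_region):
        preds = _aggregate_per_snp(region.positions, tiles, ecdf_rank(raw, pool))
        t = per_snp_truth(region, preds.positions)
        scores.append(preds.probabilities.ravel())
        truth.append(t.ravel())
    return pr_roc(np.concatenate(scores), np.concatenate(truth))
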