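"""Logistic-regression classifier for archaic ancestry of haplotype windows.

Training examples are (feature vector, archaic base fraction) pairs from
labeled coalescent simulations.  A window-haplotype is labeled archaic when
at least 70% of its bases truly descend from the archaic population and
non-archaic when at most 30% do; intermediate examples are discarded.  The
model is an unpenalized maximum-likelihood binomial logit fit on the raw
(unstandardized) features; standardization enters only when reporting
weights, as an interpretation device.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .features import REFERENCE_DEPENDENT

__all__ = [
    "ARCHAIC_MIN_FRACTION",
    "NOT_ARCHAIC_MAX_FRACTION",
    "TrainingExample",
    "TrainingSet",
    "TrainedModel",
    "label_fraction",
    "build_training_set",
    "fit_logistic",
    "predict_proba",
    "standardized_weights",
    "feature_subset_model",
    "FEATURE_GROUPS",
]

ARCHAIC_MIN_FRACTION = 0.7
NOT_ARCHAIC_MAX_FRACTION = 0.3


@dataclass
class TrainingExample:
    """One candidate example: features plus the true archaic base fraction."""

    features: np.ndarray
    ancestry_fraction: float
    window: tuple = ()
    focal: int = -1

    @property
    def label(self) -> str:
        return label_fraction(self.ancestry_fraction)


def label_fraction(fraction: float) -> str:
    """70/30 labeling rule (inclusive bounds)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"ancestry fraction must be in [0, 1], got {fraction}")
    if fraction >= ARCHAIC_MIN_FRACTION:
        return "archaic"
    if fraction <= NOT_ARCHAIC_MAX_FRACTION:
        return "not_archaic"
    return "discarded"


@dataclass
class TrainingSet:
    """Labeled design matrix after discarding intermediate-ancestry examples."""

    X: np.ndarray
    y: np.ndarray  # 1 = archaic
    feature_names: list[str]
    n_discarded: int = 0

    @property
    def n_retained(self) -> int:
        return len(self.y)


def build_training_set(
    examples: list[TrainingExample] | None = None,
    *,
    X: np.ndarray | None = None,
    fractions: np.ndarray | None = None,
    feature_names: list[str] | None = None,
) -> TrainingSet:
    """Apply the 70/30 rule and assemble the retained design matrix.

    Accepts either a list of :class:`TrainingExample` or the array form
    (``X`` stacked features with per-row ``fractions``).
    """
    if examples is not None:
        X = np.vstack([ex.features for ex in examples])
        fractions = np.asarray([ex.ancestry_fraction for ex in examples], dtype=float)
    if X is None or fractions is None:
        raise ValueError("provide either examples or (X, fractions)")
    X = np.asarray(X)
    if not np.issubdtype(X.dtype, np.floating):
        X = X.astype(np.float64)
    fractions = np.asarray(fractions, dtype=np.float64)
    if np.any(fractions < 0) or np.any(fractions > 1):
        raise ValueError("ancestry fractions must be in [0, 1]")
    keep_pos = fractions >= ARCHAIC_MIN_FRACTION
    keep_neg = fractions <= NOT_ARCHAIC_MAX_FRACTION
    keep = keep_pos | keep_neg
    if not keep.any():
        raise ValueError("no examples retained after 70/30 filtering")
    return TrainingSet(
        X=X[keep],
        y=keep_pos[keep].astype(np.int8),
        feature_names=list(feature_names) if feature_names else [],
        n_discarded=int((~keep).sum()),
    )


@dataclass
class TrainedModel:
    """Fitted logit weights with feature-standardization metadata."""

    feature_names: list[str]
    weights: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    meta: dict = field(default_factory=dict)

    def design_indices(self, full_names: list[str]) -> np.ndarray:
        """Column indices of this model's features within ``full_names``."""
        lookup = {name: i for i, name in enumerate(full_names)}
        try:
            return np.asarray([lookup[name] for name in self.feature_names])
        except KeyError as exc:
            raise ValueError(f"feature {exc} missing from the supplied columns") from exc

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "archaid-model-v1",
                "feature_names": self.feature_names,
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "feature_means": self.feature_means.tolist(),
                "feature_sds": self.feature_sds.tolist(),
                "meta": self.meta,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        obj = json.loads(text)
        if obj.get("format") != "archaid-model-v1":
            raise ValueError("not a recognized model artifact")
        return cls(
            feature_names=obj["feature_names"],
            weights=np.asarray(obj["weights"], dtype=float),
            intercept=float(obj["intercept"]),
            feature_means=np.asarray(obj["feature_means"], dtype=float),
            feature_sds=np.asarray(obj["feature_sds"], dtype=float),
            meta=obj.get("meta", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _ridge_irls(X: np.ndarray, y: np.ndarray, alpha: float, max_iter: int = 200) -> np.ndarray:
    """Tiny-ridge IRLS fallback used only under separation/singularity."""
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    pen = np.full(p + 1, alpha)
    pen[0] = 0.0  # never penalize the intercept
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        A = (Xd * w[:, None]).T @ Xd + np.diag(pen)
        b = (Xd * w[:, None]).T @ z
        new = np.linalg.solve(A, b)
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta


def fit_logistic(
    ts: TrainingSet,
    seed: int | None = None,
    ridge_fallback_alpha: float = 1e-4,
) -> TrainedModel:
    """Maximum-likelihood binomial logit on the raw features.

    Constant (zero-variance) columns are dropped from the design and given
    weight 0.  If the unpenalized fit fails to produce finite estimates
    (perfect separation or a singular design), a tiny-ridge IRLS fit is used
    instead and flagged in ``meta['ridge_fallback']``.  The fit is
    deterministic given the data; ``seed`` is recorded as provenance only.
    """
    X, y = ts.X, np.asarray(ts.y, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present to fit the classifier")
    p = X.shape[1]
    names = ts.feature_names or [f"x{i}" for i in range(p)]
    means = X.mean(axis=0, dtype=np.float64)
    sds = X.std(axis=0, dtype=np.float64)
    keep = sds > 0
    dropped = [names[i] for i in range(p) if not keep[i]]
    # The sorted-distance block is highly collinear, so the IRLS normal
    # equations are ill-conditioned: always solve in double precision even
    # when the feature matrix is stored as float32.
    Xk = np.ascontiguousarray(X[:, keep], dtype=np.float64)

    beta = None
    ridge = False
    # Newton/IRLS with a hard iteration cap.  With rare positives and a
    # collinear distance block the likelihood is near-flat at the optimum
    # (quasi-separation), so the gradient tolerance may never trigger; the
    # capped fit is the standard GLM behaviour and is accepted as-is.
    max_iter = 200
    n_iter = 0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = LogisticRegression(
                penalty=None, solver="newton-cholesky", tol=1e-8, max_iter=max_iter
            ).fit(Xk, y)
        cand = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        n_iter = int(np.max(clf.n_iter_))
        if np.all(np.isfinite(cand)):
            beta = cand
    except Exception:
        beta = None
    # A per-SD logit swing beyond ~30 means the MLE is diverging under
    # (quasi-)separation; fall back to the flagged tiny-ridge fit.
    if beta is not None and np.max(np.abs(beta[1:]) * sds[keep]) > 30:
        beta = None
    if beta is None:
        ridge = True
        beta = _ridge_irls(Xk, y, ridge_fallback_alpha)

    weights = np.zeros(p)
    weights[keep] = beta[1:]
    meta = {
        "n_examples": int(len(y)),
        "n_positive": int(y.sum()),
        "n_discarded": int(ts.n_discarded),
        "seed": seed,
        "ridge_fallback": ridge,
        "n_iter": n_iter,
        "dropped_constant_features": dropped,
        "data_hash": hashlib.sha1(np.ascontiguousarray(X).tobytes()).hexdigest()[:12],
    }
    return TrainedModel(
        feature_names=list(names),
        weights=weights,
        intercept=float(beta[0]),
        feature_means=means,
        feature_sds=sds,
        meta=meta,
    )


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Posterior probability of archaic ancestry, sigmoid(intercept + w.x)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != len(model.weights):
        raise ValueError(
            f"feature mismatch: model has {len(model.weights)} features, got {X.shape[1]}"
        )
    eta = model.intercept + X @ model.weights
    return 1.0 / (1.0 + np.exp(-eta))


def standardized_weights(model: TrainedModel) -> np.ndarray:
    """Per-feature weight x feature standard deviation (0 for constants)."""
    return model.weights * model.feature_sds


def log_abs_standardized_weights(model: TrainedModel) -> np.ndarray:
    """log10 |standardized weight|, the scale used for weight reporting
    (-inf for exactly-zero weights)."""
    with np.errstate(divide="ignore"):
        return np.log10(np.abs(standardized_weights(model)))


def _group_columns(names: list[str], group: str) -> list[str]:
    if group == "full":
        return list(names)
    if group == "skew_only":
        return ["dist_skew"]
    if group == "private_only":
        return ["n_private"]
    if group == "min_dist_only":
        return ["min_ref_dist"]
    if group == "three_feat":
        return ["dist_skew", "n_private", "min_ref_dist"]
    if group == "no_reference":
        return [n for n in names if n not in REFERENCE_DEPENDENT]
    raise ValueError(f"unknown feature group {group!r}")


FEATURE_GROUPS = ("full", "skew_only", "private_only", "min_dist_only", "three_feat", "no_reference")


def feature_subset_model(ts: TrainingSet, group: str, seed: int | None = None) -> TrainedModel:
    """Refit the classifier on a named feature subset.

    ``no_reference`` removes every feature that depends on the reference
    panel (minimum reference distance, private SNP count, and S*, whose
    candidate sites are defined by absence from the reference).
    """
    cols = _group_columns(ts.feature_names, group)
    idx = [ts.feature_names.index(c) for c in cols]
    sub = TrainingSet(
        X=ts.X[:, idx], y=ts.y, feature_names=cols, n_discarded=ts.n_discarded
    )
    model = fit_logistic(sub, seed=seed)
    model.meta["feature_group"] = group
    return model
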