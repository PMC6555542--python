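"""Per-haplotype, per-window summary statistics for archaic ancestry detection.

For one focal haplotype within one analysis window, the feature vector
concatenates (in fixed order):

* the individual frequency spectrum (IFS): a length-``n`` vector whose entry
  ``i`` (1-based) counts the derived alleles carried by the focal haplotype
  whose derived-allele count in the ``n``-haplotype target panel is ``i``;
* the sorted vector of Euclidean distances from the focal haplotype to every
  target haplotype (self included, so the first entry is 0);
* the first four moments (mean, variance, skew, kurtosis) of that vector;
* the minimum Euclidean distance to any reference haplotype;
* the number of SNPs private to the focal haplotype relative to the
  reference panel;
* the S* statistic over the private sites;
* optionally (default on) the total derived-allele count on the focal
  haplotype, for a total of ``2n + 8`` features.

All features are functions of the target and reference panels only — the
archaic genome is never touched, which is what makes the method
reference-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "SStarConfig",
    "HaplotypeWindow",
    "FeatureVector",
    "feature_names",
    "compute_ifs",
    "compute_distance_features",
    "compute_min_ref_distance",
    "count_private_snps",
    "compute_s_star",
    "featurize",
    "featurize_cohort",
]


@dataclass(frozen=True)
class SStarConfig:
    """Pairwise-score dialect of the S* dynamic program.

    A chain of candidate sites accumulates ``bp + bonus`` for each
    consecutive pair at least ``min_bp`` apart and ``penalty`` otherwise;
    chains may skip sites and restart (score floored at 0).
    """

    bonus: float = 5_000.0
    min_bp: int = 10
    penalty: float = -10_000.0


DEFAULT_SSTAR = SStarConfig()


@dataclass
class HaplotypeWindow:
    """The data visible to the featurizer for one focal haplotype.

    ``target`` is the (n x S) 0/1 target-panel matrix over the window's
    variant columns, ``reference`` the (n_ref x S) reference panel on the
    same columns; 1 encodes the derived allele.
    """

    positions: np.ndarray
    target: np.ndarray
    reference: np.ndarray
    start: int
    end: int
    focal: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.target = np.asarray(self.target, dtype=np.uint8)
        self.reference = np.asarray(self.reference, dtype=np.uint8)
        if self.target.ndim != 2 or self.reference.ndim != 2:
            raise ValueError("target and reference must be 2-D haplotype matrices")
        if self.target.shape[1] != len(self.positions) or self.reference.shape[1] != len(
            self.positions
        ):
            raise ValueError("matrices and positions disagree on the number of sites")
        if not (0 <= self.focal < self.target.shape[0]):
            raise ValueError("focal index outside the target panel")

    @property
    def n(self) -> int:
        return self.target.shape[0]

    @property
    def n_ref(self) -> int:
        return self.reference.shape[0]


@dataclass
class FeatureVector:
    """Assembled features for one (focal haplotype, window) example."""

    ifs: np.ndarray
    dist: np.ndarray
    dist_moments: tuple[float, float, float, float]
    min_ref_dist: float
    n_private: int
    s_star: float
    focal_derived: int | None = None
    names: list[str] = field(default_factory=list, repr=False)

    def to_array(self) -> np.ndarray:
        parts = [
            self.ifs.astype(float),
            self.dist.astype(float),
            np.asarray(self.dist_moments, dtype=float),
            np.asarray([self.min_ref_dist, self.n_private, self.s_star], dtype=float),
        ]
        if self.focal_derived is not None:
            parts.append(np.asarray([self.focal_derived], dtype=float))
        return np.concatenate(parts)


def feature_names(n: int, extra: bool = True) -> list[str]:
    """Column names in the fixed feature ordering for target panel size ``n``."""
    names = [f"ifs_{i}" for i in range(1, n + 1)]
    names += [f"dist_{i}" for i in range(1, n + 1)]
    names += ["dist_mean", "dist_var", "dist_skew", "dist_kurt"]
    names += ["min_ref_dist", "n_private", "s_star"]
    if extra:
        names.append("focal_derived")
    return names


#: Feature names that depend on the reference panel (used for ablations).
REFERENCE_DEPENDENT = ("min_ref_dist", "n_private", "s_star")


def compute_ifs(window: HaplotypeWindow) -> np.ndarray:
    """Individual frequency spectrum of the focal haplotype.

    Entry ``i`` (1-based, up to ``n``) counts focal-carried derived alleles
    whose derived count in the target panel equals ``i``; the last entry
    therefore counts sites fixed derived in the target panel.
    """
    T = window.target
    counts = T.sum(axis=0, dtype=np.int64)
    carried = T[window.focal].astype(bool)
    return np.bincount(counts[carried], minlength=window.n + 1)[1:].astype(np.int64)


def _moments(values: np.ndarray) -> tuple[float, float, float, float]:
    """Raw population moments: mean, variance, skew (m3/m2^1.5), kurtosis
    (m4/m2^2, non-excess).  Zero-variance input gives skew = kurtosis = 0."""
    mean = float(values.mean())
    dev = values - mean
    m2 = float(np.mean(dev**2))
    if m2 == 0.0:
        return mean, 0.0, 0.0, 0.0
    m3 = float(np.mean(dev**3))
    m4 = float(np.mean(dev**4))
    return mean, m2, m3 / m2**1.5, m4 / m2**2


def _moments_rows(values: np.ndarray) -> np.ndarray:
    """Row-wise version of :func:`_moments` for an (n, k) matrix."""
    mean = values.mean(axis=1)
    dev = values - mean[:, None]
    m2 = (dev**2).mean(axis=1)
    m3 = (dev**3).mean(axis=1)
    m4 = (dev**4).mean(axis=1)
    ok = m2 > 0
    skew = np.zeros_like(m2)
    kurt = np.zeros_like(m2)
    skew[ok] = m3[ok] / m2[ok] ** 1.5
    kurt[ok] = m4[ok] / m2[ok] ** 2
    return np.column_stack([mean, m2, skew, kurt])


def compute_distance_features(
    window: HaplotypeWindow,
) -> tuple[np.ndarray, tuple[float, float, float, float]]:
    """Sorted Euclidean distances from the focal haplotype to every target
    haplotype (self distance 0 included) plus the first four moments."""
    T = window.target.astype(np.float64)
    diff = T - T[window.focal]
    d = np.sqrt((diff**2).sum(axis=1))
    d.sort()
    return d, _moments(d)


def compute_min_ref_distance(window: HaplotypeWindow) -> float:
    """Minimum Euclidean distance from the focal haplotype to the reference
    panel over the window's site set."""
    if window.n_ref < 1:
        raise ValueError("min_ref_dist is undefined with an empty reference panel")
    if len(window.positions) == 0:
        return 0.0
    focal = window.target[window.focal : window.focal + 1].astype(np.float64)
    d = cdist(focal, window.reference.astype(np.float64))
    return float(d.min())


def _private_mask(window: HaplotypeWindow) -> np.ndarray:
    ref_counts = window.reference.sum(axis=0, dtype=np.int64)
    return window.target[window.focal].astype(bool) & (ref_counts == 0)


def count_private_snps(window: HaplotypeWindow) -> int:
    """Sites where the focal haplotype carries the derived allele and no
    reference haplotype does."""
    return int(_private_mask(window).sum())


def _s_star_dp(candidate_positions: np.ndarray, config: SStarConfig) -> float:
    """Best chain score over ordered candidate sites.

    ``S(j) = max(0, max_{i<j} S(i) + s(i, j))`` with the pairwise score
    ``s(i, j) = bp + bonus`` when the base-pair gap is at least ``min_bp``
    and ``penalty`` otherwise; a single site scores 0.
    """
    k = len(candidate_positions)
    if k < 2:
        return 0.0
    pos = candidate_positions.astype(np.float64)
    best = np.zeros(k)
    for j in range(1, k):
        gaps = pos[j] - pos[:j]
        scores = np.where(gaps >= config.min_bp, gaps + config.bonus, config.penalty)
        best[j] = max(0.0, float((best[:j] + scores).max()))
    return float(best.max())


def compute_s_star(window: HaplotypeWindow, config: SStarConfig = DEFAULT_SSTAR) -> float:
    """S* over the focal haplotype's private sites (0 with < 2 candidates)."""
    candidates = window.positions[_private_mask(window)]
    return _s_star_dp(candidates, config)


def featurize(
    window: HaplotypeWindow,
    config: SStarConfig = DEFAULT_SSTAR,
    extra_feature: bool = True,
) -> FeatureVector:
    """Assemble the full feature vector for one focal haplotype."""
    ifs = compute_ifs(window)
    dist, moments = compute_distance_features(window)
    fv = FeatureVector(
        ifs=ifs,
        dist=dist,
        dist_moments=moments,
        min_ref_dist=compute_min_ref_distance(window),
        n_private=count_private_snps(window),
        s_star=compute_s_star(window, config),
        focal_derived=int(window.target[window.focal].sum()) if extra_feature else None,
        names=feature_names(window.n, extra=extra_feature),
    )
    return fv


def featurize_cohort(
    positions: np.ndarray,
    target: np.ndarray,
    reference: np.ndarray,
    config: SStarConfig = DEFAULT_SSTAR,
    extra_feature: bool = True,
) -> np.ndarray:
    """Feature matrix for every target haplotype of one window at once.

    Vectorized equivalent of calling :func:`featurize` with each focal index
    in turn; returns an ``(n, n_features)`` array in the same ordering.
    """
    T = np.asarray(target, dtype=np.uint8)
    R = np.asarray(reference, dtype=np.uint8)
    positions = np.asarray(positions, dtype=np.int64)
    n, S = T.shape
    p = 2 * n + 7 + (1 if extra_feature else 0)
    out = np.empty((n, p), dtype=np.float64)

    counts = T.sum(axis=0, dtype=np.int64)  # target derived counts per site
    Tf = T.astype(np.float64)
    if S > 0:
        # IFS: per focal, histogram of target counts over carried sites,
        # computed as one matrix product with a one-hot count indicator.
        onehot = np.zeros((S, n + 1))
        onehot[np.arange(S), counts] = 1.0
        out[:, :n] = (Tf @ onehot)[:, 1:]
        D = cdist(Tf, Tf)  # pairwise target distances
        out[:, n : 2 * n] = np.sort(D, axis=1)
        ref_min = cdist(Tf, R.astype(np.float64)).min(axis=1)
    else:
        out[:, : 2 * n] = 0.0
        ref_min = np.zeros(n)

    out[:, 2 * n : 2 * n + 4] = _moments_rows(out[:, n : 2 * n])
    out[:, 2 * n + 4] = ref_min

    ref_counts = R.sum(axis=0, dtype=np.int64)
    private = T.astype(bool) & (ref_counts == 0)[None, :]
    out[:, 2 * n + 5] = private.sum(axis=1)
    for f in range(n):
        out[f, 2 * n + 6] = _s_star_dp(positions[private[f]], config)
    if extra_feature:
        out[:, 2 * n + 7] = T.sum(axis=1)
    return out
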