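"""Archaic-genome match diagnostics for validating ancestry calls.

When an archaic genome *is* available (e.g. a sequenced Neanderthal), calls
made without it can be validated after the fact: haplotypes called archaic
should match the archaic genome more often than haplotypes called
non-archaic.  The match statistic for a focal haplotype in a window is

    NMS = S / (N + H)

where ``S`` counts sites at which the focal haplotype carries a derived
allele also carried (in at least one copy — the archaic genome is unphased)
by the archaic genome, ``N`` counts archaic-genome mutation sites
(heterozygous or homozygous derived) in the window, and ``H`` counts human
mutation sites — sites segregating in the target sample at which the
archaic genome is not variant.  The archaic/non-archaic contrast in a
window is normalized by the window's mean NMS to cancel mutation-rate
heterogeneity:

    delta = (mean NMS archaic - mean NMS non-archaic) / mean NMS all

and its genome-wide mean is tested against zero with a 100 kb delete-one
block jackknife.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .evaluation import block_jackknife

__all__ = [
    "MatchWindow",
    "nms",
    "match_window_counts",
    "delta_nms",
    "bvalue_bins",
]

logger = logging.getLogger(__name__)

MIN_CALLABLE_FRACTION = 0.9


@dataclass
class MatchWindow:
    """Match counts for one focal haplotype in one window."""

    S: int  # focal alleles matching the archaic genome
    N: int  # archaic-genome mutation sites (het + hom)
    H: int  # human mutation sites where the archaic genome is not variant
    callable_fraction: float = 1.0

    def __post_init__(self):
        if min(self.S, self.N, self.H) < 0:
            raise ValueError("counts must be >= 0")
        if self.S > self.N + self.H:
            raise ValueError("S cannot exceed N + H")
        if not 0.0 <= self.callable_fraction <= 1.0:
            raise ValueError("callable_fraction must be in [0, 1]")


def nms(w: MatchWindow) -> float:
    """Match statistic S / (N + H); undefined when no mutation sites exist."""
    denom = w.N + w.H
    if denom == 0:
        raise ValueError("NMS undefined with no archaic or human mutation sites")
    return w.S / denom


def match_window_counts(
    positions: np.ndarray,
    focal_haplotype: np.ndarray,
    target_matrix: np.ndarray,
    archaic_genotypes: np.ndarray,
    start: int,
    end: int,
    callable_fraction: float = 1.0,
) -> MatchWindow:
    """Compute (S, N, H) from 0/1-coded matrices over one window.

    ``archaic_genotypes`` holds per-site derived-allele counts of the
    (possibly diploid, unphased) archaic genome; any count >= 1 makes the
    site an archaic mutation site, and a focal derived allele there counts
    as a match.  In simulations the simulated archaic haplotype stands in
    for a real archaic reference (a synthetic archaic-genome mode), making
    the diagnostics testable end to end without external data.
    """
    positions = np.asarray(positions)
    in_win = (positions >= start) & (positions < end)
    focal = np.asarray(focal_haplotype, dtype=np.int64)[in_win]
    arch = np.asarray(archaic_genotypes, dtype=np.int64)[in_win]
    tcounts = np.asarray(target_matrix, dtype=np.int64).sum(axis=0)[in_win]
    arch_site = arch >= 1
    human_site = (tcounts >= 1) & ~arch_site
    return MatchWindow(
        S=int(((focal >= 1) & arch_site).sum()),
        N=int(arch_site.sum()),
        H=int(human_site.sum()),
        callable_fraction=callable_fraction,
    )


def _window_delta(arch_nms: np.ndarray, non_arch_nms: np.ndarray) -> float:
    all_mean = np.concatenate([arch_nms, non_arch_nms]).mean()
    if all_mean == 0:
        return 0.0
    return float((arch_nms.mean() - non_arch_nms.mean()) / all_mean)


def delta_nms(
    windows: list[dict],
    block_size: int = 100_000,
    min_callable: float = MIN_CALLABLE_FRACTION,
) -> tuple[float, float]:
    """Genome-wide mean normalized NMS contrast and its jackknife p-value.

    Each window dict carries ``start`` (bp), ``archaic`` and ``non_archaic``
    (arrays of per-haplotype NMS values for the two call classes) and
    optionally ``callable_fraction``.  Windows with fewer than 90% callable
    bases, or missing either call class, are skipped.  The p-value is a
    two-sided z-test with the standard error from a delete-one jackknife
    over non-overlapping ``block_size`` blocks of windows.
    """
    deltas, starts = [], []
    for w in windows:
        if w.get("callable_fraction", 1.0) < min_callable:
            logger.info("window at %s skipped: insufficient callable fraction", w.get("start"))
            continue
        arch = np.asarray(w["archaic"], dtype=float)
        non = np.asarray(w["non_archaic"], dtype=float)
        if arch.size == 0 or non.size == 0:
            continue
        deltas.append(_window_delta(arch, non))
        starts.append(w["start"])
    if not deltas:
        raise ValueError("no qualifying windows for the NMS contrast")
    deltas = np.asarray(deltas)
    block_ids = np.asarray(starts) // block_size
    blocks = [deltas[block_ids == b] for b in np.unique(block_ids)]
    mean, se = block_jackknife(lambda bs: np.concatenate(bs).mean(), blocks)
    if se == 0:
        p = 1.0 if mean == 0 else 0.0
    else:
        p = float(2 * norm.sf(abs(mean / se)))
    return float(mean), p


B_VALUE_BINS = ((0, 250), (250, 500), (500, 750), (750, 1000))


def bvalue_bins(
    positions: np.ndarray,
    b_values: np.ndarray,
    archaic_frequency: np.ndarray,
    block_size: int = 50_000,
) -> tuple[dict[tuple[int, int], float], float]:
    """Mean confidently-archaic call frequency per B-value bin.

    B-values measure background selection strength (lower = more
    constrained).  Sites are binned into [0-250], (250-500], (500-750] and
    (750-1000]; an empty bin is reported as NaN.  The lowest-vs-highest bin
    difference is tested with a 50 kb block jackknife z-test.
    """
    positions = np.asarray(positions)
    b_values = np.asarray(b_values, dtype=float)
    freq = np.asarray(archaic_frequency, dtype=float)
    bin_means: dict[tuple[int, int], float] = {}
    for i, (lo, hi) in enumerate(B_VALUE_BINS):
        mask = ((b_values > lo) if i else (b_values >= lo)) & (b_values <= hi)
        bin_means[(lo, hi)] = float(freq[mask].mean()) if mask.any() else float("nan")

    low_mask = b_values <= B_VALUE_BINS[0][1]
    high_mask = b_values > B_VALUE_BINS[-1][0]
    block_ids = positions // block_size
    uniq = np.unique(block_ids)
    blocks = [
        (freq[(block_ids == b) & low_mask], freq[(block_ids == b) & high_mask]) for b in uniq
    ]

    def contrast(bs):
        lows = np.concatenate([b[0] for b in bs])
        highs = np.concatenate([b[1] for b in bs])
        if lows.size == 0 or highs.size == 0:
            return 0.0
        return lows.mean() - highs.mean()

    diff, se = block_jackknife(contrast, blocks)
    p = 1.0 if se == 0 and diff == 0 else (0.0 if se == 0 else float(2 * norm.sf(abs(diff / se))))
    return bin_means, p
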