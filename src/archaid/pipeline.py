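"""End-to-end workflows: simulate training data, train, score test regions.

These are the high-level entry points glueing the simulator, featurizer,
classifier and window machinery together; the command-line interface and
the evaluation harness are thin layers over them.
"""

from __future__ import annotations

import numpy as np

from .demography import (
    DemographyScenario,
    SimulatedRegion,
    ancestry_fraction,
    replicate_seeds,
    simulate_region,
)
from .features import DEFAULT_SSTAR, SStarConfig, feature_names, featurize_cohort
from .model import TrainedModel, TrainingSet, build_training_set, feature_subset_model, fit_logistic
from .windows import predict_per_snp

__all__ = [
    "training_features",
    "train_on_scenario",
    "simulate_test_regions",
    "snp_scores_and_truth",
    "per_snp_truth",
    "haplotype_window_scores",
]


def training_features(
    scenario: DemographyScenario,
    n_replicates: int,
    seed: int,
    n_target: int = 100,
    n_ref: int = 100,
    sstar_config: SStarConfig = DEFAULT_SSTAR,
    extra_feature: bool = True,
    dtype=np.float64,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Simulate training windows and featurize every target haplotype.

    Each replicate is one training window (default 50 kb); every one of the
    ``n_target`` haplotypes yields one candidate example.  Returns the
    stacked feature matrix, per-example true archaic base fractions, and the
    feature column names.  ``dtype=np.float32`` halves memory for
    full-scale (10^6-example) training sets; features are exact small
    integers and distances, so the narrowing loses no information that the
    classifier can use.
    """
    seeds = replicate_seeds(seed, n_replicates)
    names = feature_names(n_target, extra=extra_feature)
    X = np.empty((n_replicates * n_target, len(names)), dtype=dtype)
    fracs = np.empty(n_replicates * n_target)
    for i, s in enumerate(seeds):
        region = simulate_region(scenario, n_target=n_target, n_ref=n_ref, seed=int(s))
        rows = slice(i * n_target, (i + 1) * n_target)
        X[rows] = featurize_cohort(
            region.positions,
            region.target_matrix(),
            region.reference_matrix(),
            config=sstar_config,
            extra_feature=extra_feature,
        )
        fracs[rows] = [ancestry_fraction(region, h) for h in range(n_target)]
    return X, fracs, names


def train_on_scenario(
    scenario: DemographyScenario,
    n_replicates: int,
    seed: int,
    n_target: int = 100,
    n_ref: int = 100,
    group: str = "full",
    extra_feature: bool = True,
    dtype=np.float64,
) -> tuple[TrainedModel, TrainingSet]:
    """Simulate, label (70/30 rule) and fit the window classifier."""
    X, fracs, names = training_features(
        scenario,
        n_replicates,
        seed,
        n_target=n_target,
        n_ref=n_ref,
        extra_feature=extra_feature,
        dtype=dtype,
    )
    ts = build_training_set(X=X, fractions=fracs, feature_names=names)
    if group == "full":
        model = fit_logistic(ts, seed=seed)
    else:
        model = feature_subset_model(ts, group, seed=seed)
    model.meta.update(
        {
            "scenario": repr(scenario),
            "n_replicates": n_replicates,
            "n_target": n_target,
            "n_ref": n_ref,
        }
    )
    return model, ts


def simulate_test_regions(
    scenario: DemographyScenario,
    n_replicates: int,
    seed: int,
    region_length: int = 1_000_000,
    n_target: int = 100,
    n_ref: int = 100,
) -> list[SimulatedRegion]:
    """Independent test replicates (default 1 Mb) under a scenario."""
    sc = scenario.replace(length_bp=region_length)
    seeds = replicate_seeds(seed, n_replicates)
    return [
        simulate_region(sc, n_target=n_target, n_ref=n_ref, seed=int(s)) for s in seeds
    ]


def per_snp_truth(region: SimulatedRegion, positions: np.ndarray | None = None) -> np.ndarray:
    """True archaic indicator at each (SNP, target haplotype).

    A SNP on a haplotype is archaic when its position falls inside one of
    that haplotype's archaic ancestry tracts.
    """
    if positions is None:
        positions = region.positions
    truth = np.zeros((len(positions), region.n_target), dtype=bool)
    for h in range(region.n_target):
        for start, end in region.tracts[h]:
            lo, hi = np.searchsorted(positions, [start, end])
            truth[lo:hi, h] = True
    return truth


def snp_scores_and_truth(
    model: TrainedModel,
    region: SimulatedRegion,
    window: int = 50_000,
    step: int = 10_000,
    extra_feature: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Flattened per-SNP scores and matching true labels for one region."""
    preds = predict_per_snp(model, region, window=window, step=step, extra_feature=extra_feature)
    truth = per_snp_truth(region, preds.positions)
    return preds.probabilities.ravel(), truth.ravel()


def haplotype_window_scores(
    model: TrainedModel,
    regions: list[SimulatedRegion],
    window: int = 50_000,
    extra_feature: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """One score and true archaic fraction per (50 kb window, haplotype).

    Windows tile each region without overlap and each focal haplotype is
    scored once per window, for whole-haplotype evaluation.
    """
    from .windows import predict_windows

    scores, fracs = [], []
    for region in regions:
        tiles, probs = predict_windows(
            model, region, window=window, step=window, extra_feature=extra_feature
        )
        for (start, end), row in zip(tiles, probs):
            scores.append(row)
            fracs.append(
                [ancestry_fraction(region, h, (start, end)) for h in range(region.n_target)]
            )
    return np.concatenate(scores), np.concatenate(fracs)
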