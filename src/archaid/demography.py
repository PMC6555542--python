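"""Coalescent simulation of the split/admixture demography with ancestry tracking.

The demographic model relates three populations sampled at present: a
*target* population that received a single pulse of archaic admixture, an
unadmixed *reference* population, and the *archaic* population itself.
Forward in time: an ancestral population of diploid size ``N0`` splits
``T0`` generations ago into the archaic lineage (size ``Na``) and the
modern lineage; the modern lineage splits ``Ts`` generations ago into the
reference (``N1``) and target (``N2``) populations; ``Ta`` generations ago
the archaic population contributes a fraction ``m`` of the target
population's ancestry in a single-generation pulse.

Simulations run in :mod:`msprime` with times in generations and diploid
effective sizes, so no coalescent-unit rescaling is needed.  Archaic
ancestry is recovered exactly by placing a census between the admixture
pulse and the target/reference split and tracing which genomic intervals of
each target haplotype descend from census lineages sitting in the archaic
population.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import msprime
import numpy as np

__all__ = [
    "StructureEvent",
    "DemographyScenario",
    "SimulatedRegion",
    "table1_scenario",
    "make_structured_scenario",
    "simulate_region",
    "ancestry_fraction",
    "draw_rate_heterogeneity",
    "replicate_seeds",
]

#: Default simulated region length in base pairs.
DEFAULT_LENGTH = 50_000


@dataclass(frozen=True)
class StructureEvent:
    """Transient population structure on one branch of the demography.

    Forward in time, a fraction of the tagged population separates into a
    fully isolated deme at ``split_time`` generations ago and rejoins at
    ``rejoin_time`` generations ago (``rejoin_time < split_time``).  The
    fraction is the lineage-sampling probability at the rejoin looking
    backward in time; there is no migration during the separation.
    """

    population: str  # "target" or "ancestral"
    split_time: float
    rejoin_time: float
    fraction: float


@dataclass(frozen=True)
class DemographyScenario:
    """Full parameterization of the split/admixture training demography.

    Sizes are diploid effective population sizes; times are in generations
    before present; ``mu`` and ``r`` are per-base-pair per-generation rates.
    Defaults are the standard human–Neanderthal training configuration.
    """

    N0: float = 10_000.0
    N1: float = 10_000.0
    N2: float = 10_000.0
    Na: float = 10_000.0
    m: float = 0.02
    T0: float = 12_000.0
    Ts: float = 2_500.0
    Ta: float = 2_000.0
    mu: float = 1.25e-8
    r: float = 1e-8
    length_bp: int = DEFAULT_LENGTH
    structure: tuple[StructureEvent, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.T0 > self.Ts > self.Ta > 0):
            raise ValueError(
                f"require T0 > Ts > Ta > 0, got T0={self.T0}, Ts={self.Ts}, Ta={self.Ta}"
            )
        for name in ("N0", "N1", "N2", "Na"):
            if getattr(self, name) <= 0:
                raise ValueError(f"population size {name} must be > 0")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"admixture fraction m must be in [0, 1], got {self.m}")
        if self.mu < 0 or self.r < 0:
            raise ValueError("mutation and recombination rates must be >= 0")
        if self.length_bp < 1:
            raise ValueError("length_bp must be >= 1")
        for ev in self.structure:
            if ev.population not in ("target", "ancestral"):
                raise ValueError(f"unknown structured population {ev.population!r}")
            if not 0.0 < ev.fraction < 1.0:
                raise ValueError("structure fraction must be in (0, 1)")
            if not ev.rejoin_time < ev.split_time:
                raise ValueError("structure rejoin_time must precede split_time")
            if ev.population == "target" and not (
                self.Ta < ev.rejoin_time < ev.split_time < self.Ts
            ):
                raise ValueError("target structure must lie strictly within (Ta, Ts)")
            if ev.population == "ancestral" and not (
                self.Ts < ev.rejoin_time < ev.split_time <= self.T0
            ):
                raise ValueError("ancestral structure must lie within (Ts, T0]")

    def replace(self, **kwargs) -> "DemographyScenario":
        """Return a copy with some fields replaced (re-validated)."""
        return dataclasses.replace(self, **kwargs)

    def perturb(self, param: str, factor: float) -> "DemographyScenario":
        """Scale a single demographic parameter by ``factor``.

        Raises ``ValueError`` if the perturbed model violates the time
        ordering or parameter-range constraints (the caller decides whether
        to skip such non-sensible combinations).
        """
        if param not in {"m", "N0", "N1", "N2", "Na", "T0", "Ts", "Ta", "mu", "r"}:
            raise ValueError(f"unknown demographic parameter {param!r}")
        return self.replace(**{param: getattr(self, param) * factor})


def table1_scenario(**overrides) -> DemographyScenario:
    """The human–Neanderthal training scenario (2% pulse 2,000 generations ago)."""
    return DemographyScenario(**overrides)


def make_structured_scenario(kind: str) -> DemographyScenario:
    """Confounder scenarios: transient structure with *no* archaic admixture.

    ``recent``: 25% of the target population is isolated from just after the
    target/reference split (2,499 generations ago) until just before the
    nominal admixture time (2,001 generations ago).  ``ancestral``: 25% of
    the ancestral population is isolated from 12,000 until 2,600 generations
    ago.  Both set ``m = 0`` so any archaic-looking signal is structure, not
    introgression.
    """
    if kind == "recent":
        ev = StructureEvent("target", split_time=2_499.0, rejoin_time=2_001.0, fraction=0.25)
    elif kind == "ancestral":
        ev = StructureEvent("ancestral", split_time=12_000.0, rejoin_time=2_600.0, fraction=0.25)
    else:
        raise ValueError(f"kind must be 'recent' or 'ancestral', got {kind!r}")
    return DemographyScenario(m=0.0, structure=(ev,))


@dataclass
class SimulatedRegion:
    """One simulated replicate: haplotypes, variant positions and true tracts.

    ``genotypes`` is a (haplotype x variant) 0/1 matrix with 1 = derived.
    ``tracts[i]`` lists the half-open, 0-based base-pair intervals of target
    haplotype ``i`` that descend from the archaic population.
    """

    positions: np.ndarray  # int64, sorted, within [0, length_bp)
    genotypes: np.ndarray  # uint8 (n_hap, n_sites)
    target: np.ndarray  # haplotype indices of the target panel
    reference: np.ndarray
    archaic: np.ndarray
    tracts: list[list[tuple[int, int]]]
    length_bp: int
    seed: int
    scenario: DemographyScenario = field(repr=False, default=None)

    @property
    def n_target(self) -> int:
        return len(self.target)

    def target_matrix(self) -> np.ndarray:
        return self.genotypes[self.target]

    def reference_matrix(self) -> np.ndarray:
        return self.genotypes[self.reference]

    def tract_mask(self, focal: int) -> np.ndarray:
        """Boolean archaic-ancestry indicator at each variant position for
        target haplotype ``focal``."""
        mask = np.zeros(len(self.positions), dtype=bool)
        for start, end in self.tracts[focal]:
            mask |= (self.positions >= start) & (self.positions < end)
        return mask


def _build_demography(scenario: DemographyScenario, census_time: float | None) -> msprime.Demography:
    dem = msprime.Demography()
    dem.add_population(name="target", initial_size=scenario.N2)
    dem.add_population(name="reference", initial_size=scenario.N1)
    dem.add_population(name="archaic", initial_size=scenario.Na)
    dem.add_population(name="mh", initial_size=scenario.N0)
    dem.add_population(name="root", initial_size=scenario.N0)

    ancestral_split_extra: list[str] = []
    for i, ev in enumerate(scenario.structure):
        deme = f"struct{i}"
        parent = "target" if ev.population == "target" else "mh"
        size = scenario.N2 if ev.population == "target" else scenario.N0
        dem.add_population(name=deme, initial_size=size)
        # Backward in time: lineages enter the deme at the (forward) rejoin
        # and merge back into the parent branch at the (forward) split.
        dem.add_mass_migration(
            time=ev.rejoin_time, source=parent, dest=deme, proportion=ev.fraction
        )
        if ev.population == "ancestral" and ev.split_time >= scenario.T0:
            ancestral_split_extra.append(deme)
        else:
            dem.add_population_split(time=ev.split_time, derived=[deme], ancestral=parent)

    if scenario.m > 0:
        dem.add_mass_migration(
            time=scenario.Ta, source="target", dest="archaic", proportion=scenario.m
        )
    if census_time is not None:
        dem.add_census(time=census_time)
    dem.add_population_split(time=scenario.Ts, derived=["target", "reference"], ancestral="mh")
    dem.add_population_split(
        time=scenario.T0,
        derived=["mh", "archaic"] + ancestral_split_extra,
        ancestral="root",
    )
    dem.sort_events()
    return dem


def _extract_tracts(
    ts, census_time: float, archaic_pop: int, n_target: int, length_bp: int
) -> list[list[tuple[int, int]]]:
    nodes = ts.tables.nodes
    census_nodes = np.where(
        (nodes.time == census_time) & (nodes.population == archaic_pop)
    )[0].astype(np.int32)
    tracts: list[list[tuple[int, int]]] = [[] for _ in range(n_target)]
    if len(census_nodes) == 0:
        return tracts
    samples = np.arange(n_target, dtype=np.int32)
    edges = ts.tables.link_ancestors(samples=samples, ancestors=census_nodes)
    per_hap: dict[int, list[tuple[float, float]]] = {}
    for left, right, child in zip(edges.left, edges.right, edges.child):
        per_hap.setdefault(int(child), []).append((left, right))
    for hap, ivals in per_hap.items():
        ivals.sort()
        merged: list[tuple[int, int]] = []
        cur_l, cur_r = ivals[0]
        for left, right in ivals[1:]:
            if left <= cur_r:
                cur_r = max(cur_r, right)
            else:
                merged.append((int(cur_l), int(cur_r)))
                cur_l, cur_r = left, right
        merged.append((int(cur_l), int(cur_r)))
        tracts[hap] = [(max(0, a), min(length_bp, b)) for a, b in merged]
    return tracts


def _integer_positions(float_positions: np.ndarray, length_bp: int) -> tuple[np.ndarray, np.ndarray]:
    """Map infinite-sites float coordinates to unique integer base pairs.

    Collided integers are shifted right to the next free base; sites pushed
    past the region end (vanishingly rare) are dropped.  Returns (positions,
    keep-mask over the original sites).
    """
    pos = np.floor(float_positions).astype(np.int64)
    keep = np.ones(len(pos), dtype=bool)
    for i in range(1, len(pos)):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    if len(pos):
        keep = pos < length_bp
    return pos[keep], keep


def simulate_region(
    scenario: DemographyScenario,
    n_target: int = 100,
    n_ref: int = 100,
    n_archaic: int = 1,
    seed: int | None = None,
    mutations: bool = True,
) -> SimulatedRegion:
    """Simulate one replicate and record true archaic ancestry tracts.

    The archaic haplotype(s) are sampled at the present, like the modern
    samples; their genotypes are carried in the region but are never used as
    classifier features.  ``seed`` is mandatory: every replicate must be
    reproducible.  With ``mutations=False`` only the ancestry (and hence the
    tracts) is generated, which is much faster when only labels are needed.
    """
    if seed is None:
        raise ValueError("a seed is required; simulations must be reproducible")
    if min(n_target, n_ref, n_archaic) < 0:
        raise ValueError("sample counts must be >= 0")
    scenario.validate()

    census_time = scenario.Ta + 0.5 * (scenario.Ts - scenario.Ta)
    dem = _build_demography(scenario, census_time)
    anc_seed, mut_seed = (
        np.random.SeedSequence(seed).generate_state(2, dtype=np.uint64) % (2**31 - 2) + 1
    )
    ts = msprime.sim_ancestry(
        samples=[
            msprime.SampleSet(n_target, population="target", ploidy=1),
            msprime.SampleSet(n_ref, population="reference", ploidy=1),
            msprime.SampleSet(n_archaic, population="archaic", ploidy=1),
        ],
        demography=dem,
        sequence_length=scenario.length_bp,
        recombination_rate=scenario.r,
        ploidy=2,
        random_seed=int(anc_seed),
    )
    archaic_pop = next(p.id for p in dem.populations if p.name == "archaic")
    tracts = _extract_tracts(ts, census_time, archaic_pop, n_target, scenario.length_bp)

    if mutations:
        mts = msprime.sim_mutations(
            ts,
            rate=scenario.mu,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=int(mut_seed),
        )
        float_pos = mts.tables.sites.position
        positions, keep = _integer_positions(float_pos, scenario.length_bp)
        genotypes = np.ascontiguousarray(mts.genotype_matrix()[keep].T.astype(np.uint8))
    else:
        positions = np.empty(0, dtype=np.int64)
        genotypes = np.empty((n_target + n_ref + n_archaic, 0), dtype=np.uint8)

    return SimulatedRegion(
        positions=positions,
        genotypes=genotypes,
        target=np.arange(n_target),
        reference=np.arange(n_target, n_target + n_ref),
        archaic=np.arange(n_target + n_ref, n_target + n_ref + n_archaic),
        tracts=tracts,
        length_bp=scenario.length_bp,
        seed=seed,
        scenario=scenario,
    )


def ancestry_fraction(
    region: SimulatedRegion, focal: int, interval: tuple[int, int] | None = None
) -> float:
    """Fraction of bases in ``interval`` (default: the whole region) that are
    archaic on target haplotype ``focal``."""
    if focal not in region.target:
        raise ValueError(f"haplotype {focal} is not in the target panel")
    if interval is None:
        interval = (0, region.length_bp)
    start, end = interval
    if not (0 <= start < end <= region.length_bp):
        raise ValueError(f"interval {interval} outside region bounds")
    overlap = 0
    for a, b in region.tracts[int(focal)]:
        overlap += max(0, min(b, end) - max(a, start))
    return overlap / (end - start)


def draw_rate_heterogeneity(
    mu_r_pairs: Sequence[tuple[float, float]], seed: int | None = None, rng=None
) -> tuple[float, float]:
    """Draw one (mu, r) pair uniformly from an empirical joint distribution.

    The pairing is preserved: mutation and recombination rates are drawn
    together, emulating joint local-rate variation along real genomes.
    """
    if len(mu_r_pairs) == 0:
        raise ValueError("mu_r_pairs must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(len(mu_r_pairs))
    mu, r = mu_r_pairs[idx]
    return float(mu), float(r)


def replicate_seeds(global_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent per-replicate seeds from one global seed."""
    ss = np.random.SeedSequence(global_seed)
    return ss.generate_state(n, dtype=np.uint64) % (2**31 - 2) + 1
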