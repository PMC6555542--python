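"""Simulator contracts: parameter validation, tract bookkeeping, coalescent scaling."""

import numpy as np
import pytest

from archaid.demography import (
    DemographyScenario,
    StructureEvent,
    ancestry_fraction,
    draw_rate_heterogeneity,
    make_structured_scenario,
    replicate_seeds,
    simulate_region,
)


class TestScenarioValidation:
    def test_defaults_match_training_configuration(self):
        sc = DemographyScenario()
        assert (sc.N0, sc.N1, sc.N2, sc.Na) == (10_000, 10_000, 10_000, 10_000)
        assert sc.m == 0.02
        assert (sc.T0, sc.Ts, sc.Ta) == (12_000, 2_500, 2_000)
        assert sc.mu == 1.25e-8 and sc.r == 1e-8

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"Ta": 3_000},  # Ta > Ts
            {"Ts": 13_000},  # Ts > T0
            {"N1": 0},
            {"m": 1.5},
            {"mu": -1e-8},
            {"length_bp": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DemographyScenario(**kwargs)

    def test_perturb_rejects_non_sensible_models(self):
        sc = DemographyScenario()
        with pytest.raises(ValueError):
            sc.perturb("Ta", 2.0)  # admixture after the target/reference split
        doubled = sc.perturb("Ts", 2.0)
        assert doubled.Ts == 5_000

    def test_structure_event_bounds(self):
        with pytest.raises(ValueError):
            DemographyScenario(
                structure=(StructureEvent("target", split_time=2_600, rejoin_time=2_100, fraction=0.25),)
            )


class TestStructuredScenarios:
    def test_recent_structure_parameters(self):
        sc = make_structured_scenario("recent")
        (ev,) = sc.structure
        assert (ev.split_time, ev.rejoin_time, ev.fraction) == (2_499, 2_001, 0.25)
        assert ev.population == "target"
        assert sc.m == 0.0

    def test_ancestral_structure_parameters(self):
        sc = make_structured_scenario("ancestral")
        (ev,) = sc.structure
        assert (ev.split_time, ev.rejoin_time) == (12_000, 2_600)
        assert sc.m == 0.0

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_structured_scenario("sideways")

    @pytest.mark.parametrize("kind", ["recent", "ancestral"])
    def test_structured_simulations_have_no_archaic_tracts(self, kind):
        sc = make_structured_scenario(kind)
        region = simulate_region(sc, n_target=20, n_ref=20, seed=7, mutations=False)
        assert all(len(t) == 0 for t in region.tracts)


class TestSimulateRegion:
    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError):
            simulate_region(DemographyScenario())

    def test_reproducible(self):
        a = simulate_region(DemographyScenario(), n_target=10, n_ref=10, seed=5)
        b = simulate_region(DemographyScenario(), n_target=10, n_ref=10, seed=5)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert a.tracts == b.tracts

    def test_region_invariants(self):
        region = simulate_region(DemographyScenario(m=0.1), seed=17)
        assert np.all(np.diff(region.positions) > 0)
        assert region.positions.min() >= 0 and region.positions.max() < region.length_bp
        counts = region.genotypes.sum(axis=0)
        assert np.all(counts >= 1) and np.all(counts < region.genotypes.shape[0])
        assert set(np.unique(region.genotypes)) <= {0, 1}
        for tract_list in region.tracts:
            for (a, b), nxt in zip(tract_list, tract_list[1:] + [None]):
                assert 0 <= a < b <= region.length_bp
                if nxt is not None:
                    assert b < nxt[0]  # sorted, non-overlapping

    def test_no_admixture_means_no_tracts(self):
        for seed in range(1, 21):
            region = simulate_region(
                DemographyScenario(m=0.0), n_target=20, n_ref=20, seed=seed, mutations=False
            )
            assert all(len(t) == 0 for t in region.tracts)

    def test_full_pulse_makes_everything_archaic(self):
        # With m = 1 every target lineage alive at Ta is archaic-derived.
        fracs = [
            ancestry_fraction(
                simulate_region(
                    DemographyScenario(m=1.0), n_target=10, n_ref=10, seed=s, mutations=False
                ),
                h,
            )
            for s in range(1, 6)
            for h in range(10)
        ]
        assert np.mean(fracs) > 0.999

    def test_mean_ancestry_fraction_matches_pulse(self):
        # Genome-wide mean archaic fraction over replicates ~ m = 2%.
        fracs = []
        for seed in replicate_seeds(99991, 400):
            region = simulate_region(
                DemographyScenario(), n_target=50, n_ref=0, n_archaic=0,
                seed=int(seed), mutations=False,
            )
            fracs.append(np.mean([ancestry_fraction(region, h) for h in range(50)]))
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.02) < 3 * se + 1e-4


class TestAncestryFraction:
    def _region_with_tracts(self, tracts, length=50_000):
        region = simulate_region(
            DemographyScenario(), n_target=2, n_ref=2, seed=1, mutations=False
        )
        region.tracts[0] = tracts
        return region

    def test_known_overlap(self):
        region = self._region_with_tracts([(10_000, 30_000)])
        assert ancestry_fraction(region, 0, (0, 50_000)) == pytest.approx(0.4)

    def test_empty_tracts(self):
        region = self._region_with_tracts([])
        assert ancestry_fraction(region, 0, (0, 50_000)) == 0.0

    def test_non_target_haplotype_rejected(self):
        region = self._region_with_tracts([])
        with pytest.raises(ValueError):
            ancestry_fraction(region, 3, (0, 50_000))

    def test_matches_per_base_enumeration(self, rng):
        length = 2_000
        region = simulate_region(
            DemographyScenario(length_bp=length), n_target=2, n_ref=2, seed=3, mutations=False
        )
        for _ in range(20):
            k = rng.integers(0, 4)
            edges = np.sort(rng.choice(length, size=2 * k, replace=False))
            tracts = [(int(edges[2 * i]), int(edges[2 * i + 1])) for i in range(k)]
            region.tracts[0] = tracts
            a, b = sorted(rng.choice(length, size=2, replace=False).tolist())
            base = np.zeros(length, dtype=bool)
            for lo, hi in tracts:
                base[lo:hi] = True
            expected = base[a:b].mean()
            assert ancestry_fraction(region, 0, (a, b)) == pytest.approx(expected)


def _structured_coalescent_tree_length(rng, scenario, n_target, n_ref, n_archaic):
    """Independent single-locus oracle: total branch length (generations)
    under the split/admixture model, simulated directly from the exponential
    waiting-time construction of the structured coalescent."""
    pops = {
        "target": [0.0] * n_target,
        "reference": [0.0] * n_ref,
        "archaic": [0.0] * n_archaic,
    }
    sizes = {"target": scenario.N2, "reference": scenario.N1, "archaic": scenario.Na}
    events = [(scenario.Ta, "pulse"), (scenario.Ts, "split"), (scenario.T0, "root")]
    t = 0.0
    total = 0.0
    while sum(len(v) for v in pops.values()) > 1:
        rates = {p: len(v) * (len(v) - 1) / 2 / (2 * sizes[p]) for p, v in pops.items()}
        rate = sum(rates.values())
        wait = rng.exponential(1 / rate) if rate > 0 else np.inf
        next_event = events[0][0] if events else np.inf
        if t + wait < next_event:
            t += wait
            p = rng.choice(list(rates), p=np.array(list(rates.values())) / rate)
            pair = rng.choice(len(pops[p]), size=2, replace=False)
            for i in sorted(pair, reverse=True):
                total += t - pops[p].pop(i)
            pops[p].append(t)
        else:
            t, kind = events.pop(0)
            if kind == "pulse":
                movers = [i for i in range(len(pops["target"])) if rng.random() < scenario.m]
                for i in sorted(movers, reverse=True):
                    pops["archaic"].append(pops["target"].pop(i))
            elif kind == "split":
                pops["target"].extend(pops.pop("reference"))
                sizes["target"] = scenario.N0
                sizes.pop("reference")
            else:
                pops["target"].extend(pops.pop("archaic"))
                sizes.pop("archaic")
    return total  # the MRCA itself carries no branch length


class TestCoalescentScaling:
    def test_pairwise_diversity_closed_form(self):
        # With all sizes equal and m = 0, two target lineages coalesce at
        # rate 1/(2N) throughout, so E[pairwise differences] = 4 N mu L.
        sc = DemographyScenario(m=0.0)
        diffs = []
        for seed in replicate_seeds(2024, 300):
            region = simulate_region(sc, n_target=2, n_ref=0, n_archaic=0, seed=int(seed))
            diffs.append(int(region.genotypes.sum()))  # n=2: every site is a difference
        diffs = np.asarray(diffs, dtype=float)
        expected = 4 * sc.N0 * sc.mu * sc.length_bp
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - expected) < 3 * se

    def test_segregating_sites_match_structured_coalescent_oracle(self, rng):
        # Small sample for speed; oracle re-simulates the same demography
        # from first principles without msprime.
        sc = DemographyScenario(length_bp=20_000, r=0.0)
        n_t, n_r, n_a = 10, 10, 1
        seg = [
            len(simulate_region(sc, n_target=n_t, n_ref=n_r, n_archaic=n_a, seed=int(s)).positions)
            for s in replicate_seeds(31337, 400)
        ]
        oracle_totals = [
            _structured_coalescent_tree_length(rng, sc, n_t, n_r, n_a) for _ in range(400)
        ]
        seg = np.asarray(seg, dtype=float)
        expected = sc.mu * sc.length_bp * np.mean(oracle_totals)
        se_impl = seg.std(ddof=1) / np.sqrt(len(seg))
        se_oracle = sc.mu * sc.length_bp * np.std(oracle_totals, ddof=1) / np.sqrt(len(oracle_totals))
        tol = 3 * np.hypot(se_impl, se_oracle)
        assert abs(seg.mean() - expected) < tol


class TestRateHeterogeneity:
    def test_single_pair(self):
        assert draw_rate_heterogeneity([(1.25e-8, 1e-8)], seed=1) == (1.25e-8, 1e-8)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            draw_rate_heterogeneity([], seed=1)

    def test_uniform_and_joint(self):
        pairs = [(1e-8, 1e-8), (2e-8, 5e-9), (3e-8, 2e-8), (4e-8, 1e-9)]
        rng = np.random.default_rng(0)
        draws = [draw_rate_heterogeneity(pairs, rng=rng) for _ in range(4_000)]
        assert set(draws) == set(pairs)  # pairing preserved, never mixed
        freqs = [draws.count(p) / len(draws) for p in pairs]
        assert np.allclose(freqs, 0.25, atol=0.03)

    def test_seeded_draws_reproducible(self):
        pairs = [(1e-8, 1e-8), (2e-8, 5e-9)]
        a = [draw_rate_heterogeneity(pairs, seed=s) for s in range(20)]
        b = [draw_rate_heterogeneity(pairs, seed=s) for s in range(20)]
        assert a == b
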