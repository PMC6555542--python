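"""Text formats: ms-style haplotypes, tract sidecars, feature tables, VCF.

Simulated replicates round-trip through the classic ms text layout
(``//`` record separator, ``segsites:``, ``positions:`` as fractions of the
region length, one 0/1 row per haplotype) plus a BED-like sidecar of true
archaic tracts (replicate, haplotype, start, end; 0-based half-open).
Empirical data enters as phased biallelic VCF with derived-allele polarity
taken from the ``AA`` INFO tag; sites without a usable ancestral allele are
dropped (and counted).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .demography import DemographyScenario, SimulatedRegion

logger = logging.getLogger(__name__)

__all__ = [
    "write_ms",
    "read_ms",
    "write_tracts",
    "read_tracts",
    "write_features",
    "read_features",
    "read_phased_vcf",
    "scenario_to_dict",
    "scenario_from_dict",
]

_POS_DIGITS = 10


def write_ms(regions: list[SimulatedRegion], path) -> None:
    """Write replicates in ms-style text (positions as fractions of length)."""
    with open(path, "w") as fh:
        first = regions[0]
        n_hap = first.genotypes.shape[0]
        fh.write(f"ms {n_hap} {len(regions)} -L {first.length_bp}\n")
        fh.write(" ".join(str(r.seed) for r in regions) + "\n")
        for region in regions:
            fh.write("\n//\n")
            fh.write(f"segsites: {len(region.positions)}\n")
            fracs = region.positions / region.length_bp
            fh.write("positions: " + " ".join(f"{p:.{_POS_DIGITS}f}" for p in fracs) + "\n")
            for row in region.genotypes:
                fh.write("".join("1" if g else "0" for g in row) + "\n")


def read_ms(
    path, length_bp: int, n_target: int = 100, n_ref: int = 100
) -> list[SimulatedRegion]:
    """Read ms-style text back into regions (tracts empty; see read_tracts)."""
    regions: list[SimulatedRegion] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        seg = int(lines[i + 1].split(":")[1])
        if seg > 0:
            fracs = np.asarray(lines[i + 2].split(":")[1].split(), dtype=float)
            positions = np.round(fracs * length_bp).astype(np.int64)
            rows = []
            j = i + 3
            while j < len(lines) and lines[j].strip() and not lines[j].startswith("//"):
                rows.append([int(c) for c in lines[j].strip()])
                j += 1
            genotypes = np.asarray(rows, dtype=np.uint8)
        else:
            positions = np.empty(0, dtype=np.int64)
            j = i + 2
            while j < len(lines) and lines[j].strip() and not lines[j].startswith("//"):
                j += 1
            genotypes = np.empty((n_target + n_ref, 0), dtype=np.uint8)
        n_hap = genotypes.shape[0]
        n_archaic = n_hap - n_target - n_ref
        regions.append(
            SimulatedRegion(
                positions=positions,
                genotypes=genotypes,
                target=np.arange(n_target),
                reference=np.arange(n_target, n_target + n_ref),
                archaic=np.arange(n_target + n_ref, n_hap),
                tracts=[[] for _ in range(n_target)],
                length_bp=length_bp,
                seed=-1,
            )
        )
        i = j
    return regions


def write_tracts(regions: list[SimulatedRegion], path) -> None:
    """BED-like sidecar of true archaic tracts: replicate, hap, start, end."""
    with open(path, "w") as fh:
        fh.write("replicate\thaplotype\tstart\tend\n")
        for rep, region in enumerate(regions):
            for hap, tract_list in enumerate(region.tracts):
                for start, end in tract_list:
                    fh.write(f"{rep}\t{hap}\t{start}\t{end}\n")


def read_tracts(path, regions: list[SimulatedRegion]) -> None:
    """Attach tracts from a sidecar file to regions read via read_ms."""
    df = pd.read_csv(path, sep="\t")
    for rep, hap, start, end in df.itertuples(index=False):
        regions[rep].tracts[hap].append((int(start), int(end)))


def write_features(X: np.ndarray, names: list[str], path, fractions=None) -> None:
    """Headered TSV feature table; optional true ancestry-fraction column."""
    df = pd.DataFrame(X, columns=names)
    if fractions is not None:
        df.insert(0, "ancestry_fraction", fractions)
    df.to_csv(path, sep="\t", index=False)


def read_features(path) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    df = pd.read_csv(path, sep="\t")
    fractions = None
    if "ancestry_fraction" in df.columns:
        fractions = df.pop("ancestry_fraction").to_numpy()
    return df.to_numpy(dtype=float), list(df.columns), fractions


def read_phased_vcf(path, max_sites: int | None = None):
    """Read phased biallelic SNVs with ancestral-allele polarity from a VCF.

    Returns (positions, haplotype matrix with 1 = derived, sample names).
    Sites that are not biallelic SNVs, are unphased, or lack an ``AA`` INFO
    allele matching REF or ALT are dropped and counted in the log.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions, rows = [], []
    dropped = 0
    for variant in vcf:
        if max_sites is not None and len(positions) >= max_sites:
            break
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            dropped += 1
            continue
        aa = (variant.INFO.get("AA") or "").split("|")[0].strip().upper()
        if aa == variant.REF.upper():
            derived_is_alt = True
        elif aa == variant.ALT[0].upper():
            derived_is_alt = False
        else:
            dropped += 1
            continue
        gts = variant.genotype.array()
        if np.any(gts[:, :2] < 0) or not np.all(gts[:, 2] == 1):
            dropped += 1  # missing or unphased
            continue
        haps = gts[:, :2].reshape(-1)
        rows.append(haps if derived_is_alt else 1 - haps)
        positions.append(variant.POS - 1)  # 0-based
    if dropped:
        logger.info("read_phased_vcf: dropped %d unusable sites", dropped)
    if not rows:
        return np.empty(0, dtype=np.int64), np.empty((2 * len(samples), 0), np.uint8), samples
    matrix = np.asarray(rows, dtype=np.uint8).T
    return np.asarray(positions, dtype=np.int64), matrix, samples


_SCENARIO_FIELDS = ("N0", "N1", "N2", "Na", "m", "T0", "Ts", "Ta", "mu", "r", "length_bp")


def scenario_to_dict(scenario: DemographyScenario) -> dict:
    d = {k: getattr(scenario, k) for k in _SCENARIO_FIELDS}
    d["structure"] = [
        {
            "population": ev.population,
            "split_time": ev.split_time,
            "rejoin_time": ev.rejoin_time,
            "fraction": ev.fraction,
        }
        for ev in scenario.structure
    ]
    return d


def scenario_from_dict(d: dict) -> DemographyScenario:
    from .demography import StructureEvent

    kwargs = {k: d[k] for k in _SCENARIO_FIELDS if k in d}
    if "length_bp" in kwargs:
        kwargs["length_bp"] = int(kwargs["length_bp"])
    structure = tuple(StructureEvent(**ev) for ev in d.get("structure", []))
    return DemographyScenario(structure=structure, **kwargs)
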