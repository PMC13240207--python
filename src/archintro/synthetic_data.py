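"""Synthetic inputs with the statistical structure the pipeline assumes.

The panel simulator is a deterministic mosaic/mutation-drop model, not a
full coalescent: modern haplotypes draw derived alleles from a shared
neutral variant pool (derived count i with probability ∝ 1/i), archaic
pseudo-genomes carry an excess of lineage-private derived alleles, and
carrier haplotypes are archaic-derived inside a planted tract whose
per-side genetic length is Exponential(mean 100/g cM) — the standard
post-admixture recombination clock, and the same model the ILS survival
test assumes, which gives an internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from archintro.core_io import (
    ARCHAIC,
    HET,
    MODERN_CARRIER,
    MODERN_NONCARRIER,
    GeneticMap,
    HaplotypePanel,
    RegionMask,
    VariantSite,
)
from archintro.kinetics import KineticDataset, velocity

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs for the panel simulator; identical seeds give identical output."""

    n_modern_haplotypes: int = 40
    n_archaic_genomes: int = 3
    region_length: int = 400_000
    region_start: int = 1
    chrom: str = "chr8"
    mutation_density: float = 0.8  # expected modern segregating sites per kb
    divergence_scale: float = 2.0  # archaic-shared private-variant enrichment
    archaic_private_scale: float = 0.3  # per-archaic private density, × archaic density
    admixture_generations: float = 2000.0
    recombination_rate: float = 1.0  # cM per Mb, uniform
    carrier_fraction: float = 0.15
    archaic_het_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modern_haplotypes < 2 or self.n_modern_haplotypes % 2:
            raise ValueError("n_modern_haplotypes must be an even count >= 2")
        if self.n_archaic_genomes < 1:
            raise ValueError("need at least one archaic genome")
        if self.region_length < 1:
            raise ValueError("region_length must be positive")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must lie in [0, 1]")
        if self.admixture_generations <= 0:
            raise ValueError("admixture_generations must be positive")
        if self.recombination_rate <= 0 or self.mutation_density <= 0:
            raise ValueError("rates must be positive")


@dataclass
class TruthRecord:
    """Ground truth of a simulation: who carries the tract, and where it is."""

    carrier_haplotypes: list[str]
    tract_start: int  # 1-based inclusive, 0/0 when no tract planted
    tract_end: int
    tract_cM: float
    source_archaic: str | None = None
    seed: int | None = None

    @property
    def tract_span_bp(self) -> int:
        return max(self.tract_end - self.tract_start, 0)


class SimulatedPanel(NamedTuple):
    panel: HaplotypePanel
    genetic_map: GeneticMap
    mask: RegionMask
    truth: TruthRecord


def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Simulate a phased modern panel with archaic pseudo-genomes and,
    optionally, a planted introgressed tract shared by the carriers.

    The tract is centred on the region midpoint; each side's genetic length
    is Exponential(mean 100/g cM), converted to bp through the uniform
    recombination rate and clipped to the region. Inside the tract carrier
    haplotypes copy the source archaic (first archaic) and drop their
    modern-pool alleles; outside it they are ordinary modern background.
    """
    rng = np.random.default_rng(config.seed)
    L = config.region_length
    start = config.region_start
    n_mod = config.n_modern_haplotypes
    n_arch = config.n_archaic_genomes

    n_pool = rng.poisson(config.mutation_density * L / 1000.0)
    arch_density = config.mutation_density * config.divergence_scale
    n_shared = rng.poisson(arch_density * L / 1000.0)
    n_private = rng.poisson(
        arch_density * config.archaic_private_scale * L / 1000.0, size=n_arch
    )

    n_carriers = round(config.carrier_fraction * n_mod)
    if n_carriers > 0 and n_shared + n_private[0] == 0:
        raise ValueError("carrier_fraction > 0 but the simulation drew zero archaic variants")

    total = n_pool + n_shared + int(n_private.sum())
    if total > L:
        raise ValueError("mutation densities draw more variants than region positions")
    all_pos = np.sort(rng.choice(L, size=total, replace=False)) + start
    perm = rng.permutation(total)

    carrier_rows = np.sort(rng.choice(n_mod, size=n_carriers, replace=False))
    modern_ids = [f"mod{j // 2:03d}_{j % 2 + 1}" for j in range(n_mod)]
    archaic_ids = [f"arch{a}" for a in range(n_arch)]

    # planted tract
    g = config.admixture_generations
    if n_carriers > 0:
        center = start + L // 2
        side_cM = rng.exponential(100.0 / g, size=2)
        side_bp = np.maximum((side_cM / config.recombination_rate * 1e6).round(), 1).astype(
            np.int64
        )
        tract_start = max(start, center - int(side_bp[0]))
        tract_end = min(start + L - 1, center + int(side_bp[1]))
    else:
        rng.exponential(100.0 / g, size=2)  # keep the stream aligned across configs
        tract_start = tract_end = 0

    sites_pos = all_pos  # already sorted
    kind = np.empty(total, dtype=np.int64)  # -1 pool, -2 shared, a>=0 private to archaic a
    kind[perm[:n_pool]] = -1
    kind[perm[n_pool : n_pool + n_shared]] = -2
    offset = n_pool + n_shared
    for a in range(n_arch):
        kind[perm[offset : offset + n_private[a]]] = a
        offset += n_private[a]

    A = np.zeros((n_mod + n_arch, total), dtype=np.int8)
    in_tract = (sites_pos >= tract_start) & (sites_pos <= tract_end) if n_carriers else (
        np.zeros(total, dtype=bool)
    )

    # modern variant pool: derived count from the neutral SFS (P(i) ∝ 1/i)
    pool_cols = np.flatnonzero(kind == -1)
    if n_mod > 1 and pool_cols.size:
        counts = np.arange(1, n_mod)
        sfs = (1.0 / counts) / np.sum(1.0 / counts)
        derived_counts = rng.choice(counts, size=pool_cols.size, p=sfs)
        for j, dc in zip(pool_cols, derived_counts):
            rows = rng.choice(n_mod, size=dc, replace=False)
            A[rows, j] = 1

    shared_cols = np.flatnonzero(kind == -2)
    A[np.ix_(np.arange(n_mod, n_mod + n_arch), shared_cols)] = 1
    for a in range(n_arch):
        A[n_mod + a, kind == a] = 1

    if n_carriers:
        tract_cols = np.flatnonzero(in_tract)
        # carriers copy the source archaic inside the tract
        A[np.ix_(carrier_rows, tract_cols)] = A[n_mod, tract_cols][None, :]

    # archaic heterozygosity (unphased genotype ambiguity on the pseudo-haplotype)
    if config.archaic_het_rate > 0:
        het = rng.random((n_arch, total)) < config.archaic_het_rate
        for a in range(n_arch):
            A[n_mod + a, het[a]] = HET

    ref = _BASES[rng.integers(0, 4, size=total)]
    alt = np.array([_BASES[(np.flatnonzero(_BASES == r)[0] + rng.integers(1, 4)) % 4]
                    for r in ref])
    sites = [
        VariantSite(
            chrom=config.chrom,
            pos=int(p),
            id=f"site{j}",
            ref_allele=str(ref[j]),
            alt_allele=str(alt[j]),
            ancestral_state="ref",
        )
        for j, p in enumerate(sites_pos)
    ]

    groups = [
        MODERN_CARRIER if j in set(carrier_rows.tolist()) else MODERN_NONCARRIER
        for j in range(n_mod)
    ] + [ARCHAIC] * n_arch
    panel = HaplotypePanel(
        haplotype_ids=modern_ids + archaic_ids,
        alleles=A,
        sites=sites,
        group_labels=groups,
    )

    gmap = GeneticMap(
        positions=np.array([start, start + L - 1], dtype=np.float64),
        cumulative_cM=np.array(
            [0.0, (L - 1) * config.recombination_rate / 1e6], dtype=np.float64
        ),
        chrom=config.chrom,
    )
    mask = RegionMask({config.chrom: np.array([[start - 1, start + L - 1]])})

    if n_carriers:
        tract_cM = float(gmap.cm_between(tract_start, tract_end))
    else:
        tract_cM = 0.0
    truth = TruthRecord(
        carrier_haplotypes=[modern_ids[j] for j in carrier_rows],
        tract_start=int(tract_start),
        tract_end=int(tract_end),
        tract_cM=tract_cM,
        source_archaic=archaic_ids[0] if n_carriers else None,
        seed=config.seed,
    )
    return SimulatedPanel(panel=panel, genetic_map=gmap, mask=mask, truth=truth)


def simulate_fragments(n: int, mean_cM: float, seed: int | None = None) -> np.ndarray:
    """i.i.d. Exponential fragment genetic lengths (cM)."""
    if n < 1:
        raise ValueError(f"need n >= 1 fragments, got {n}")
    if mean_cM <= 0:
        raise ValueError(f"mean length must be positive, got {mean_cM}")
    return np.random.default_rng(seed).exponential(mean_cM, size=n)


def simulate_kinetic_dataset(
    model: str,
    params: dict,
    S_grid: Sequence[float] | np.ndarray,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int | None = None,
    condition: str = "synthetic",
) -> KineticDataset:
    """Noisy dose-response table: model(S) plus i.i.d. Gaussian noise per replicate."""
    S = np.asarray(S_grid, dtype=np.float64)
    if np.any(S < 0):
        raise ValueError("substrate concentrations must be >= 0")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    clean = velocity(model, S, params)
    rng = np.random.default_rng(seed)
    rows_S, rows_v, rows_r = [], [], []
    for r in range(replicates):
        noise = rng.normal(0.0, noise_sd, size=S.size) if noise_sd > 0 else 0.0
        rows_S.append(S)
        rows_v.append(clean + noise)
        rows_r.append(np.full(S.size, r, dtype=np.int64))
    return KineticDataset(
        condition=condition,
        S=np.concatenate(rows_S),
        velocity=np.concatenate(rows_v),
        replicate=np.concatenate(rows_r),
    )


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "carrier_haplotype": truth.carrier_haplotypes or ["."],
            "tract_start": truth.tract_start,
            "tract_end": truth.tract_end,
            "tract_cM": truth.tract_cM,
            "source_archaic": truth.source_archaic or ".",
            "seed": truth.seed if truth.seed is not None else ".",
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> TruthRecord:
    df = pd.read_csv(path, sep="\t")
    carriers = [c for c in df["carrier_haplotype"].astype(str) if c != "."]
    src = str(df["source_archaic"].iloc[0])
    seed = df["seed"].iloc[0]
    return TruthRecord(
        carrier_haplotypes=carriers,
        tract_start=int(df["tract_start"].iloc[0]),
        tract_end=int(df["tract_end"].iloc[0]),
        tract_cM=float(df["tract_cM"].iloc[0]),
        source_archaic=None if src == "." else src,
        seed=None if str(seed) == "." else int(seed),
    )
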