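"""Haplotypic r² and LD-defined haplotype-block boundary calling.

A block around a focal variant is delimited by the outermost variants, on
each side and within a finite search window, whose haplotypic r² with the
focal variant strictly exceeds a threshold (internal dips below the
threshold are tolerated). LD is computed on phased modern haplotypes by
default; archaic pseudo-haplotypes are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from archintro.core_io import (
    MODERN_CARRIER,
    MODERN_NONCARRIER,
    GeneticMap,
    HaplotypePanel,
    VariantSite,
)

DEFAULT_R2_THRESHOLD = 0.8
DEFAULT_MAX_WINDOW_BP = 1_000_000

MODERN_GROUPS = (MODERN_CARRIER, MODERN_NONCARRIER)


class MonomorphicSiteError(ValueError):
    """r² is undefined against a monomorphic allele column."""


@dataclass
class LDProfile:
    """Per-site r² of every polymorphic variant in the window with the focal variant."""

    focal_site: VariantSite
    entries: list[tuple[int, float]] = field(default_factory=list)  # (pos, r²)

    def to_rows(self) -> list[dict]:
        return [
            {"chrom": self.focal_site.chrom, "pos": pos, "r2": r2}
            for pos, r2 in self.entries
        ]


@dataclass
class HaplotypeBlock:
    """LD-defined block: focal variant plus upstream/downstream boundary variants."""

    focal_site: VariantSite
    upstream_boundary: VariantSite
    downstream_boundary: VariantSite
    threshold: float
    profile: LDProfile | None = None
    genetic_length_cM: float | None = None

    def __post_init__(self) -> None:
        if not (
            self.upstream_boundary.pos <= self.focal_site.pos <= self.downstream_boundary.pos
        ):
            raise ValueError("block boundaries must bracket the focal site")

    @property
    def span_bp(self) -> int:
        return self.downstream_boundary.pos - self.upstream_boundary.pos

    @property
    def span_kb(self) -> int:
        """Span rounded to the nearest kilobase (as reported)."""
        return round(self.span_bp / 1000)

    def to_dict(self) -> dict:
        return {
            "chrom": self.focal_site.chrom,
            "focal_pos": self.focal_site.pos,
            "upstream_pos": self.upstream_boundary.pos,
            "downstream_pos": self.downstream_boundary.pos,
            "span_bp": self.span_bp,
            "span_kb": self.span_kb,
            "threshold": self.threshold,
            "genetic_length_cM": self.genetic_length_cM,
        }


def r_squared(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Haplotypic r²: squared Pearson correlation of phased allele indicators.

    Raises :class:`MonomorphicSiteError` when either column is monomorphic
    (r² is undefined there, which is distinct from 0).
    """
    a = np.asarray(hap_a, dtype=np.float64)
    b = np.asarray(hap_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("allele columns must be 1-D and equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("allele columns must be missing-free")
    pa, pb = a.mean(), b.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va == 0 or vb == 0:
        raise MonomorphicSiteError("monomorphic allele column")
    d = (a * b).mean() - pa * pb
    return float(d * d / (va * vb))


def ld_profile(
    panel: HaplotypePanel,
    focal_pos: int,
    max_window_bp: int = DEFAULT_MAX_WINDOW_BP,
    groups: tuple[str, ...] = MODERN_GROUPS,
) -> LDProfile:
    """r² of the focal variant with every polymorphic variant within the window.

    Monomorphic columns (within the selected haplotype groups) are skipped:
    their r² is undefined rather than zero.
    """
    focal_idx = panel.site_index(focal_pos)
    rows = panel.indices_for(*groups)
    if rows.size < 2:
        raise ValueError("need at least two haplotypes in the selected groups")
    X = panel.alleles[rows, :].astype(np.float64)
    if np.any(X < 0):
        raise ValueError("panel has missing/het calls; run filter_sites first")

    focal = X[:, focal_idx]
    if focal.min() == focal.max():
        raise MonomorphicSiteError(
            f"focal site at {focal_pos} is monomorphic in the selected groups"
        )
    positions = panel.positions
    in_window = np.abs(positions - focal_pos) <= max_window_bp

    p = X.mean(axis=0)
    var = p * (1 - p)
    pf = focal.mean()
    cov = (X * focal[:, None]).mean(axis=0) - p * pf
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = cov * cov / (var * (pf * (1 - pf)))

    entries = [
        (int(positions[j]), float(r2[j]))
        for j in np.flatnonzero(in_window & (var > 0))
    ]
    return LDProfile(focal_site=panel.sites[focal_idx], entries=entries)


def call_block(
    panel: HaplotypePanel,
    focal_pos: int,
    threshold: float = DEFAULT_R2_THRESHOLD,
    max_window_bp: int = DEFAULT_MAX_WINDOW_BP,
    groups: tuple[str, ...] = MODERN_GROUPS,
) -> HaplotypeBlock:
    """Call the haplotype block around a focal variant.

    Boundaries are the outermost variants within ``max_window_bp`` whose r²
    with the focal variant strictly exceeds ``threshold``; when no variant
    qualifies on a side the boundary collapses to the focal site (so an
    unlinked focal variant yields a zero-span block).
    """
    profile = ld_profile(panel, focal_pos, max_window_bp=max_window_bp, groups=groups)
    focal_site = profile.focal_site

    up = down = focal_site
    for pos, r2 in profile.entries:
        if r2 > threshold:
            if pos < up.pos:
                up = panel.sites[panel.site_index(pos)]
            if pos > down.pos:
                down = panel.sites[panel.site_index(pos)]
    return HaplotypeBlock(
        focal_site=focal_site,
        upstream_boundary=up,
        downstream_boundary=down,
        threshold=threshold,
        profile=profile,
    )


def block_genetic_length(block: HaplotypeBlock, gmap: GeneticMap) -> float:
    """Genetic length of a block in cM by linear interpolation of the map.

    Both boundaries must lie inside the map range; no extrapolation.
    """
    length = gmap.cm_between(block.upstream_boundary.pos, block.downstream_boundary.pos)
    block.genetic_length_cM = length
    return length
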