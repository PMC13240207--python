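"""Tajima's D and sliding-window neutrality scans.

D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)) with the 1989 constants computed
from the haplotype count n. pi is evaluated from the site-frequency form
sum_j 2 p_j (1 - p_j) * n/(n-1), which equals the mean pairwise difference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from archintro.core_io import HaplotypePanel


@dataclass(frozen=True)
class TajimaConstants:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """The 1989 normalizing constants for a sample of n sequences."""
    if n < 2:
        raise ValueError(f"need at least 2 sequences, got {n}")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class TajimaResult:
    n: int
    S: int
    pi: float
    constants: TajimaConstants
    D: float
    defined: bool

    def __post_init__(self) -> None:
        if self.S < 0 or self.pi < 0:
            raise ValueError("S and pi must be nonnegative")


def tajimas_d(alleles: np.ndarray | HaplotypePanel) -> TajimaResult:
    """Tajima's D over a missing-free biallelic 0/1 matrix (haplotypes × sites).

    Monomorphic columns contribute nothing (S counts segregating sites
    only). D is flagged undefined when S = 0 or the variance term vanishes.
    """
    if isinstance(alleles, HaplotypePanel):
        alleles = alleles.alleles
    X = np.asarray(alleles)
    if X.ndim != 2:
        raise ValueError("allele matrix must be 2-D")
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 haplotypes, got {n}")
    if np.any(X < 0):
        raise ValueError("allele matrix must be missing-free")

    const = tajima_constants(n)
    p = X.mean(axis=0)
    seg = (p > 0) & (p < 1)
    S = int(np.count_nonzero(seg))
    pi = float(np.sum(2.0 * p[seg] * (1.0 - p[seg])) * n / (n - 1))

    var = const.e1 * S + const.e2 * S * (S - 1)
    if S == 0 or var <= 0:
        return TajimaResult(n=n, S=S, pi=pi, constants=const, D=math.nan, defined=False)
    D = (pi - S / const.a1) / math.sqrt(var)
    return TajimaResult(n=n, S=S, pi=pi, constants=const, D=D, defined=True)


@dataclass
class WindowTrack:
    """Per-step-position averaged D over all covering windows."""

    positions: np.ndarray
    values: np.ndarray  # NaN where no covering window had a defined D
    window_bp: int
    step_bp: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pos": self.positions, "D": self.values})


def sliding_tajima(
    panel: HaplotypePanel,
    region: tuple[int, int] | None = None,
    window: int = 10_000,
    step: int = 100,
    unit: str = "bp",
) -> WindowTrack:
    """Sliding-window Tajima's D with per-step averaging of overlapping windows.

    Windows of ``window`` bp start on the step grid; each grid position's
    value is the mean D over every window that covers it, windows with
    undefined D excluded. ``unit="sites"`` instead slides over site counts
    (``window``/``step`` then measured in segregating sites).
    """
    if unit not in ("bp", "sites"):
        raise ValueError("unit must be 'bp' or 'sites'")
    if step < 1 or window < 1:
        raise ValueError("window and step must be positive")
    n = panel.n_haplotypes
    if n < 2:
        raise ValueError("need at least 2 haplotypes")

    positions = panel.positions
    if region is None:
        if positions.size == 0:
            raise ValueError("empty panel and no region given")
        region = (int(positions.min()), int(positions.max()))
    start, end = region
    if window > (end - start + 1) and unit == "bp":
        raise ValueError("window larger than scan region")

    X = panel.alleles
    if np.any(X < 0):
        raise ValueError("panel must be missing-free; run filter_sites first")
    p = X.mean(axis=0)
    seg = (p > 0) & (p < 1)
    const = tajima_constants(n)

    if unit == "sites":
        return _sliding_by_sites(positions, p, seg, const, n, window, step)

    # prefix sums over sites ordered by position: S and pi contributions
    contrib = np.where(seg, 2.0 * p * (1.0 - p) * n / (n - 1), 0.0)
    cum_pi = np.concatenate([[0.0], np.cumsum(contrib)])
    cum_s = np.concatenate([[0], np.cumsum(seg.astype(np.int64))])

    starts = np.arange(start, end - window + 2, step, dtype=np.int64)
    if starts.size == 0:
        starts = np.array([start], dtype=np.int64)
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, starts + window - 1, side="right")
    S_w = cum_s[hi] - cum_s[lo]
    pi_w = cum_pi[hi] - cum_pi[lo]

    var = const.e1 * S_w + const.e2 * S_w * (S_w - 1.0)
    defined = (S_w > 0) & (var > 0)
    D_w = np.full(starts.size, np.nan)
    with np.errstate(invalid="ignore"):
        D_w[defined] = (pi_w[defined] - S_w[defined] / const.a1) / np.sqrt(var[defined])

    if not np.any(defined):
        warnings.warn("no window with polymorphism; empty track", stacklevel=2)

    # per-step-grid averaging: grid position i is covered by window k iff
    # k <= i < k + window/step (window starts share the step grid)
    grid = np.arange(start, end + 1, step, dtype=np.int64)
    span = max(1, -(-window // step))  # ceil
    vals = np.where(defined, D_w, 0.0)
    cnts = defined.astype(np.float64)
    csum_v = np.concatenate([[0.0], np.cumsum(vals)])
    csum_c = np.concatenate([[0.0], np.cumsum(cnts)])
    out = np.full(grid.size, np.nan)
    for gi in range(grid.size):
        k_hi = min(gi, starts.size - 1)
        k_lo = max(0, gi - span + 1)
        if k_lo > k_hi:
            continue
        c = csum_c[k_hi + 1] - csum_c[k_lo]
        if c > 0:
            out[gi] = (csum_v[k_hi + 1] - csum_v[k_lo]) / c
    return WindowTrack(positions=grid, values=out, window_bp=window, step_bp=step)


def _sliding_by_sites(positions, p, seg, const, n, window, step) -> WindowTrack:
    seg_idx = np.flatnonzero(seg)
    if seg_idx.size < window:
        warnings.warn("fewer segregating sites than window; empty track", stacklevel=2)
        return WindowTrack(
            positions=np.array([], dtype=np.int64),
            values=np.array([]),
            window_bp=window,
            step_bp=step,
        )
    contrib = 2.0 * p[seg_idx] * (1.0 - p[seg_idx]) * n / (n - 1)
    mids, values = [], []
    for lo in range(0, seg_idx.size - window + 1, step):
        sl = slice(lo, lo + window)
        S = window
        pi = float(contrib[sl].sum())
        var = const.e1 * S + const.e2 * S * (S - 1)
        D = (pi - S / const.a1) / math.sqrt(var) if var > 0 else math.nan
        mids.append(int(positions[seg_idx[lo + window // 2]]))
        values.append(D)
    return WindowTrack(
        positions=np.array(mids, dtype=np.int64),
        values=np.array(values),
        window_bp=window,
        step_bp=step,
    )
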