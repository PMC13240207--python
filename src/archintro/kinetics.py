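"""Dose-response kinetics: Michaelis–Menten and substrate-inhibition models,
standard-curve calibration, and global nonlinear fits with shared or fixed Km.

Models:

* ``michaelis_menten``:    v = Vmax * S / (Km + S)
* ``substrate_inhibition``: v = Vmax * S / (Km + S * (1 + S / Ki))

Global fits minimize unweighted squared residuals jointly over datasets
(one Vmax per dataset; Km shared, fixed, or free per dataset; Ki shared for
substrate inhibition). Confidence intervals are asymptotic, from the
Jacobian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

MICHAELIS_MENTEN = "michaelis_menten"
SUBSTRATE_INHIBITION = "substrate_inhibition"
MODELS = (MICHAELIS_MENTEN, SUBSTRATE_INHIBITION)


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; message carries solver diagnostics."""


def michaelis_menten(S, Vmax: float, Km: float):
    S = np.asarray(S, dtype=np.float64)
    return Vmax * S / (Km + S)


def substrate_inhibition(S, Vmax: float, Km: float, Ki: float):
    S = np.asarray(S, dtype=np.float64)
    return Vmax * S / (Km + S * (1.0 + S / Ki))


def velocity(model: str, S, params: dict) -> np.ndarray:
    """Evaluate a named model; parameters must be positive."""
    S = np.asarray(S, dtype=np.float64)
    if np.any(S < 0):
        raise ValueError("substrate concentrations must be >= 0")
    if model == MICHAELIS_MENTEN:
        vmax, km = params["Vmax"], params["Km"]
        if vmax <= 0 or km <= 0:
            raise ValueError("Vmax and Km must be positive")
        return michaelis_menten(S, vmax, km)
    if model == SUBSTRATE_INHIBITION:
        vmax, km, ki = params["Vmax"], params["Km"], params["Ki"]
        if vmax <= 0 or km <= 0 or ki <= 0:
            raise ValueError("Vmax, Km and Ki must be positive")
        return substrate_inhibition(S, vmax, km, ki)
    raise ValueError(f"unknown model {model!r}")


def peak_substrate(Km: float, Ki: float) -> float:
    """Substrate concentration at maximum velocity of the inhibition model."""
    return float(np.sqrt(Km * Ki))


@dataclass
class KineticDataset:
    """One condition's dose-response rows (with replicate index)."""

    condition: str
    S: np.ndarray
    velocity: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)
        self.velocity = np.asarray(self.velocity, dtype=np.float64)
        if self.S.shape != self.velocity.shape:
            raise ValueError("S and velocity must have the same length")
        if np.any(self.S < 0):
            raise ValueError("substrate concentrations must be >= 0")
        if self.replicate is None:
            self.replicate = np.zeros(self.S.size, dtype=np.int64)

    @property
    def n_distinct_concentrations(self) -> int:
        return int(np.unique(self.S).size)


def read_kinetic_table(path: str | Path) -> list[KineticDataset]:
    """Read a TSV with columns (condition, S, replicate, velocity)."""
    df = pd.read_csv(path, sep="\t")
    required = {"condition", "S", "velocity"}
    if not required.issubset(df.columns):
        raise ValueError(f"kinetic table needs columns {sorted(required)}")
    out = []
    for cond, grp in df.groupby("condition", sort=False):
        rep = grp["replicate"].to_numpy() if "replicate" in grp.columns else None
        out.append(
            KineticDataset(
                condition=str(cond),
                S=grp["S"].to_numpy(dtype=np.float64),
                velocity=grp["velocity"].to_numpy(dtype=np.float64),
                replicate=rep,
            )
        )
    return out


def write_kinetic_table(datasets: Sequence[KineticDataset], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "condition": ds.condition,
                "S": ds.S,
                "replicate": ds.replicate,
                "velocity": ds.velocity,
            }
        )
        for ds in datasets
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


@dataclass
class ConditionFit:
    condition: str
    vmax: float
    vmax_ci: tuple[float, float]
    km: float | None = None  # populated in free mode
    ki: float | None = None


@dataclass
class KineticFit:
    model: str
    km_mode: str  # "shared" | "fixed" | "free"
    conditions: list[ConditionFit]
    km: float | None  # shared/fixed value (None in free mode)
    km_ci: tuple[float, float] | None
    ki: float | None
    ki_ci: tuple[float, float] | None
    rss: float
    n_obs: int
    n_params: int

    @property
    def dof(self) -> int:
        return self.n_obs - self.n_params

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "km_mode": self.km_mode,
            "km": self.km,
            "km_ci": list(self.km_ci) if self.km_ci else None,
            "ki": self.ki,
            "ki_ci": list(self.ki_ci) if self.ki_ci else None,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "conditions": [
                {
                    "condition": c.condition,
                    "vmax": c.vmax,
                    "vmax_ci": list(c.vmax_ci),
                    "km": c.km,
                    "ki": c.ki,
                }
                for c in self.conditions
            ],
        }


@dataclass
class CalibrationResult:
    concentrations: np.ndarray
    slope: float
    intercept: float


def rfu_to_concentration(rfu_values, standard_points) -> CalibrationResult:
    """Convert raw fluorescence to concentration via a linear standard curve.

    ``standard_points`` are (concentration, signal) pairs; an ordinary
    least-squares line signal = slope*conc + intercept is fitted and
    inverted.
    """
    pts = np.asarray(standard_points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (concentration, signal) standard points")
    conc, signal = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("degenerate standards: all concentrations equal")
    slope, intercept = np.polyfit(conc, signal, 1)
    if slope == 0:
        raise ValueError("flat standard curve; cannot invert")
    rfu = np.asarray(rfu_values, dtype=np.float64)
    return CalibrationResult(
        concentrations=(rfu - intercept) / slope,
        slope=float(slope),
        intercept=float(intercept),
    )


def percent_change(vmax_variant: float, vmax_reference: float) -> float:
    """Percent reduction of the variant relative to the reference (negative if increased)."""
    if vmax_reference <= 0:
        raise ValueError("reference Vmax must be positive")
    return 100.0 * (vmax_reference - vmax_variant) / vmax_reference


# ---------------------------------------------------------------------------
# Global fitting
# ---------------------------------------------------------------------------


def _initial_values(datasets: Sequence[KineticDataset], model: str):
    vmax0 = [max(float(ds.velocity.max()), 1e-9) for ds in datasets]
    km0 = []
    for ds, v0 in zip(datasets, vmax0):
        half = v0 / 2.0
        above = ds.S[ds.velocity >= half]
        km0.append(float(above.min()) if above.size and above.min() > 0 else
                   max(float(np.median(ds.S[ds.S > 0])), 1e-9))
    ki0 = max(float(max(ds.S.max() for ds in datasets)), 1e-9)
    return vmax0, km0, ki0


def global_fit(
    datasets: Sequence[KineticDataset] | KineticDataset,
    model: str = SUBSTRATE_INHIBITION,
    km_mode: str = "shared",
    km_value: float | None = None,
    confidence: float = 0.95,
) -> KineticFit:
    """Joint nonlinear least-squares fit over one or more dose-response datasets.

    ``km_mode``:

    * ``"shared"`` — a single Km (and, for substrate inhibition, a single
      Ki) is estimated across all datasets;
    * ``"fixed"``  — Km held at ``km_value`` (Ki still estimated, shared);
    * ``"free"``   — per-dataset Km (and Ki), equivalent to independent fits.

    Asymptotic CIs come from the inverse Gauss–Newton Hessian at the
    optimum with a Student-t quantile on the residual degrees of freedom.
    """
    if isinstance(datasets, KineticDataset):
        datasets = [datasets]
    datasets = list(datasets)
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if km_mode not in ("shared", "fixed", "free"):
        raise ValueError(f"unknown km_mode {km_mode!r}")
    if km_mode == "fixed":
        if km_value is None or km_value <= 0:
            raise ValueError("km_mode='fixed' requires a positive km_value")
    if not datasets:
        raise ValueError("need at least one dataset")
    for ds in datasets:
        if ds.n_distinct_concentrations < 3:
            raise ValueError(
                f"dataset {ds.condition!r} has fewer than 3 distinct concentrations"
            )

    K = len(datasets)
    si = model == SUBSTRATE_INHIBITION
    vmax0, km0, ki0 = _initial_values(datasets, model)

    # parameter layout (all log-transformed for positivity):
    #   [Vmax_1..Vmax_K] + km block + ki block
    names: list[str] = [f"vmax_{i}" for i in range(K)]
    x0 = list(vmax0)
    if km_mode == "shared":
        names.append("km")
        x0.append(float(np.median(km0)))
    elif km_mode == "free":
        names.extend(f"km_{i}" for i in range(K))
        x0.extend(km0)
    if si:
        if km_mode == "free":
            names.extend(f"ki_{i}" for i in range(K))
            x0.extend([ki0] * K)
        else:
            names.append("ki")
            x0.append(ki0)

    n_obs = sum(ds.S.size for ds in datasets)
    n_params = len(x0)
    if n_obs <= n_params:
        raise ValueError(f"{n_obs} observations cannot constrain {n_params} parameters")

    idx = {nm: i for i, nm in enumerate(names)}

    def unpack(theta, i):
        vmax = theta[idx[f"vmax_{i}"]]
        if km_mode == "fixed":
            km = km_value
        elif km_mode == "shared":
            km = theta[idx["km"]]
        else:
            km = theta[idx[f"km_{i}"]]
        ki = None
        if si:
            ki = theta[idx[f"ki_{i}"]] if km_mode == "free" else theta[idx["ki"]]
        return vmax, km, ki

    def residuals(log_theta):
        theta = np.exp(log_theta)
        res = []
        for i, ds in enumerate(datasets):
            vmax, km, ki = unpack(theta, i)
            pred = substrate_inhibition(ds.S, vmax, km, ki) if si else michaelis_menten(
                ds.S, vmax, km
            )
            res.append(pred - ds.velocity)
        return np.concatenate(res)

    sol = optimize.least_squares(
        residuals, np.log(np.asarray(x0)), method="lm", xtol=1e-12, ftol=1e-12, max_nfev=20000
    )
    if not sol.success:
        raise FitError(f"fit did not converge: {sol.message} (status {sol.status})")

    theta = np.exp(sol.x)
    rss = float(np.sum(sol.fun**2))
    dof = n_obs - n_params
    s2 = rss / dof if dof > 0 else np.nan

    # covariance in the log-parameterization, delta-method back-transform
    J = sol.jac
    JTJ = J.T @ J
    try:
        cov_log = np.linalg.inv(JTJ) * s2
    except np.linalg.LinAlgError:
        cov_log = np.linalg.pinv(JTJ) * s2
    se = theta * np.sqrt(np.maximum(np.diag(cov_log), 0.0))  # d(exp x) = exp(x) dx
    tq = stats.t.ppf(0.5 + confidence / 2.0, dof) if dof > 0 else np.inf

    def ci(i):
        return (float(theta[i] - tq * se[i]), float(theta[i] + tq * se[i]))

    conditions = []
    for i, ds in enumerate(datasets):
        vmax, km, ki = unpack(theta, i)
        conditions.append(
            ConditionFit(
                condition=ds.condition,
                vmax=float(vmax),
                vmax_ci=ci(idx[f"vmax_{i}"]),
                km=float(km) if km_mode == "free" else None,
                ki=float(ki) if (si and km_mode == "free") else None,
            )
        )

    km = km_ci = ki = ki_ci = None
    if km_mode == "shared":
        km, km_ci = float(theta[idx["km"]]), ci(idx["km"])
    elif km_mode == "fixed":
        km = float(km_value)
    if si and km_mode != "free":
        ki, ki_ci = float(theta[idx["ki"]]), ci(idx["ki"])

    return KineticFit(
        model=model,
        km_mode=km_mode,
        conditions=conditions,
        km=km,
        km_ci=km_ci,
        ki=ki,
        ki_ci=ki_ci,
        rss=rss,
        n_obs=n_obs,
        n_params=n_params,
    )


def select_model(
    datasets: Sequence[KineticDataset] | KineticDataset,
    km_mode: str = "shared",
    km_value: float | None = None,
    alpha: float = 0.05,
) -> tuple[str, float]:
    """Choose between the two models by an extra-sum-of-squares F-test.

    Michaelis–Menten is nested in substrate inhibition (Ki → ∞); the richer
    model is kept only when the F-test rejects at ``alpha``. Returns
    (model, p_value).
    """
    fit_mm = global_fit(datasets, MICHAELIS_MENTEN, km_mode=km_mode, km_value=km_value)
    fit_si = global_fit(datasets, SUBSTRATE_INHIBITION, km_mode=km_mode, km_value=km_value)
    extra = fit_si.n_params - fit_mm.n_params
    if extra <= 0 or fit_si.dof <= 0:
        return MICHAELIS_MENTEN, 1.0
    num = max(fit_mm.rss - fit_si.rss, 0.0) / extra
    den = fit_si.rss / fit_si.dof
    if den == 0:
        return (SUBSTRATE_INHIBITION, 0.0) if num > 0 else (MICHAELIS_MENTEN, 1.0)
    f = num / den
    p = float(stats.f.sf(f, extra, fit_si.dof))
    return (SUBSTRATE_INHIBITION, p) if p < alpha else (MICHAELIS_MENTEN, p)
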