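"""Trend fits and replicate summaries for the phantom experiment.

Two trend models tie the imaged Cherenkov intensity to the colorimetry of
the phantoms: a straight line in CIE-L (light scattering and escape scale
together over the measured range) and an exponential decay in melanin index
(diffusion theory with an attenuation coefficient linear in MI).  The grid
summary aggregates the (skin type x plan x replicate) maximum-Dice table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FitResult",
    "GridSummary",
    "fit_exponential_decay",
    "fit_linear_r2",
    "summarize_dsc_grid",
    "tukey_hsd_dsc",
]


@dataclass(frozen=True)
class FitResult:
    """Result of a trend fit.

    ``params`` holds ``slope``/``intercept`` for the linear model and
    ``i0``/``k_hat`` for the exponential model.  For the exponential model
    ``r_squared`` is computed on the log-transformed intensities (the model
    is fitted in log space); the original-scale value is kept alongside it
    in ``params`` as ``r_squared_original``.
    """

    model: str
    params: dict
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_points < 3:
            raise ValueError("a trend fit needs at least 3 points")


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("response is constant; r^2 reported as 0", stacklevel=3)
        return 0.0
    ss_res = float(np.sum((y - fitted) ** 2))
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def fit_linear_r2(x, y) -> FitResult:
    """Ordinary least squares line with ``r^2 = 1 - SS_res / SS_tot``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("x is constant; the line is undefined")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    fitted = slope * x + intercept
    return FitResult(
        model="linear",
        params={"slope": slope, "intercept": intercept},
        r_squared=_r_squared(y, fitted),
        n_points=int(x.size),
    )


def fit_exponential_decay(mi, intensity, method: str = "log_linear") -> FitResult:
    """Fit ``I = I0 * exp(-k_hat * MI)`` to positive intensities.

    The default is the log-linearised least-squares fit
    ``ln I = ln I0 - k_hat * MI`` (deterministic, exact on noise-free
    exponential data); ``method="nls"`` refines it by nonlinear least
    squares on the original scale.  ``r_squared`` is reported in log space;
    the original-scale value is stored as ``params["r_squared_original"]``.
    """
    mi = np.asarray(mi, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mi.shape != intensity.shape or mi.ndim != 1:
        raise ValueError("mi and intensity must be 1-D sequences of equal length")
    if mi.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(intensity <= 0.0):
        raise ValueError("all intensities must be > 0 for an exponential-decay fit")

    log_fit = fit_linear_r2(mi, np.log(intensity))
    i0 = float(np.exp(log_fit.params["intercept"]))
    k_hat = float(-log_fit.params["slope"])

    if method == "nls":
        popt, _ = optimize.curve_fit(
            lambda m, a, k: a * np.exp(-k * m), mi, intensity, p0=(i0, k_hat)
        )
        i0, k_hat = float(popt[0]), float(popt[1])
    elif method != "log_linear":
        raise ValueError("method must be 'log_linear' or 'nls'")

    fitted = i0 * np.exp(-k_hat * mi)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-response warning already raised once
        r2_original = _r_squared(intensity, fitted)
    return FitResult(
        model="exponential",
        params={"i0": i0, "k_hat": k_hat, "r_squared_original": r2_original},
        r_squared=_r_squared(np.log(intensity), np.log(fitted)),
        n_points=int(mi.size),
    )


REQUIRED_COLUMNS = ("skin_type", "plan", "replicate", "max_dsc")


@dataclass
class GridSummary:
    """Per-(skin type, plan) summary of the maximum-Dice table."""

    per_cell: pd.DataFrame
    mean_replicate_std: float


def summarize_dsc_grid(table: pd.DataFrame, ddof: int = 0) -> GridSummary:
    """Mean / std / min / max of max-DSC per (skin type, plan) cell.

    ``ddof=0`` (population standard deviation) by default for replicate
    summaries.  Also reports the overall mean replicate standard deviation,
    the study's setup-reproducibility figure.
    """
    if table is None or len(table) == 0:
        raise ValueError("experiment table is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"experiment table lacks columns: {missing}")
    grouped = table.groupby(["skin_type", "plan"], sort=False)["max_dsc"]
    per_cell = grouped.agg(
        mean_dsc="mean",
        std_dsc=lambda v: float(np.std(v, ddof=ddof)),
        min_dsc="min",
        max_dsc="max",
        n="count",
    ).reset_index()
    return GridSummary(
        per_cell=per_cell,
        mean_replicate_std=float(per_cell["std_dsc"].mean()),
    )


def tukey_hsd_dsc(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Tukey HSD p-values across (skin type, plan) cells.

    Delegated to :func:`scipy.stats.tukey_hsd`; returned as a labelled
    p-value matrix.  Requires at least two replicates per cell.
    """
    if table is None or len(table) == 0:
        raise ValueError("experiment table is empty")
    groups, labels = [], []
    for (skin, plan), sub in table.groupby(["skin_type", "plan"], sort=False):
        groups.append(np.asarray(sub["max_dsc"], dtype=float))
        labels.append(f"{skin}/{plan}")
    if len(groups) < 2:
        raise ValueError("need at least two cells for Tukey HSD")
    res = stats.tukey_hsd(*groups)
    return pd.DataFrame(res.pvalue, index=labels, columns=labels)
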