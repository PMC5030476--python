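"""Disease-specific cutoff at the maximum deviation between exceedance curves.

The two groups' co-expression levels form two empirical distributions.  For
a threshold c, the exceedance F(c) = Prob(|r| >= c) is the fraction of pairs
at least as co-expressed as c.  The maximum deviation

    D = max_c |F_disease(c) - F_normal(c)|

is the classical two-sample Kolmogorov-Smirnov statistic (the supremum of a
difference of step functions, attained on the union of observed values), and
the threshold C attaining it is the disease-specific cutoff point.  D is
compared against the asymptotic Smirnov critical value

    D_critical = c(alpha) * sqrt((n1 + n2) / (n1 * n2))

with the standard coefficient table (c(0.05) = 1.36).  Gene pairs share
genes, so the pair-level samples are not independent; the significance call
is therefore approximate and is flagged as such in reports.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Asymptotic two-sample Smirnov coefficients c(alpha).
SMIRNOV_COEFFICIENTS = {
    0.10: 1.22,
    0.05: 1.36,
    0.025: 1.48,
    0.01: 1.63,
    0.005: 1.73,
    0.001: 1.95,
}


@dataclass(frozen=True)
class CutoffResult:
    """Outcome of the maximum-deviation cutoff search."""

    D: float
    C: float
    D_critical: float
    alpha: float
    n_normal_pairs: int
    n_disease_pairs: int
    significant: bool

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["note"] = ("pair-level samples share genes and are not "
                          "independent; the KS significance call is "
                          "approximate")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def exceedance(values, c: float) -> float:
    """Fraction of ``values`` that are >= c (survival function at c)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value collection")
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {c}")
    return float(np.count_nonzero(v >= c) / v.size)


def _exceedance_curve(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Vectorized exceedance of sorted ``values`` at every grid point."""
    srt = np.sort(values)
    return 1.0 - np.searchsorted(srt, grid, side="left") / srt.size


def max_deviation(table: pd.DataFrame) -> tuple[float, float]:
    """Maximum deviation D and cutoff C from a co-expression table.

    Candidate thresholds are the union of all observed c_normal and
    c_disease values; the supremum of a difference of step functions is
    attained there, so the search is exact.  Ties are broken toward the
    smallest candidate attaining D.
    """
    if len(table) == 0:
        raise ValueError("empty co-expression table")
    cn = table["c_normal"].to_numpy(dtype=float)
    cd = table["c_disease"].to_numpy(dtype=float)
    grid = np.unique(np.concatenate([cn, cd]))
    diff = np.abs(_exceedance_curve(cd, grid) - _exceedance_curve(cn, grid))
    best = int(np.argmax(diff))  # argmax returns the first = smallest C
    D = float(diff[best])
    C = float(grid[best])
    n_ties = int(np.count_nonzero(diff == D))
    logger.info("max deviation D=%.6g at C=%.6g (grid size %d, %d tie(s))",
                D, C, grid.size, n_ties)
    return D, C


def critical_deviation(n1: int, n2: int, alpha: float = 0.05) -> float:
    """Asymptotic Smirnov critical deviation for samples of size n1, n2."""
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    try:
        coeff = SMIRNOV_COEFFICIENTS[alpha]
    except KeyError:
        raise ValueError(
            f"unsupported alpha {alpha}; supported: "
            f"{sorted(SMIRNOV_COEFFICIENTS)}") from None
    return coeff * math.sqrt((n1 + n2) / (n1 * n2))


def ks_decision(D: float, D_critical: float) -> bool:
    """Significance decision: the deviation must strictly exceed critical."""
    if D < 0 or D_critical < 0:
        raise ValueError("deviations must be non-negative")
    return D > D_critical


def detect_cutoff(table: pd.DataFrame, alpha: float = 0.05) -> CutoffResult:
    """Full cutoff analysis for a co-expression table."""
    D, C = max_deviation(table)
    n = len(table)
    d_crit = critical_deviation(n, n, alpha)
    return CutoffResult(D=D, C=C, D_critical=d_crit, alpha=alpha,
                        n_normal_pairs=n, n_disease_pairs=n,
                        significant=ks_decision(D, d_crit))


def plot_exceedance(table: pd.DataFrame, result: CutoffResult, path) -> None:
    """Plot both exceedance curves and the deviation curve versus threshold."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cn = table["c_normal"].to_numpy(dtype=float)
    cd = table["c_disease"].to_numpy(dtype=float)
    grid = np.unique(np.concatenate([cn, cd]))
    fn = _exceedance_curve(cn, grid)
    fd = _exceedance_curve(cd, grid)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.step(grid, fn, where="post", label="normal")
    ax1.step(grid, fd, where="post", label="disease")
    ax1.axvline(result.C, ls="--", c="gray")
    ax1.set_xlabel("co-expression level |r|")
    ax1.set_ylabel("exceedance Prob(|r| ≥ c)")
    ax1.legend()
    ax2.step(grid, np.abs(fd - fn), where="post", color="k")
    ax2.axvline(result.C, ls="--", c="gray")
    ax2.axhline(result.D_critical, ls=":", c="red", label="critical D")
    ax2.set_xlabel("co-expression level |r|")
    ax2.set_ylabel("|F_d − F_n|")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
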