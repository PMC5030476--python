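"""Four-way gene-pair classification at the disease-specific cutoff.

A pair is strongly co-expressed in a group when its |r| is greater than or
equal to the cutoff C (the boundary counts as strong).  The joint
(strong_normal, strong_disease) booleans partition all pairs into the four
regions of the co-expression galaxy:

    (True,  False) -> normal_specific_strong  (== disease-specific weak)
    (False, True)  -> disease_specific_strong (== normal-specific weak)
    (True,  True)  -> common_strong
    (False, False) -> common_weak
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

NORMAL_SPECIFIC_STRONG = "normal_specific_strong"
DISEASE_SPECIFIC_STRONG = "disease_specific_strong"
COMMON_STRONG = "common_strong"
COMMON_WEAK = "common_weak"
CATEGORIES = (NORMAL_SPECIFIC_STRONG, DISEASE_SPECIFIC_STRONG,
              COMMON_STRONG, COMMON_WEAK)


def category_from_flags(strong_normal: bool, strong_disease: bool) -> str:
    """Galaxy category as a pure function of the two strong/weak booleans."""
    if strong_normal:
        return COMMON_STRONG if strong_disease else NORMAL_SPECIFIC_STRONG
    return DISEASE_SPECIFIC_STRONG if strong_disease else COMMON_WEAK


def classify_pairs(table: pd.DataFrame, C: float) -> pd.DataFrame:
    """Annotate a co-expression table with strong/weak flags and category."""
    if not 0.0 <= C <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {C}")
    out = table.copy()
    out["strong_normal"] = out["c_normal"].to_numpy() >= C
    out["strong_disease"] = out["c_disease"].to_numpy() >= C
    out["category"] = np.select(
        [out["strong_normal"] & ~out["strong_disease"],
         ~out["strong_normal"] & out["strong_disease"],
         out["strong_normal"] & out["strong_disease"]],
        [NORMAL_SPECIFIC_STRONG, DISEASE_SPECIFIC_STRONG, COMMON_STRONG],
        default=COMMON_WEAK)
    return out


def galaxy_summary(classified: pd.DataFrame) -> dict:
    """Counts and percentages for the four galaxy regions.

    Also reports per-group strong/weak totals (strong_normal =
    normal-specific strong + common strong, and likewise for disease).
    """
    total = len(classified)
    if total == 0:
        raise ValueError("empty classification")
    counts = {cat: int((classified["category"] == cat).sum())
              for cat in CATEGORIES}
    percentages = {cat: 100.0 * counts[cat] / total for cat in CATEGORIES}
    return {
        "total_pairs": total,
        "counts": counts,
        "percentages": percentages,
        "strong_normal_count": counts[NORMAL_SPECIFIC_STRONG] + counts[COMMON_STRONG],
        "weak_normal_count": counts[DISEASE_SPECIFIC_STRONG] + counts[COMMON_WEAK],
        "strong_disease_count": counts[DISEASE_SPECIFIC_STRONG] + counts[COMMON_STRONG],
        "weak_disease_count": counts[NORMAL_SPECIFIC_STRONG] + counts[COMMON_WEAK],
    }


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)


def galaxy_plot(classified: pd.DataFrame, C: float, path) -> None:
    """Scatter of (c_normal, c_disease) with the two cutoff lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(classified["c_normal"], classified["c_disease"],
               s=4, alpha=0.4, c="k", linewidths=0)
    ax.axvline(C, ls="--", c="red")
    ax.axhline(C, ls="--", c="red")
    ax.set_xlabel("co-expression level, normal group")
    ax.set_ylabel("co-expression level, disease group")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
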