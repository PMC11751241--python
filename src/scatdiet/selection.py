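"""Prey use vs. availability: log-likelihood goodness-of-fit (G) test and
Manly selection ratios with Bonferroni-adjusted simultaneous CIs."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import AvailabilityTable, FrequencyTable

__all__ = [
    "GoodnessOfFitResult",
    "SelectionResult",
    "g_test",
    "selection_ratios",
    "selection_report",
]


@dataclass(frozen=True)
class GoodnessOfFitResult:
    predator: str
    g_statistic: float
    df: int
    p_value: float


@dataclass
class SelectionResult:
    """Per-prey selection ratios w = used/available with simultaneous CIs.

    ``table`` columns: prey, used_prop, avail_prop, ratio, ci_low, ci_high,
    classification (preference iff ci_low > 1, avoidance iff ci_high < 1,
    else neutral).
    """

    predator: str
    alpha: float
    z: float
    table: pd.DataFrame


def _align(observed: FrequencyTable, availability: AvailabilityTable):
    """Categories are the availability support; observed defaults to zero."""
    pi = availability.proportions
    extra = {
        p for p, c in observed.occurrence_counts.items() if c > 0 and pi.get(p, 0) <= 0
    }
    if extra:
        raise ValueError(
            f"prey observed but with zero availability: {sorted(extra)}"
        )
    prey = sorted(p for p in pi if pi[p] > 0)
    obs = np.array([observed.occurrence_counts.get(p, 0) for p in prey], dtype=float)
    avail = np.array([pi[p] for p in prey])
    return prey, obs, avail


def g_test(
    observed: FrequencyTable, availability: AvailabilityTable
) -> GoodnessOfFitResult:
    """G = 2 Σ Oᵢ ln(Oᵢ/Eᵢ) with Eᵢ = n·πᵢ; p from χ²(k−1) upper tail.

    Availability proportions are treated as fixed (not estimated from the
    data), so df = k − 1 over the k categories with expected > 0.
    """
    prey, obs, avail = _align(observed, availability)
    n = obs.sum()
    if n <= 0:
        raise ValueError("no observed occurrences")
    expected = n * avail
    mask = obs > 0
    g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))
    df = len(prey) - 1
    p = float(stats.chi2.sf(g, df))
    return GoodnessOfFitResult(observed.predator, g, df, p)


def selection_ratios(
    observed: FrequencyTable,
    availability: AvailabilityTable,
    alpha: float = 0.05,
) -> SelectionResult:
    """Selection ratios wᵢ = oᵢ/πᵢ with Bonferroni simultaneous normal CIs.

    se(wᵢ) = sqrt(oᵢ(1−oᵢ)/(n·πᵢ²)) (availability treated as known);
    z is the standard-normal quantile at 1 − α/(2k) so the k intervals
    jointly hold at level 1 − α. CIs are truncated below at 0. Prey with
    zero observed occurrences get w = 0 and a degenerate [0, 0] interval,
    flagged with a warning.
    """
    prey, obs, avail = _align(observed, availability)
    k = len(prey)
    if k < 2:
        raise ValueError("selection requires >= 2 prey categories")
    n = obs.sum()
    if n <= 0:
        raise ValueError("no observed occurrences")
    o = obs / n
    w = o / avail
    se = np.sqrt(o * (1.0 - o) / (n * avail**2))
    z = float(stats.norm.ppf(1.0 - alpha / (2.0 * k)))
    lo = np.maximum(w - z * se, 0.0)
    hi = w + z * se
    if np.any(obs == 0):
        zero_prey = [p for p, c in zip(prey, obs) if c == 0]
        warnings.warn(
            f"prey with zero observed occurrences {zero_prey}: ratio 0 with "
            "a degenerate CI; interpret with caution at small counts",
            stacklevel=2,
        )
    classification = np.where(lo > 1.0, "preference", np.where(hi < 1.0, "avoidance", "neutral"))
    table = pd.DataFrame(
        {
            "prey": prey,
            "used_prop": o,
            "avail_prop": avail,
            "ratio": w,
            "ci_low": lo,
            "ci_high": hi,
            "classification": classification,
        }
    )
    return SelectionResult(observed.predator, alpha, z, table)


def selection_report(result: SelectionResult, plot_path=None):
    """Sorted ratio table plus a horizontal-CI-bar figure (reference line at 1).

    Prey whose CI spans 1 with width > 2 are annotated ``inconclusive``.
    Returns (table, figure); the figure is also written to ``plot_path``
    when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = result.table.sort_values("ratio", ascending=True).reset_index(drop=True)
    width = table["ci_high"] - table["ci_low"]
    table["note"] = np.where(
        (table["classification"] == "neutral") & (width > 2.0),
        "inconclusive",
        "",
    )
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(table) + 1.5))
    y = np.arange(len(table))
    ax.hlines(y, table["ci_low"], table["ci_high"], color="0.4", lw=2)
    ax.plot(table["ratio"], y, "o", color="C0")
    ax.axvline(1.0, ls="--", color="k", lw=1)
    ax.set_yticks(y)
    ax.set_yticklabels(table["prey"])
    ax.set_xlabel("selection ratio (used / available)")
    ax.set_title(f"{result.predator}: prey selection ratios "
                 f"({100 * (1 - result.alpha):.0f}% simultaneous CIs)")
    fig.tight_layout()
    if plot_path is not None:
        fig.savefig(plot_path)
    return table, fig
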