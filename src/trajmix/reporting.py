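"""Descriptive surfaces: cohort x class contingency tables, class
proportions, uncorrected contingency odds ratios, and fitted mean curves
annotated with adult BMI bands.

The contingency odds ratios here are plain cross-product ratios of modal
counts and are labelled "uncorrected" throughout: they do NOT account for
classification error, so they will generally differ from 3-step-corrected
estimates computed on the same assignments (see :mod:`trajmix.three_step`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "contingency",
    "class_proportions",
    "naive_or_from_contingency",
    "mean_trajectory_curves",
    "plot_trajectories",
]

# Fixed adult BMI cut-offs (kg/m²); child bands need an external age-sex table.
ADULT_CUTOFFS = {"thinness": 18.5, "overweight": 25.0, "obesity": 30.0}
ADULT_AGE = 18.0


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """Cohort x class modal counts with within-cohort percentages."""

    counts: pd.DataFrame  # index: cohort, columns: class (1..K), integer counts
    row_pcts: pd.DataFrame  # same shape, percentages to 1 dp (half-up)
    class_proportions: pd.Series  # overall class shares, percentages to 1 dp


def contingency(labels, cohorts) -> ContingencyTable:
    """Cross-tabulate modal class labels against cohort membership."""
    labels = np.asarray(labels)
    cohorts = pd.Series(cohorts)
    if len(labels) != len(cohorts):
        raise ValueError("labels and cohorts must be equal length")
    counts = pd.crosstab(cohorts, pd.Series(labels, name="class"))
    counts.index.name = "cohort"
    # preserve first-appearance cohort order
    counts = counts.reindex(pd.unique(cohorts))
    row_pcts = counts.div(counts.sum(axis=1), axis=0) * 100.0
    row_pcts = row_pcts.map(_round_half_up)
    overall = counts.sum(axis=0) / counts.to_numpy().sum() * 100.0
    overall = overall.map(_round_half_up)
    return ContingencyTable(counts=counts, row_pcts=row_pcts, class_proportions=overall)


def class_proportions(labels, group=None) -> pd.Series | pd.DataFrame:
    """Share (%) of each class, overall or within each group level, to 1 dp."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty labels")
    if group is None:
        counts = pd.Series(labels).value_counts().sort_index()
        return (counts / counts.sum() * 100.0).map(_round_half_up)
    return contingency(labels, group).row_pcts


def naive_or_from_contingency(table: ContingencyTable, ref_class=None, ref_cohort=None) -> pd.DataFrame:
    """Uncorrected odds ratios from modal counts (cross-product ratios).

    OR[c, k] = (n_ck / n_c,ref_class) / (n_ref_cohort,k / n_ref_cohort,ref_class);
    reference row and column are exactly 1.  These ignore classification
    error and are descriptive companions to, not substitutes for, the
    corrected 3-step estimates.
    """
    counts = table.counts
    if ref_class is None:
        ref_class = counts.columns[0]
    if ref_cohort is None:
        ref_cohort = counts.index[0]
    if counts.loc[ref_cohort, ref_class] == 0 or (counts[ref_class] == 0).any():
        raise ValueError("zero reference cell")
    base = counts.loc[ref_cohort] / counts.loc[ref_cohort, ref_class]
    odds = counts.div(counts[ref_class], axis=0)
    return odds.div(base, axis=1)


def _band(bmi: float, age: float, child_cutoffs: pd.DataFrame | None) -> str:
    if age >= ADULT_AGE:
        thin, over, obese = ADULT_CUTOFFS["thinness"], ADULT_CUTOFFS["overweight"], ADULT_CUTOFFS["obesity"]
    elif child_cutoffs is not None:
        thin = np.interp(age, child_cutoffs["age"], child_cutoffs["thinness"])
        over = np.interp(age, child_cutoffs["age"], child_cutoffs["overweight"])
        obese = np.interp(age, child_cutoffs["age"], child_cutoffs["obesity"])
    else:
        return "user-table required"
    if bmi < thin:
        return "thinness"
    if bmi < over:
        return "normal"
    if bmi < obese:
        return "overweight"
    return "obese"


def mean_trajectory_curves(fit_result, age_grid, child_cutoffs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-class fitted mean BMI over an age grid with weight-status bands.

    ``age_grid`` is in raw years; it is centered with the fit's stored
    centering age before evaluating each class's polynomial.  For ages >= 18
    the fixed adult cut-offs (18.5 / 25 / 30) label the band; younger ages
    need a user-supplied child cut-off table (columns: age, thinness,
    overweight, obesity) and are otherwise labelled "user-table required".
    """
    if fit_result.centering_age is None:
        raise ValueError("fit has no centering age recorded")
    ages = np.asarray(age_grid, dtype=float)
    t = ages - fit_result.centering_age
    span = (t.min(), t.max())
    data_span = 30.0  # decades of follow-up; warn on clearly wider grids
    if span[1] - span[0] > 1.5 * data_span:
        warnings.warn("age grid extends well beyond typical data support", stacklevel=2)
    rows = []
    for k, pk in enumerate(fit_result.params, start=1):
        bmi = np.polynomial.polynomial.polyval(t, pk.beta)
        for a, b in zip(ages, bmi):
            rows.append((k, float(a), float(b), _band(float(b), float(a), child_cutoffs)))
    return pd.DataFrame(rows, columns=["class", "age", "bmi", "band"])


def plot_trajectories(curves: pd.DataFrame, path=None):
    """Plot fitted mean curves with adult band shading (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    amin, amax = curves["age"].min(), curves["age"].max()
    if amax >= ADULT_AGE:
        ax.axhspan(ADULT_CUTOFFS["thinness"], ADULT_CUTOFFS["overweight"], alpha=0.08, color="green")
        ax.axhspan(ADULT_CUTOFFS["overweight"], ADULT_CUTOFFS["obesity"], alpha=0.08, color="orange")
        ax.axhspan(ADULT_CUTOFFS["obesity"], curves["bmi"].max() + 2, alpha=0.08, color="red")
    for k, grp in curves.groupby("class"):
        ax.plot(grp["age"], grp["bmi"], label=f"class {k}")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("BMI (kg/m²)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
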