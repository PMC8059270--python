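"""Class enumeration and covariance-structure ladders, compared by BIC.

Mirrors the usual model-development sequence for trajectory mixtures: fit a
grid over the number of classes and over covariance-structure variants
(shared vs class-specific residuals, AR(1) on/off, class-specific intercept
variance), tabulate BIC and entropy, and pick the class number by BIC.
Entropy is reported for every row but never used for selection — it measures
classification sharpness, not fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from trajmix.gmm_core import FitError, FitResult, ModelSpec, fit

logger = logging.getLogger(__name__)

__all__ = ["SelectionTable", "fit_grid", "select", "default_variants", "load_variants"]

# The four named relaxation stages, applied cumulatively to a cubic model
# with random intercept/slope and sweep-heteroskedastic residuals.
_STAGES: tuple[tuple[str, dict], ...] = (
    ("het_sweeps", {}),
    ("class_resid", {"class_specific_residuals": True}),
    ("class_resid_ar1", {"class_specific_residuals": True, "ar1": True}),
    (
        "class_resid_ar1_intvar",
        {"class_specific_residuals": True, "ar1": True, "class_specific_intercept_var": True},
    ),
)


def default_variants() -> list[tuple[str, dict]]:
    """The cumulative relaxation ladder as (label, spec-overrides) pairs."""
    return [(label, dict(over)) for label, over in _STAGES]


def load_variants(path) -> list[tuple[str, dict]]:
    """Read variant templates from YAML: a list of {label, overrides} maps."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [(v["label"], dict(v.get("overrides", {}))) for v in doc["variants"]]


@dataclass
class SelectionTable:
    """Grid results: one row per (variant, K) with fit statistics."""

    table: pd.DataFrame  # columns: label, K, loglik, n_params, bic, entropy, converged
    fits: dict[tuple[str, int], FitResult] = field(default_factory=dict)

    @property
    def best_row(self) -> int:
        ok = self.table[self.table["converged"]]
        if ok.empty:
            raise ValueError("no converged rows")
        return int(ok["bic"].idxmin())


def fit_grid(
    ds,
    K_range,
    variants: list[tuple[str, dict]] | None = None,
    seed: int = 0,
    *,
    spec_base: dict | None = None,
    keep_fits: bool = True,
    **fit_kwargs,
) -> SelectionTable:
    """Fit every (K, variant) combination; failures are recorded, not fatal.

    ``spec_base`` supplies fields shared by all variants (``n_sweeps`` is
    mandatory, from the data if omitted).  Determinism: the same ``seed`` is
    passed to every fit, so a rerun reproduces the grid exactly.
    """
    K_range = list(K_range)
    variants = variants if variants is not None else default_variants()
    if not K_range or not variants:
        raise ValueError("empty grid")
    base = {"n_sweeps": ds.n_sweeps, "degree": 3}
    base.update(spec_base or {})
    rows = []
    fits: dict[tuple[str, int], FitResult] = {}
    for label, over in variants:
        for K in K_range:
            spec = ModelSpec(K=K, **{**base, **over})
            try:
                res = fit(ds, spec, seed=seed, **fit_kwargs)
                rows.append((label, K, res.loglik, res.n_params, res.bic, res.entropy, res.converged))
                if keep_fits:
                    fits[(label, K)] = res
            except (FitError, ValueError, np.linalg.LinAlgError) as err:
                logger.warning("fit_grid: (%s, K=%d) failed: %s", label, K, err)
                rows.append((label, K, np.nan, np.nan, np.nan, np.nan, False))
    table = pd.DataFrame(
        rows, columns=["label", "K", "loglik", "n_params", "bic", "entropy", "converged"]
    )
    return SelectionTable(table=table, fits=fits)


def select(table: SelectionTable, rule: str = "bic_min", elbow_frac: float = 0.01) -> tuple[str, int]:
    """Pick (variant label, K) from a grid.

    ``bic_min``: strict BIC minimum over converged rows.  ``bic_elbow``:
    within the variant holding the BIC minimum, walk K upward and stop at the
    last K before the BIC improvement over the previous K falls below
    ``elbow_frac`` of the first (K_min -> K_min+1) improvement; useful when
    BIC keeps creeping down with vanishing gains.
    """
    df = table.table[table.table["converged"]]
    if df.empty:
        raise ValueError("no converged rows to select from")
    best = df.loc[df["bic"].idxmin()]
    if rule == "bic_min":
        return str(best["label"]), int(best["K"])
    if rule != "bic_elbow":
        raise ValueError(f"unknown rule {rule!r}")
    sub = df[df["label"] == best["label"]].sort_values("K")
    Ks = sub["K"].to_numpy()
    bics = sub["bic"].to_numpy()
    if len(Ks) == 1:
        return str(best["label"]), int(Ks[0])
    gains = bics[:-1] - bics[1:]  # improvement going K -> K+1
    ref = gains[0]
    if ref <= 0:
        return str(best["label"]), int(Ks[0])
    for i, gain in enumerate(gains):
        if gain < elbow_frac * ref:
            return str(best["label"]), int(Ks[i])
    return str(best["label"]), int(Ks[-1])


def plausibility_report(table: SelectionTable, label: str, K: int) -> pd.DataFrame:
    """Class sizes and trajectory-crossing count for human review.

    Interpretability of a solution (do trajectories cross? are classes
    non-trivial in size?) is a judgement call; this reports the raw
    ingredients rather than automating the judgement.
    """
    res = table.fits[(label, K)]
    grid = np.linspace(-12, 18, 61)
    curves = np.stack([np.polynomial.polynomial.polyval(grid, pk.beta) for pk in res.params])
    crossings = 0
    for a in range(len(res.params)):
        for b in range(a + 1, len(res.params)):
            d = curves[a] - curves[b]
            crossings += int(np.sum(np.diff(np.sign(d)) != 0))
    rows = [
        (k + 1, pk.pi, float(curves[k][0]), float(curves[k][-1]))
        for k, pk in enumerate(res.params)
    ]
    df = pd.DataFrame(rows, columns=["class", "pi", "bmi_at_grid_start", "bmi_at_grid_end"])
    df.attrs["n_trajectory_crossings"] = crossings
    return df
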