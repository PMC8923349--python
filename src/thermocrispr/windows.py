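"""Segmental and categorical PGLS along the temperature axis.

The relationship between defense-system abundance and growth temperature
is strongly non-linear, but inside a narrow temperature segment a linear
PGLS is a reasonable local model.  ``segmental_pgls`` slides a fixed-size
window along the species sorted by Topt, re-fitting a λ-model PGLS in
every window; ``category_pgls`` fits within fixed temperature bands
(e.g. 4-34 / 35-49 / 50-85 °C).  ``tertile_split`` derives near-equal
bands from the data for small datasets, and ``paired_domain_comparison``
contrasts two domains (Bacteria vs Archaea) at their shared temperatures
with a Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_data import TraitTable
from .phylo import PGLSFit, PhyloCovariance, pgls_fit, phylo_covariance

__all__ = [
    "WindowResult",
    "CategorySpec",
    "segmental_pgls",
    "category_pgls",
    "tertile_split",
    "paired_domain_comparison",
]


@dataclass
class WindowResult:
    window_index: int
    species: list[str]
    mean_topt: float
    fit: PGLSFit

    @property
    def significant_05(self) -> bool:
        return self.fit.slope_p < 0.05

    @property
    def significant_01(self) -> bool:
        return self.fit.slope_p < 0.01

    @property
    def positive_slope(self) -> bool:
        return self.fit.slope > 0

    def to_row(self) -> dict:
        return {
            "window_index": self.window_index,
            "mean_topt": self.mean_topt,
            "n": self.fit.n,
            "slope": self.fit.slope,
            "p": self.fit.slope_p,
            "lambda_hat": self.fit.lambda_hat,
            "sig05": self.significant_05,
            "sig01": self.significant_01,
        }


@dataclass(frozen=True)
class CategorySpec:
    name: str
    topt_low: float
    topt_high: float  # inclusive bounds


def _sorted_order(table: TraitTable) -> pd.DataFrame:
    # deterministic ordering: equal-Topt ties broken by species_id
    return table.data.sort_values(
        ["topt_c", "species_id"], kind="stable"
    ).reset_index(drop=True)


def segmental_pgls(
    table: TraitTable,
    tree_or_cov,
    measure: str,
    window: int = 200,
    stride: int = 1,
) -> tuple[list[WindowResult], int]:
    """Sliding-window PGLS of ``measure`` on Topt over the sorted species.

    Windows whose temperatures are all identical are skipped (no covariate
    variance).  λ is re-estimated within every window.  Returns the fitted
    windows and the number skipped.
    """
    n = len(table)
    if n < window:
        raise ValueError(f"need at least window={window} species, got {n}")
    df = _sorted_order(table)
    cov = tree_or_cov if isinstance(tree_or_cov, PhyloCovariance) else phylo_covariance(tree_or_cov)
    pos = {label: i for i, label in enumerate(cov.tip_order)}

    topt = df["topt_c"].to_numpy(dtype=float)
    y_all = df[measure].to_numpy(dtype=float)
    idx_all = np.array([pos[s] for s in df["species_id"]])

    results: list[WindowResult] = []
    n_skipped = 0
    for start in range(0, n - window + 1, stride):
        sl = slice(start, start + window)
        x = topt[sl]
        if np.ptp(x) == 0:
            n_skipped += 1
            continue
        idx = idx_all[sl]
        sub = PhyloCovariance(
            cov.matrix[np.ix_(idx, idx)], list(df["species_id"][sl])
        )
        fit = pgls_fit(y_all[sl], x, sub)
        results.append(
            WindowResult(
                window_index=start,  # start offset in the Topt-sorted order
                species=list(df["species_id"][sl]),
                mean_topt=float(np.mean(x)),
                fit=fit,
            )
        )
    return results, n_skipped


def category_pgls(
    table: TraitTable,
    tree_or_cov,
    categories: list[CategorySpec],
    measures: list[str] | None = None,
    include_full_range: bool = True,
) -> pd.DataFrame:
    """PGLS per temperature category x measure, plus a whole-range fit.

    Categories with fewer than 4 species are skipped with a warning row
    (status column).  Output mirrors a slope/p table layout.
    """
    measures = measures or table.measures
    cov = tree_or_cov if isinstance(tree_or_cov, PhyloCovariance) else phylo_covariance(tree_or_cov)
    cats = list(categories)
    if include_full_range:
        lo, hi = table.data["topt_c"].min(), table.data["topt_c"].max()
        cats.append(CategorySpec("full_range", lo, hi))

    rows = []
    for cat in cats:
        mask = (table.data["topt_c"] >= cat.topt_low) & (
            table.data["topt_c"] <= cat.topt_high
        )
        sub = table.data[mask]
        for m in measures:
            row = {
                "category": cat.name,
                "topt_low": cat.topt_low,
                "topt_high": cat.topt_high,
                "measure": m,
                "n": int(mask.sum()),
            }
            if mask.sum() < 4:
                row["status"] = "skipped: <4 species"
                rows.append(row)
                continue
            subcov = cov.submatrix(list(sub["species_id"]))
            try:
                fit = pgls_fit(
                    sub[m].to_numpy(dtype=float),
                    sub["topt_c"].to_numpy(dtype=float),
                    subcov,
                )
            except ValueError as exc:
                row["status"] = f"skipped: {exc}"
                rows.append(row)
                continue
            row.update(fit.to_row())
            row["status"] = "ok"
            rows.append(row)
    return pd.DataFrame(rows)


def tertile_split(table: TraitTable) -> list[CategorySpec]:
    """Split species into three near-equal Topt groups without splitting ties.

    Boundaries are placed between runs of equal temperatures, at the cuts
    closest to n/3 and 2n/3, so species sharing a Topt always land in the
    same group.
    """
    n = len(table)
    if n < 6:
        raise ValueError("need at least 6 species for a tertile split")
    topt = np.sort(table.data["topt_c"].to_numpy(dtype=float))
    values, counts = np.unique(topt, return_counts=True)
    if len(values) < 3:
        raise ValueError("need at least 3 distinct Topt values")
    cuts = np.cumsum(counts)[:-1]  # allowed boundary positions

    first = cuts[np.argmin(np.abs(cuts - n / 3))]
    later = cuts[cuts > first]
    second = later[np.argmin(np.abs(later - 2 * n / 3))]

    bounds = [0, int(first), int(second), n]
    specs = []
    for g, name in enumerate(["low", "moderate", "high"]):
        members = topt[bounds[g]:bounds[g + 1]]
        specs.append(CategorySpec(name, float(members.min()), float(members.max())))
    return specs


def paired_domain_comparison(
    bacteria: TraitTable, archaea: TraitTable, measure: str
) -> tuple[int, float, float]:
    """Wilcoxon signed-rank comparison of domain means at shared Topts.

    At every integer temperature occupied by both domains the measure is
    averaged within each domain; the paired averages are compared with the
    signed-rank test (zero differences dropped; exact null for <= 25
    informative pairs, tie-corrected normal approximation above).  Returns
    (number of pairs, test statistic, p value); all-zero differences give
    statistic 0 and p = 1.
    """
    b = bacteria.data.groupby("topt_c")[measure].mean()
    a = archaea.data.groupby("topt_c")[measure].mean()
    shared = sorted(set(b.index) & set(a.index))
    if not shared:
        raise ValueError("no shared Topt between the two domains")
    diffs = np.array([b[t] - a[t] for t in shared], dtype=float)
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        return len(shared), 0.0, 1.0
    exact_ok = len(nonzero) <= 25 and len(np.unique(np.abs(nonzero))) == len(nonzero)
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", method="exact" if exact_ok else "approx"
    )
    return len(shared), float(res.statistic), float(res.pvalue)
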