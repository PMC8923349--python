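"""Temperature binning, the D-ratio step statistic and its permutation test.

The D statistic contrasts mean abundance above and below each integer
temperature i:

    D_i = mean(abundance | Topt >= i) / mean(abundance | Topt < i)

A large D_i says species at or above i are much richer in the feature than
species below it.  D_max is the largest D_i inside a trusted temperature
window (default 20-64 °C, where per-side sample sizes keep the means
stable), and its significance is assessed by permuting abundances against
the fixed temperature axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinSummary",
    "DCurve",
    "DMaxResult",
    "PermutationResult",
    "bin_summaries",
    "d_curve",
    "d_max",
    "permutation_test",
]


@dataclass
class BinSummary:
    bin_low: int
    bin_high: int
    n: int
    median_abundance: float
    mean_abundance: float


@dataclass
class DCurve:
    i_values: np.ndarray      # integer temperatures with both sides populated
    d_values: np.ndarray      # ratios; np.inf where the lower mean is zero
    n_lower: np.ndarray
    n_upper: np.ndarray


@dataclass
class DMaxResult:
    d_max: float
    argmax_i: int
    window: tuple[int, int]
    n_infinite: int = 0


@dataclass
class PermutationResult:
    observed: DMaxResult
    null_dmax: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    p_variant: str = "strict"
    measure: str = field(default="", compare=False)


def bin_summaries(topt, abundance, width: int = 5) -> list[BinSummary]:
    """Per-bin n/median/mean over fixed-width temperature bins.

    Bin b covers [width*b, width*b + width - 1]; empty bins are omitted
    (plotting layers mark them separately).
    """
    topt = np.asarray(topt)
    abundance = np.asarray(abundance, dtype=float)
    bins = np.floor_divide(topt.astype(int), width)
    out = []
    for b in np.unique(bins):
        vals = abundance[bins == b]
        out.append(
            BinSummary(
                bin_low=int(b * width),
                bin_high=int(b * width + width - 1),
                n=len(vals),
                median_abundance=float(np.median(vals)),
                mean_abundance=float(np.mean(vals)),
            )
        )
    return out


def d_curve(topt, abundance, grid: str = "integer") -> DCurve:
    """Compute D_i at every split point of the temperature axis.

    ``grid="integer"`` evaluates every integer i in (min(topt), max(topt)];
    ``grid="observed"`` only the observed temperatures above the minimum.
    Requires at least two distinct temperatures; a zero lower mean with a
    positive upper mean is flagged as +inf.
    """
    topt = np.asarray(topt, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    if np.any(abundance < 0):
        raise ValueError("abundance must be non-negative")
    tmin, tmax = topt.min(), topt.max()
    if tmin == tmax:
        raise ValueError("degenerate temperature axis: all Topt equal")

    order = np.argsort(topt, kind="stable")
    t_sorted = topt[order]
    a_sorted = abundance[order]
    csum = np.concatenate([[0.0], np.cumsum(a_sorted)])
    total = csum[-1]
    n = len(topt)

    if grid == "integer":
        i_values = np.arange(int(np.floor(tmin)) + 1, int(np.floor(tmax)) + 1)
    elif grid == "observed":
        i_values = np.unique(t_sorted[t_sorted > tmin]).astype(int)
    else:
        raise ValueError(f"unknown grid mode {grid!r}")

    # species strictly below i: count via searchsorted on the sorted axis
    k = np.searchsorted(t_sorted, i_values, side="left")
    n_lower = k
    n_upper = n - k
    valid = (n_lower >= 1) & (n_upper >= 1)
    i_values, k = i_values[valid], k[valid]
    n_lower, n_upper = n_lower[valid], n_upper[valid]

    lower_mean = csum[k] / n_lower
    upper_mean = (total - csum[k]) / n_upper
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(lower_mean > 0, upper_mean / lower_mean, np.inf)
    return DCurve(i_values, d, n_lower, n_upper)


def d_max(curve: DCurve, lo: int = 20, hi: int = 64) -> DMaxResult:
    """Maximum finite D_i over the window [lo, hi]; ties break to smallest i.

    +inf values inside the window are excluded from the maximum (they arise
    from a zero lower-side mean) but counted in ``n_infinite``.
    """
    mask = (curve.i_values >= lo) & (curve.i_values <= hi)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] disjoint from curve support")
    d = curve.d_values[mask]
    i = curve.i_values[mask]
    finite = np.isfinite(d)
    n_inf = int((~finite).sum())
    if not finite.any():
        raise ValueError("no finite D_i inside the window")
    k = int(np.argmax(d[finite]))  # argmax returns the first (smallest-i) max
    return DMaxResult(
        d_max=float(d[finite][k]),
        argmax_i=int(i[finite][k]),
        window=(lo, hi),
        n_infinite=n_inf,
    )


def _dmax_many(t_sorted, abund_matrix, i_values, k, n) -> np.ndarray:
    """D_max per row of abund_matrix against a fixed sorted axis."""
    csum = np.concatenate(
        [np.zeros((abund_matrix.shape[0], 1)), np.cumsum(abund_matrix, axis=1)], axis=1
    )
    total = csum[:, -1][:, None]
    lower = csum[:, k] / k
    upper = (total - csum[:, k]) / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(lower > 0, upper / lower, np.inf)
    d = np.where(np.isfinite(d), d, -np.inf)  # infinities excluded from max
    return d.max(axis=1)


def permutation_test(
    topt,
    abundance,
    n_perm: int = 1000,
    lo: int = 20,
    hi: int = 64,
    seed: int = 0,
    p_variant: str = "strict",
) -> PermutationResult:
    """Permutation null for D_max: shuffle abundances against the Topt axis.

    Shuffling the abundance vector while holding temperatures fixed is the
    same null as shuffling species along the temperature axis.  The default
    p-value counts strictly larger null maxima, p = #(null > observed)/n_perm;
    ``p_variant="conservative"`` uses (k+1)/(n_perm+1) instead.
    """
    topt = np.asarray(topt, dtype=float)
    abundance = np.asarray(abundance, dtype=float)
    if np.ptp(abundance) == 0:
        raise ValueError("constant abundance: permutation null is degenerate")
    observed = d_max(d_curve(topt, abundance), lo=lo, hi=hi)

    order = np.argsort(topt, kind="stable")
    t_sorted = topt[order]
    n = len(topt)
    i_values = np.arange(int(np.floor(t_sorted[0])) + 1, int(np.floor(t_sorted[-1])) + 1)
    k = np.searchsorted(t_sorted, i_values, side="left")
    win = (i_values >= lo) & (i_values <= hi) & (k >= 1) & (k <= n - 1)
    k = k[win]
    if len(k) == 0:
        raise ValueError(f"window [{lo}, {hi}] disjoint from curve support")

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(2e7 // max(n, 1))))
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        perms = rng.permuted(np.broadcast_to(abundance, (m, n)).copy(), axis=1)
        null[start:start + m] = _dmax_many(t_sorted, perms, i_values, k, n)

    exceed = int(np.sum(null > observed.d_max))
    if p_variant == "strict":
        p = exceed / n_perm
    elif p_variant == "conservative":
        p = (exceed + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown p_variant {p_variant!r}")
    return PermutationResult(observed, null, float(p), n_perm, seed, p_variant)
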