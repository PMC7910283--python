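"""Normalized information content, CIE and f-VICE.

For each position window of a V-plot, the fragment-size count vector is
summarised by its normalized Shannon information

    I(x) = 1 - H(x) / H_max,

where H is the plug-in (maximum-likelihood) entropy of the empirical size
distribution and H_max = log(L) is the entropy of the uniform distribution
over the L possible sizes (L = max_size - 40). I(x) is 1 when all fragments
in a window share one size and 0 when sizes are uniform. Both entropies use
the natural log; the ratio is base-invariant.

Raw information is confounded by coverage (sparse windows look "organised"
by chance), so the observed profile is compared with the profile expected
when fragment sizes are independent of position: size labels are randomly
permuted against position labels and the profile recomputed. The chromatin
information enrichment is

    CIE = log2(I_observed / I_expected)

per window, and f-VICE sums the positive part of CIE over landmark
positions: TF-proximal [-25, 25] bp, plus half the sum over the
TF-adjacent intervals [-70, -50] and [50, 70] bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .vplot import (
    DEFAULT_MAX_SIZE,
    DEFAULT_MIN_SIZE,
    VPlotMatrix,
    WindowGrid,
    aggregate_vplot,
)

__all__ = [
    "CIEProfile",
    "FVICEResult",
    "normalized_info",
    "info_profile",
    "observed_profile",
    "expected_profile",
    "cie_profile",
    "fvice",
    "normalize_fvices",
    "reference_qc",
]

CIE_FLOOR = 1e-6


@dataclass
class CIEProfile:
    """Observed/expected normalized information and their log2 ratio per window."""

    observed_info: np.ndarray
    expected_info: np.ndarray
    cie: np.ndarray
    grid: WindowGrid
    n_permutations: int = 1
    rng_seed: int | None = None
    undefined_windows: np.ndarray | None = None  # True where either I undefined

    @property
    def centers(self) -> np.ndarray:
        return self.grid.centers


@dataclass
class FVICEResult:
    """Raw and normalized f-VICE for one feature set (motif).

    ``m`` is the number of bound motif instances and ``f`` the total number
    of ATAC-seq fragments at those instances; both feed the linear-model
    normalization.
    """

    motif_id: str
    raw_fvice: float
    m: int
    f: int
    normalized_fvice: float | None = None
    ctcf_normalized_fvice: float | None = None


def normalized_info(size_counts: np.ndarray, n_sizes: int | None = None) -> float:
    """Normalized information content of one window's size-count vector.

    ``n_sizes`` (L) defaults to the vector length and must be >= 2; it is the
    number of representable fragment sizes (max size minus 40 under the
    default size bounds), not the number of sizes observed. Returns NaN for
    an all-zero vector (no fragments -> information undefined).
    """
    counts = np.asarray(size_counts, dtype=float)
    L = int(n_sizes) if n_sizes is not None else counts.size
    if L < 2:
        raise ValueError("need at least 2 possible fragment sizes")
    total = counts.sum()
    if total == 0:
        return float("nan")
    p = counts[counts > 0] / total
    h = -np.sum(p * np.log(p))
    return float(1.0 - h / np.log(L))


def info_profile(matrix: VPlotMatrix) -> np.ndarray:
    """Per-window normalized information of a V-plot matrix (NaN where empty)."""
    counts = matrix.counts.astype(float)
    L = counts.shape[0]
    if L < 2:
        raise ValueError("need at least 2 possible fragment sizes")
    totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=0)
    out = 1.0 - h / np.log(L)
    out[totals == 0] = np.nan
    return out


def _pool(per_feature_fragments: list[np.ndarray]) -> np.ndarray:
    arrays = [a for a in per_feature_fragments if len(a)]
    if not arrays:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(arrays)


def observed_profile(
    per_feature_fragments: list[np.ndarray],
    grid: WindowGrid,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> np.ndarray:
    matrix = aggregate_vplot(per_feature_fragments, grid, min_size, max_size)
    return info_profile(matrix)


def expected_profile(
    per_feature_fragments: list[np.ndarray],
    grid: WindowGrid,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    n_permutations: int = 1,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Expected per-window information under size-position independence.

    Fragment size labels are permuted against position labels across the
    pooled fragment list (the marginal size histogram is unchanged), the
    matrix is rebuilt and the information profile recomputed; with
    ``n_permutations > 1`` the per-window mean across permutations is
    returned.
    """
    rng = np.random.default_rng(rng)
    pooled = _pool(per_feature_fragments)
    profiles = np.empty((n_permutations, grid.n_windows))
    for i in range(n_permutations):
        perm = pooled.copy()
        if len(perm):
            perm[:, 1] = perm[rng.permutation(len(perm)), 1]
        profiles[i] = observed_profile([perm], grid, min_size, max_size)
    return profiles.mean(axis=0)


def cie_profile(
    observed: np.ndarray,
    expected: np.ndarray,
    grid: WindowGrid,
    floor: float = CIE_FLOOR,
    n_permutations: int = 1,
    rng_seed: int | None = None,
) -> CIEProfile:
    """CIE = log2(observed / expected) per window, with both informations
    floored at ``floor``; windows where either is undefined (no fragments)
    get CIE 0 and are flagged in ``undefined_windows``.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape or observed.shape != (grid.n_windows,):
        raise ValueError("observed/expected profile lengths do not match the grid")
    undefined = np.isnan(observed) | np.isnan(expected)
    obs = np.maximum(np.nan_to_num(observed), floor)
    exp = np.maximum(np.nan_to_num(expected), floor)
    cie = np.log2(obs / exp)
    cie[undefined] = 0.0
    return CIEProfile(
        observed_info=observed,
        expected_info=expected,
        cie=cie,
        grid=grid,
        n_permutations=n_permutations,
        rng_seed=rng_seed,
        undefined_windows=undefined,
    )


def compute_cie(
    per_feature_fragments: list[np.ndarray],
    grid: WindowGrid,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    n_permutations: int = 1,
    rng: np.random.Generator | int | None = None,
) -> CIEProfile:
    """Convenience: observed + expected profiles and their CIE in one call."""
    rng = np.random.default_rng(rng)
    obs = observed_profile(per_feature_fragments, grid, min_size, max_size)
    exp = expected_profile(
        per_feature_fragments, grid, min_size, max_size, n_permutations, rng
    )
    return cie_profile(obs, exp, grid, n_permutations=n_permutations)


# f-VICE landmark intervals (bp relative to the feature center): the
# TF-proximal window and the two TF-adjacent linker windows.
PROXIMAL = (-25, 25)
ADJACENT_LEFT = (-70, -50)
ADJACENT_RIGHT = (50, 70)


def _per_bp_cie(profile: CIEProfile, mapping: str) -> tuple[np.ndarray, np.ndarray]:
    lo = min(PROXIMAL[0], ADJACENT_LEFT[0])
    hi = max(PROXIMAL[1], ADJACENT_RIGHT[1])
    centers = profile.centers
    if centers[0] > lo or centers[-1] < hi:
        raise ValueError(
            f"grid window centers span [{centers[0]}, {centers[-1]}] but f-VICE "
            f"needs coverage of [{lo}, {hi}] bp"
        )
    positions = np.arange(lo, hi + 1)
    if mapping == "interpolate":
        values = np.interp(positions, centers, profile.cie)
    elif mapping == "nearest":
        idx = np.abs(positions[:, None] - centers[None, :]).argmin(axis=1)
        values = profile.cie[idx]
    else:
        raise ValueError(f"unknown per-bp mapping {mapping!r}")
    return positions, values


def fvice(profile: CIEProfile, mapping: str = "interpolate") -> float:
    """Raw f-VICE of a CIE profile.

    Per-bp CIE values at integer positions are obtained from the window-
    center values (linear interpolation by default, ``mapping="nearest"``
    assigns the nearest window), non-positive values are clamped to zero,
    and the landmark sums combined:

        f-VICE = sum_{i=-25..25} CIE_i
                 + (sum_{i=-70..-50} CIE_i + sum_{i=50..70} CIE_i) / 2
    """
    positions, values = _per_bp_cie(profile, mapping)
    clamped = np.clip(values, 0.0, None)

    def span(a: int, b: int) -> float:
        sel = (positions >= a) & (positions <= b)
        return float(clamped[sel].sum())

    return span(*PROXIMAL) + (span(*ADJACENT_LEFT) + span(*ADJACENT_RIGHT)) / 2.0


def normalize_fvices(results: list[FVICEResult], ctcf_key: str = "CTCF") -> pd.DataFrame:
    """Normalize raw f-VICEs across motifs for instance count and coverage.

    Fits the ordinary-least-squares model ``f-VICE ~ log10(m) + log10(f)``
    across all motifs (m = bound instances, f = total fragments at bound
    instances) and takes residuals, then divides every residual by the CTCF
    residual so CTCF is pinned at 1. A regression-free ``raw / raw_CTCF``
    column is also emitted.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 motifs to fit the 3-parameter model")
    ids = [r.motif_id for r in results]
    if ctcf_key not in ids:
        raise ValueError(f"reference motif {ctcf_key!r} not in the table")
    if any(r.m <= 0 or r.f <= 0 for r in results):
        raise ValueError("m and f must be positive for the log10 covariates")
    import statsmodels.api as sm

    df = pd.DataFrame(
        {
            "motif_id": ids,
            "raw_fvice": [r.raw_fvice for r in results],
            "m": [r.m for r in results],
            "f": [r.f for r in results],
        }
    )
    X = sm.add_constant(np.column_stack([np.log10(df["m"]), np.log10(df["f"])]))
    fit = sm.OLS(df["raw_fvice"].to_numpy(), X).fit()
    resid = fit.resid
    ctcf_resid = resid[df.index[df["motif_id"] == ctcf_key][0]]
    if ctcf_resid == 0:
        raise ValueError("CTCF residual is zero; cannot scale")
    df["normalized_fvice"] = resid / ctcf_resid
    raw_ctcf = float(df.loc[df["motif_id"] == ctcf_key, "raw_fvice"].iloc[0])
    if raw_ctcf == 0:
        raise ValueError("CTCF raw f-VICE is zero; cannot scale")
    df["ctcf_normalized_fvice"] = df["raw_fvice"] / raw_ctcf
    for r in results:
        row = df[df["motif_id"] == r.motif_id].iloc[0]
        r.normalized_fvice = float(row["normalized_fvice"])
        r.ctcf_normalized_fvice = float(row["ctcf_normalized_fvice"])
    return df


def reference_qc(
    sample_cie: CIEProfile,
    reference_cie: CIEProfile,
    max_distance: float = 200,
    min_rho: float = 0.8,
) -> tuple[float, bool]:
    """Sample-quality check against a reference CIE profile (e.g. the profile
    at ubiquitous CTCF-cohesin sites): Spearman correlation over windows with
    |center| <= ``max_distance`` bp; pass iff rho >= ``min_rho``.
    """
    if not np.array_equal(sample_cie.grid.starts, reference_cie.grid.starts):
        raise ValueError("CIE profiles are on different window grids")
    sel = np.abs(sample_cie.centers) <= max_distance
    if sel.sum() < 3:
        raise ValueError("fewer than 3 windows within max_distance")
    rho = stats.spearmanr(sample_cie.cie[sel], reference_cie.cie[sel]).statistic
    return float(rho), bool(rho >= min_rho)
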