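"""BMO: negative-binomial prediction of bound TF motif instances.

A motif instance is more likely to be TF-occupied when its flanking
chromatin is accessible and when additional instances of the same PWM are
nearby. BMO scores each instance of a PWM with two one-sided tests:

1. ATAC-seq accessibility — fragments overlapping +/-100 bp of the motif
   center (ignoring fragments whose Tn5 integration sites fall inside the
   motif, which are dominated by sequence bias), compared with a negative
   binomial background fitted on instances outside accessibility peaks;
2. motif co-occurrence — the number of same-PWM instances within +/-100 bp,
   compared with a negative binomial fitted on all instances.

The two p-values are combined by summing Z-scores (Stouffer), corrected for
multiple testing with Benjamini-Yekutieli (valid under arbitrary
dependence), and instances with adjusted p < 0.05 are called bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureInterval, FragmentRecord, PeakSet

__all__ = [
    "NBParams",
    "BMOScore",
    "count_flanking_fragments",
    "count_cooccurring",
    "fit_nb",
    "fit_background",
    "nb_upper_pvalue",
    "combine_stouffer",
    "adjust_benjamini_yekutieli",
    "score_counts",
    "bmo_predict",
]

BMO_FLANK = 100
BOUND_ALPHA = 0.05


@dataclass(frozen=True)
class NBParams:
    """Negative binomial parameters: mean ``mu`` and overdispersion ``size``
    with variance = mu + mu^2/size (size -> inf recovers the Poisson).
    """

    mu: float
    size: float
    converged: bool = True  # False when the method-of-moments fallback was used

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.size <= 0:
            raise ValueError("mu and size must be positive")

    @property
    def scipy_args(self) -> tuple[float, float]:
        """(n, p) for scipy.stats.nbinom."""
        return self.size, self.size / (self.size + self.mu)


@dataclass
class BMOScore:
    """Per-motif-instance BMO result."""

    motif_id: str
    atac_count: int
    cooccur_count: int
    p_atac: float
    p_cooccur: float
    z_combined: float
    p_combined: float
    p_adjusted: float
    bound: bool


def count_flanking_fragments(
    motifs: list[FeatureInterval],
    fragments: list[FragmentRecord],
    flank: int = BMO_FLANK,
) -> np.ndarray:
    """ATAC-seq fragments overlapping +/-``flank`` bp of each motif center,
    ignoring fragments that integrate directly in the motif.

    A fragment counts toward a motif iff its interval overlaps
    ``[center - flank, center + flank)`` and neither Tn5 integration site
    (the fragment's first and last base) lies within the motif interval.
    """
    counts = np.zeros(len(motifs), dtype=np.int64)
    if not motifs or not fragments:
        return counts
    by_chrom: dict[str, list[FragmentRecord]] = {}
    for fr in fragments:
        by_chrom.setdefault(fr.chrom, []).append(fr)
    starts_by_chrom = {
        c: np.array(sorted(range(len(v)), key=lambda i: v[i].start)) for c, v in by_chrom.items()
    }
    for c in by_chrom:
        by_chrom[c] = [by_chrom[c][i] for i in starts_by_chrom[c]]
    start_arrays = {c: np.array([fr.start for fr in v]) for c, v in by_chrom.items()}
    max_len = {c: max(fr.size for fr in v) for c, v in by_chrom.items()}
    for i, m in enumerate(motifs):
        frs = by_chrom.get(m.chrom)
        if frs is None:
            continue
        win_lo, win_hi = m.center - flank, m.center + flank  # half-open window
        starts = start_arrays[m.chrom]
        lo = np.searchsorted(starts, win_lo - max_len[m.chrom], side="left")
        hi = np.searchsorted(starts, win_hi, side="left")
        n = 0
        for fr in frs[lo:hi]:
            if fr.end <= win_lo or fr.start >= win_hi:
                continue
            cut5, cut3 = fr.start, fr.end - 1  # integration site base positions
            if m.start <= cut5 < m.end or m.start <= cut3 < m.end:
                continue
            n += 1
        counts[i] = n
    return counts


def count_cooccurring(motifs: list[FeatureInterval], flank: int = BMO_FLANK) -> np.ndarray:
    """Number of additional same-PWM instances whose center lies within
    +/-``flank`` bp of each instance's center (symmetric by construction).
    """
    counts = np.zeros(len(motifs), dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, m in enumerate(motifs):
        by_chrom.setdefault(m.chrom, []).append((m.center, i))
    for entries in by_chrom.values():
        entries.sort()
        centers = np.array([c for c, _ in entries])
        for j, (c, i) in enumerate(entries):
            lo = np.searchsorted(centers, c - flank, side="left")
            hi = np.searchsorted(centers, c + flank, side="right")
            counts[i] = hi - lo - 1
    return counts


def _nb_mom(counts: np.ndarray) -> tuple[float, float]:
    mu = counts.mean()
    var = counts.var(ddof=1)
    if var <= mu:
        return float(mu), 1e6  # effectively Poisson
    return float(mu), float(mu**2 / (var - mu))


def fit_nb(counts: np.ndarray, method: str = "ml") -> NBParams:
    """Fit NB(mu, size) by maximum likelihood (profile likelihood in size;
    the MLE of mu is the sample mean). Falls back to method of moments with
    ``converged=False`` when the ML root-finding fails.

    Poisson-like data (variance <= mean) yields a very large ``size``
    estimate, flagged via ``converged=False``.
    """
    counts = np.asarray(counts)
    if counts.size < 2 or np.all(counts == counts[0]):
        raise ValueError("need at least 2 distinct count values to fit an NB")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    mu = float(counts.mean())
    if method == "mom":
        mom_mu, mom_size = _nb_mom(counts)
        return NBParams(mom_mu, mom_size, converged=True)

    var = counts.var(ddof=1)
    if var <= mu:
        return NBParams(mu, 1e6, converged=False)

    n = counts.size
    total = counts.sum()

    def score(size: float) -> float:
        # d/d(size) of the NB log-likelihood at mu fixed at the sample mean
        return float(
            np.sum(special.digamma(counts + size))
            - n * special.digamma(size)
            + n * np.log(size / (size + mu))
            + n
            - (total + n * size) / (size + mu)
        )

    _, mom_size = _nb_mom(counts)
    lo, hi = mom_size / 64, mom_size * 64
    try:
        f_lo, f_hi = score(lo), score(hi)
        for _ in range(20):
            if f_lo > 0 > f_hi:
                break
            if f_lo <= 0:
                lo /= 4
                f_lo = score(lo)
            if f_hi >= 0:
                hi *= 4
                f_hi = score(hi)
        else:
            mom_mu, mom_size = _nb_mom(counts)
            return NBParams(mom_mu, mom_size, converged=False)
        size = optimize.brentq(score, lo, hi, xtol=1e-10, rtol=1e-12)
    except (ValueError, RuntimeError):
        mom_mu, mom_size = _nb_mom(counts)
        return NBParams(mom_mu, mom_size, converged=False)
    return NBParams(mu, float(size), converged=True)


def fit_background(
    counts_outside_peaks: np.ndarray,
    n_sample: int = 10_000,
    n_reps: int = 100,
    rng: np.random.Generator | int | None = None,
) -> NBParams:
    """Background accessibility NB from motif instances outside peaks.

    Randomly samples ``n_sample`` instances without replacement, fits an NB,
    repeats ``n_reps`` times, and averages the mean and overdispersion
    parameters. When fewer than ``n_sample`` instances are available all of
    them are used in a single fit, with a warning.
    """
    counts = np.asarray(counts_outside_peaks)
    if counts.size == 0:
        raise ValueError("no motif instances outside peaks")
    rng = np.random.default_rng(rng)
    if counts.size < n_sample:
        warnings.warn(
            f"only {counts.size} instances outside peaks (< {n_sample}); "
            "fitting once on all of them",
            stacklevel=2,
        )
        return fit_nb(counts)
    mus = np.empty(n_reps)
    sizes = np.empty(n_reps)
    converged = True
    for r in range(n_reps):
        if n_sample == counts.size:
            sub = counts  # sampling all of them is the identity
        else:
            sub = counts[rng.choice(counts.size, size=n_sample, replace=False)]
        params = fit_nb(sub)
        mus[r], sizes[r] = params.mu, params.size
        converged &= params.converged
    return NBParams(float(mus.mean()), float(sizes.mean()), converged=converged)


def nb_upper_pvalue(count: np.ndarray | int, params: NBParams) -> np.ndarray | float:
    """Upper-tail p-value P(X >= count) under NB(params); p(0) = 1."""
    n, p = params.scipy_args
    out = stats.nbinom.sf(np.asarray(count) - 1, n, p)
    return float(out) if np.isscalar(count) else out


def combine_stouffer(p_atac, p_cooccur) -> tuple[np.ndarray, np.ndarray]:
    """Stouffer combination: z_i = Phi^-1(1 - p_i), z = (z1 + z2)/sqrt(2),
    p = 1 - Phi(z). p-values of exactly 0 or 1 are clipped into the open
    interval by a machine-epsilon margin.
    """
    eps = np.finfo(float).tiny
    p1 = np.clip(np.asarray(p_atac, dtype=float), eps, 1 - 1e-16)
    p2 = np.clip(np.asarray(p_cooccur, dtype=float), eps, 1 - 1e-16)
    z = (stats.norm.isf(p1) + stats.norm.isf(p2)) / np.sqrt(2.0)
    return z, stats.norm.sf(z)


def adjust_benjamini_yekutieli(pvals) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values (original input order)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_by")[1]


def score_counts(
    atac_counts: np.ndarray,
    cooccur_counts: np.ndarray,
    atac_background: NBParams,
    cooccur_background: NBParams | None = None,
    alpha: float = BOUND_ALPHA,
    motif_ids: list[str] | None = None,
) -> list[BMOScore]:
    """Score motif instances from their accessibility and co-occurrence
    counts (the statistical core of :func:`bmo_predict`).

    ``cooccur_background`` defaults to an NB fitted on ``cooccur_counts``
    themselves; when those counts are all identical (no co-occurrence
    signal anywhere) the co-occurrence test is skipped (p = 1).
    """
    atac_counts = np.asarray(atac_counts)
    cooccur_counts = np.asarray(cooccur_counts)
    if atac_counts.shape != cooccur_counts.shape:
        raise ValueError("count vectors must align")
    p_atac = nb_upper_pvalue(atac_counts, atac_background)
    if cooccur_background is None:
        try:
            cooccur_background = fit_nb(cooccur_counts)
        except ValueError:
            cooccur_background = None
    if cooccur_background is not None:
        p_cooccur = nb_upper_pvalue(cooccur_counts, cooccur_background)
    else:
        p_cooccur = np.ones_like(p_atac)
    z, p_combined = combine_stouffer(p_atac, p_cooccur)
    p_adj = adjust_benjamini_yekutieli(p_combined)
    ids = motif_ids if motif_ids is not None else [f"m{i}" for i in range(atac_counts.size)]
    return [
        BMOScore(
            motif_id=ids[i],
            atac_count=int(atac_counts[i]),
            cooccur_count=int(cooccur_counts[i]),
            p_atac=float(np.atleast_1d(p_atac)[i]),
            p_cooccur=float(np.atleast_1d(p_cooccur)[i]),
            z_combined=float(z[i]),
            p_combined=float(p_combined[i]),
            p_adjusted=float(p_adj[i]),
            bound=bool(p_adj[i] < alpha),
        )
        for i in range(atac_counts.size)
    ]


def _outside_peaks(motifs: list[FeatureInterval], peaks: PeakSet) -> np.ndarray:
    """Boolean mask: True where a motif does not overlap any peak."""
    out = np.ones(len(motifs), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    for c in by_chrom:
        by_chrom[c].sort()
    for i, m in enumerate(motifs):
        ivs = by_chrom.get(m.chrom)
        if not ivs:
            continue
        starts = [s for s, _ in ivs]
        j = np.searchsorted(starts, m.end)
        for s, e in ivs[max(0, j - len(ivs)) : j]:
            if s < m.end and m.start < e:
                out[i] = False
                break
    return out


def bmo_predict(
    motifs: list[FeatureInterval],
    fragments: list[FragmentRecord],
    peaks: PeakSet,
    flank: int = BMO_FLANK,
    n_sample: int = 10_000,
    n_reps: int = 100,
    alpha: float = BOUND_ALPHA,
    rng: np.random.Generator | int | None = None,
) -> list[BMOScore]:
    """Full BMO pipeline for one PWM's motif instances.

    Counts flanking fragments and co-occurring instances, fits the
    accessibility background on instances outside ``peaks`` (resampled
    ``n_reps`` x ``n_sample``) and the co-occurrence NB on all instances,
    combines the two upper-tail p-values per instance and calls bound at
    BY-adjusted p < ``alpha``. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(rng)
    atac_counts = count_flanking_fragments(motifs, fragments, flank)
    cooccur_counts = count_cooccurring(motifs, flank)
    outside = _outside_peaks(motifs, peaks)
    if not outside.any():
        raise ValueError("no motif instances outside peaks to fit the background")
    background = fit_background(atac_counts[outside], n_sample, n_reps, rng)
    return score_counts(
        atac_counts,
        cooccur_counts,
        background,
        alpha=alpha,
        motif_ids=[m.name for m in motifs],
    )
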