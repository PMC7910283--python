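"""Permutation and classification statistics downstream of CIE / f-VICE.

Includes the CIE left/right asymmetry flip test, the TSS direction bias and
its binomial concordance check, Gaussian-mixture splitting of f-VICE
distributions, rank-sum enrichment of motif groups (DNA-binding domains),
quantile-matched downsampling for confounder control, the k-mer decile
symmetry test, canonical k-mer utilities and binary-classification metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .information import cie_profile, expected_profile, observed_profile
from .io import FeatureInterval
from .vplot import DEFAULT_MAX_SIZE, DEFAULT_MIN_SIZE, WindowGrid

__all__ = [
    "AsymmetryResult",
    "MixtureFit",
    "EnrichmentResult",
    "cie_asymmetry",
    "tss_direction_bias",
    "concordance_binomial",
    "fit_fvice_mixture",
    "rank_sum_enrichment",
    "quantile_matched_downsample",
    "decile_symmetry_test",
    "kmer_canonical_set",
    "hamming_neighbor_range",
    "f1_score",
    "pr_auc",
    "label_truth_by_containment",
]


# ---------------------------------------------------------------------------
# CIE asymmetry


@dataclass
class AsymmetryResult:
    """Left/right CIE asymmetry of a feature set.

    ``log2_ratio`` compares the summed positive CIE in windows left of the
    oriented feature center with the right side; the null is generated by
    giving every fragment midpoint a 50% chance of mirroring about the
    center and recomputing the full CIE. The normal-extrapolated p
    (``z = (obs - null_mean)/null_sd``) is reported alongside the empirical
    p; the former is meaningful only when the null passes a normality check.
    """

    log2_ratio: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    p_empirical: float
    n_permutations: int
    normality_p: float
    defined: bool = True


def _positive_side_sums(cie: np.ndarray, centers: np.ndarray) -> tuple[float, float]:
    pos = np.clip(cie, 0.0, None)
    left = float(pos[centers < 0].sum())
    right = float(pos[centers > 0].sum())  # center exactly 0 excluded from both
    return left, right


def cie_asymmetry(
    per_feature_fragments: list[np.ndarray],
    grid: WindowGrid,
    n_permutations: int = 1000,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    rng: np.random.Generator | int | None = None,
    normality_alpha: float = 0.01,
) -> AsymmetryResult:
    """CIE asymmetry flip-permutation test on strand-oriented features."""
    rng = np.random.default_rng(rng)
    pooled = (
        np.concatenate([a for a in per_feature_fragments if len(a)])
        if any(len(a) for a in per_feature_fragments)
        else np.empty((0, 2), dtype=np.int64)
    )
    centers = grid.centers

    def statistic(frags: np.ndarray) -> float:
        obs = observed_profile([frags], grid, min_size, max_size)
        exp = expected_profile([frags], grid, min_size, max_size, 1, rng)
        prof = cie_profile(obs, exp, grid)
        left, right = _positive_side_sums(prof.cie, centers)
        if left == 0 or right == 0:
            return np.nan
        return float(np.log2(left / right))

    observed = statistic(pooled)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        flip = rng.random(len(pooled)) < 0.5
        flipped = pooled.copy()
        flipped[flip, 0] *= -1
        null[i] = statistic(flipped)
    defined = np.isfinite(observed) and np.isfinite(null).all()
    if not defined:
        return AsymmetryResult(
            log2_ratio=observed,
            null_mean=np.nan,
            null_sd=np.nan,
            z=np.nan,
            p=np.nan,
            p_empirical=np.nan,
            n_permutations=n_permutations,
            normality_p=np.nan,
            defined=False,
        )
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    z = (observed - null_mean) / null_sd
    normality_p = float(sps.shapiro(null[: min(len(null), 5000)]).pvalue)
    p_normal = float(2.0 * sps.norm.sf(abs(z)))
    p_emp = float(
        (1 + np.sum(np.abs(null - null_mean) >= abs(observed - null_mean)))
        / (n_permutations + 1)
    )
    p = p_normal if normality_p > normality_alpha else p_emp
    return AsymmetryResult(
        log2_ratio=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p=p,
        p_empirical=p_emp,
        n_permutations=n_permutations,
        normality_p=normality_p,
    )


def tss_direction_bias(
    features: list[FeatureInterval],
    tss_list: list[tuple[str, int]],
) -> float:
    """log2 ratio of nearest-TSS occurrences left vs right of oriented motifs.

    ``tss_list`` holds (chrom, position) points. For each motif the nearest
    TSS is classified as left or right in motif orientation; counts are
    aggregated and log2(left/right) returned, with a +1 pseudocount on both
    sides (and a warning) when either side is zero.
    """
    if not tss_list:
        raise ValueError("empty TSS list")
    by_chrom: dict[str, np.ndarray] = {}
    for c, p in tss_list:
        by_chrom.setdefault(c, []).append(p)  # type: ignore[arg-type]
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}
    left = right = 0
    for f in features:
        pts = by_chrom.get(f.chrom)
        if pts is None or len(pts) == 0:
            continue
        i = np.searchsorted(pts, f.center)
        cands = [pts[j] for j in (i - 1, i) if 0 <= j < len(pts)]
        nearest = min(cands, key=lambda p: abs(p - f.center))
        delta = nearest - f.center
        if delta == 0:
            continue
        if f.strand == "-":
            delta = -delta
        if delta < 0:
            left += 1
        else:
            right += 1
    if left == 0 or right == 0:
        warnings.warn("one side has zero TSS counts; applying +1 pseudocount", stacklevel=2)
        left += 1
        right += 1
    return float(np.log2(left / right))


def concordance_binomial(n_agree: int, n_total: int) -> float:
    """Exact two-sided binomial test of ``n_agree`` successes in ``n_total``
    trials at null probability 0.5 (two-sidedness by summing outcomes with
    point probability <= the observed one).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_agree <= n_total:
        raise ValueError("n_agree must lie in [0, n_total]")
    return float(sps.binomtest(n_agree, n_total, 0.5).pvalue)


# ---------------------------------------------------------------------------
# f-VICE mixture model


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture split of normalized f-VICEs."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    posteriors_high: np.ndarray
    high_labels: np.ndarray
    bic_mixture: float
    bic_single: float
    high_fraction: float
    threshold_posterior: float = 0.5


def fit_fvice_mixture(
    normalized_fvices: np.ndarray,
    bound_counts: np.ndarray | None = None,
    seed: int | None = 0,
    n_init: int = 10,
) -> MixtureFit:
    """Split motifs into high/low f-VICE classes with a 2-Gaussian mixture.

    Motifs whose total bound-instance count falls in the lowest decile are
    filtered first (sparse motifs are biased toward low f-VICE). The mixture
    is fitted by EM with ``n_init`` seeded restarts; the component with the
    larger mean is "high" and motifs with posterior(high) > 0.5 are labeled
    high. BIC is reported for the mixture and a single Gaussian.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(normalized_fvices, dtype=float)
    if bound_counts is not None:
        bound_counts = np.asarray(bound_counts)
        if bound_counts.shape != x.shape:
            raise ValueError("bound_counts must align with normalized_fvices")
        cutoff = np.quantile(bound_counts, 0.1)
        x = x[bound_counts > cutoff]
    if x.size < 20:
        raise ValueError("need at least 20 motifs after the lowest-decile filter")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all f-VICE values identical")
    X = x[:, None]
    gm2 = GaussianMixture(n_components=2, n_init=n_init, random_state=seed).fit(X)
    if not gm2.converged_:
        raise RuntimeError(
            f"mixture EM did not converge after {n_init} restarts "
            f"(lower bound {gm2.lower_bound_:.4g})"
        )
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(X)
    means = gm2.means_.ravel()
    order = np.argsort(means)  # low, high
    post = gm2.predict_proba(X)[:, order[1]]
    high = post > 0.5
    return MixtureFit(
        weights=gm2.weights_[order],
        means=means[order],
        sds=np.sqrt(gm2.covariances_.ravel())[order],
        posteriors_high=post,
        high_labels=high,
        bic_mixture=float(gm2.bic(X)),
        bic_single=float(gm1.bic(X)),
        high_fraction=float(high.mean()),
    )


# ---------------------------------------------------------------------------
# Rank-sum group enrichment


@dataclass
class EnrichmentResult:
    group_id: str
    n_members: int
    observed_rank_sum: float
    null_median: float
    log2_enrichment: float
    empirical_p: float
    fdr: float = np.nan


def rank_sum_enrichment(
    fvices: dict[str, float],
    group_map: dict[str, str],
    min_group: int = 5,
    n_perm: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> list[EnrichmentResult]:
    """f-VICE rank-sum enrichment per motif group (e.g. DNA-binding domain).

    Motifs are ranked ascending by f-VICE (midranks for ties; the largest
    f-VICE gets the largest rank). Each group's observed rank sum is
    compared with a null of ``n_perm`` label permutations that preserve all
    group sizes simultaneously. Enrichment is log2(observed / median null);
    the empirical p is one-sided toward the observed direction with the
    +1 correction, and BH FDR is computed across groups.
    """
    rng = np.random.default_rng(rng)
    members = list(fvices)
    missing = [m for m in group_map if m not in fvices]
    if missing:
        raise ValueError(f"group members missing from the f-VICE table: {missing[:5]}")
    ranks = sps.rankdata([fvices[m] for m in members])
    groups: dict[str, np.ndarray] = {}
    for g in sorted(set(group_map.values())):
        idx = np.array([i for i, m in enumerate(members) if group_map.get(m) == g])
        if idx.size < min_group:
            warnings.warn(f"group {g!r} has {idx.size} < {min_group} members; dropped",
                          stacklevel=2)
            continue
        groups[g] = idx
    if not groups:
        return []
    indicator = np.zeros((len(groups), len(members)))
    for r, idx in enumerate(groups.values()):
        indicator[r, idx] = 1.0
    observed = indicator @ ranks
    null = np.empty((n_perm, len(groups)))
    for i in range(n_perm):
        null[i] = indicator @ ranks[rng.permutation(len(members))]
    null_median = np.median(null, axis=0)
    results = []
    pvals = []
    for r, (g, idx) in enumerate(groups.items()):
        obs = observed[r]
        med = null_median[r]
        # tail toward the observed direction, doubled for two-sidedness
        # (the direction is chosen post hoc, so the undoubled tail would
        # reject at twice the nominal rate); rank sums are discrete, so ties
        # are counted into the tail with a roundoff guard
        if obs >= med:
            p_dir = (1 + np.sum(null[:, r] >= obs - 1e-9)) / (n_perm + 1)
        else:
            p_dir = (1 + np.sum(null[:, r] <= obs + 1e-9)) / (n_perm + 1)
        p = min(1.0, 2.0 * p_dir)
        pvals.append(p)
        results.append(
            EnrichmentResult(
                group_id=g,
                n_members=idx.size,
                observed_rank_sum=float(obs),
                null_median=float(med),
                log2_enrichment=float(np.log2(obs / med)),
                empirical_p=float(p),
            )
        )
    from statsmodels.stats.multitest import multipletests

    fdr = multipletests(pvals, method="fdr_bh")[1]
    for res, q in zip(results, fdr):
        res.fdr = float(q)
    return results


# ---------------------------------------------------------------------------
# Quantile-matched downsampling


def quantile_matched_downsample(
    covariates_a: "np.ndarray | dict[str, np.ndarray]",
    covariates_b: "np.ndarray | dict[str, np.ndarray]",
    n_quantiles: int = 20,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Match two feature sets on covariates by per-quantile downsampling.

    ``covariates_*`` map covariate name -> value per element (a bare array is
    treated as a single covariate). Covariates are processed sequentially;
    for each, quantile bin edges are computed on the union of the two
    current sets and, within each bin, the set with more elements is
    downsampled without replacement to the other's bin count. Returns index
    arrays into the original sets.
    """
    if not isinstance(covariates_a, dict):
        covariates_a = {"cov": np.asarray(covariates_a)}
        covariates_b = {"cov": np.asarray(covariates_b)}
    if set(covariates_a) != set(covariates_b):
        raise ValueError("both sets must carry the same covariates")
    rng = np.random.default_rng(rng)
    idx_a = np.arange(len(next(iter(covariates_a.values()))))
    idx_b = np.arange(len(next(iter(covariates_b.values()))))
    for name in covariates_a:
        va = np.asarray(covariates_a[name])[idx_a]
        vb = np.asarray(covariates_b[name])[idx_b]
        edges = np.quantile(np.concatenate([va, vb]), np.linspace(0, 1, n_quantiles + 1))
        edges[0], edges[-1] = -np.inf, np.inf
        bins_a = np.digitize(va, edges[1:-1])
        bins_b = np.digitize(vb, edges[1:-1])
        keep_a: list[np.ndarray] = []
        keep_b: list[np.ndarray] = []
        for q in range(n_quantiles):
            in_a = np.nonzero(bins_a == q)[0]
            in_b = np.nonzero(bins_b == q)[0]
            if in_a.size == 0 or in_b.size == 0:
                if in_a.size != in_b.size:
                    warnings.warn(
                        f"covariate {name!r} quantile {q}: one set empty; bin dropped",
                        stacklevel=2,
                    )
                continue
            n = min(in_a.size, in_b.size)
            keep_a.append(rng.choice(in_a, size=n, replace=False) if in_a.size > n else in_a)
            keep_b.append(rng.choice(in_b, size=n, replace=False) if in_b.size > n else in_b)
        sel_a = np.sort(np.concatenate(keep_a)) if keep_a else np.array([], dtype=int)
        sel_b = np.sort(np.concatenate(keep_b)) if keep_b else np.array([], dtype=int)
        idx_a, idx_b = idx_a[sel_a], idx_b[sel_b]
    return idx_a, idx_b


# ---------------------------------------------------------------------------
# k-mer decile symmetry


def decile_symmetry_test(
    transitions_selected: np.ndarray,
    transitions_all: np.ndarray,
    n_perm: int = 1_000_000,
    pseudocount: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, float, float]:
    """Directional-bias test on k-mer f-VICE decile transition counts.

    X_ij = log2((selected_ij / sum selected) / (all_ij / sum all)) with a
    pseudocount on every cell; the diagonal is ignored. The statistic is
    T = sum_{i<j} (X_ij - X_ji); the null gives every symmetric pair a 50%
    chance of swapping its two log-ratio values (which flips that pair's
    contribution). Returns (X, T, two-sided empirical p).
    """
    sel = np.asarray(transitions_selected, dtype=float)
    all_ = np.asarray(transitions_all, dtype=float)
    if sel.ndim != 2 or sel.shape[0] != sel.shape[1] or sel.shape != all_.shape:
        raise ValueError("transition matrices must be square and same shape")
    rng = np.random.default_rng(rng)
    sel = sel + pseudocount
    all_ = all_ + pseudocount
    X = np.log2((sel / sel.sum()) / (all_ / all_.sum()))
    n = X.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    diffs = X[iu, ju] - X[ju, iu]
    T = float(diffs.sum())
    signs = rng.integers(0, 2, size=(n_perm, diffs.size)) * 2 - 1
    T_null = signs @ diffs
    # ties count into the tail (conservative); the epsilon guards exact ties
    # against summation-order roundoff
    p = float((1 + np.sum(np.abs(T_null) >= abs(T) - 1e-12)) / (n_perm + 1))
    return X, T, p


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


def kmer_canonical_set(k: int = 6) -> list[str]:
    """Canonical DNA k-mers: the lexicographically smaller member of each
    reverse-complement pair, excluding palindromic k-mers (a k-mer equal to
    its own reverse complement). For k = 6 this yields (4096 - 64)/2 = 2016.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    from itertools import product

    out = []
    for tup in product("ACGT", repeat=k):
        kmer = "".join(tup)
        rc = revcomp(kmer)
        if kmer < rc:
            out.append(kmer)
    return out


def canonicalize(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def hamming_neighbor_range(
    kmer: str, fvice_table: dict[str, float]
) -> tuple[float, float, float]:
    """f-VICE variation across the Hamming-1 neighborhood of a k-mer.

    The 3k single-substitution neighbors are mapped to canonical form and
    looked up in ``fvice_table``; neighbors without a value (e.g.
    palindromes absent from the canonical set) are skipped with a warning.
    Returns (max_delta, min_delta, range) where deltas are relative to the
    focal k-mer's f-VICE and range is the absolute difference between the
    highest- and lowest-f-VICE neighbors (their 1-D Euclidean distance).
    """
    focal = fvice_table.get(canonicalize(kmer))
    if focal is None:
        raise KeyError(f"focal k-mer {kmer} not in the f-VICE table")
    values = []
    skipped = 0
    for pos in range(len(kmer)):
        for base in "ACGT":
            if base == kmer[pos]:
                continue
            nb = canonicalize(kmer[:pos] + base + kmer[pos + 1 :])
            v = fvice_table.get(nb)
            if v is None:
                skipped += 1
                continue
            values.append(v)
    if skipped:
        warnings.warn(f"{skipped} neighbor(s) of {kmer} missing from the table", stacklevel=2)
    if not values:
        raise ValueError(f"no scored neighbors for {kmer}")
    values = np.asarray(values)
    return (
        float(values.max() - focal),
        float(values.min() - focal),
        float(values.max() - values.min()),
    )


# ---------------------------------------------------------------------------
# Binding-prediction evaluation


def label_truth_by_containment(
    motifs: list[FeatureInterval], chip_peaks
) -> np.ndarray:
    """True-positive labels: a motif is bound iff fully contained in a peak."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in chip_peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    labels = np.zeros(len(motifs), dtype=bool)
    for i, m in enumerate(motifs):
        for s, e in by_chrom.get(m.chrom, []):
            if s <= m.start and m.end <= e:
                labels[i] = True
                break
    return labels


def f1_score(predicted_bound: np.ndarray, truth_bound: np.ndarray) -> float:
    """F1 = 2 * precision * recall / (precision + recall); NaN (with a
    warning) when the truth has no positives.
    """
    pred = np.asarray(predicted_bound, dtype=bool)
    truth = np.asarray(truth_bound, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth vectors must align")
    if not truth.any():
        warnings.warn("no positives in truth; F1 undefined", stacklevel=2)
        return float("nan")
    tp = np.sum(pred & truth)
    if tp == 0:
        return 0.0
    precision = tp / pred.sum()
    recall = tp / truth.sum()
    return float(2 * precision * recall / (precision + recall))


def pr_auc(scores: np.ndarray, truth_bound: np.ndarray) -> float:
    """Area under the precision-recall curve by trapezoidal integration over
    the ranked scores.
    """
    from sklearn.metrics import precision_recall_curve

    truth = np.asarray(truth_bound, dtype=bool)
    if not truth.any():
        warnings.warn("no positives in truth; AUPR undefined", stacklevel=2)
        return float("nan")
    precision, recall, _ = precision_recall_curve(truth, np.asarray(scores, dtype=float))
    order = np.argsort(recall)
    return float(np.trapezoid(precision[order], recall[order]))
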