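"""Oriented V-plot count matrices.

A V-plot is a 2-D histogram of ATAC-seq fragment midpoints around a set of
aligned genomic features (e.g. TF motif instances): the x-axis is midpoint
position relative to the oriented feature center, the y-axis is fragment
size. Bound TFs flanked by well-phased nucleosomes produce the stereotyped
"V" pattern of short protected fragments at the center and nucleosome-sized
fragments at phased offsets.

Positions are summed in overlapping sliding windows (default 10 bp wide,
8 bp apart) to reduce sparsity; fragment sizes are never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FeatureInterval, FragmentRecord

__all__ = [
    "WindowGrid",
    "VPlotMatrix",
    "build_window_grid",
    "select_features",
    "collect_relative_fragments",
    "aggregate_vplot",
    "downsample_for_display",
    "DEFAULT_FLANK",
    "DEFAULT_WIDTH",
    "DEFAULT_STEP",
    "DEFAULT_MIN_SIZE",
    "DEFAULT_MAX_SIZE",
]

DEFAULT_FLANK = 500
DEFAULT_WIDTH = 10
DEFAULT_STEP = 8
DEFAULT_MIN_SIZE = 41
DEFAULT_MAX_SIZE = 500


@dataclass(frozen=True)
class WindowGrid:
    """Sliding position windows relative to the feature center.

    Window k is the half-open interval ``[starts[k], starts[k] + width)``.
    Starts begin at ``-flank`` and advance by ``step`` while
    ``start <= flank - width``; with ``step < width`` consecutive windows
    overlap by ``width - step`` bp.
    """

    flank: int
    width: int
    step: int
    starts: np.ndarray = field(repr=False)

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.width / 2.0

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def window_indices(self, rel_positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map relative midpoint positions to (position_idx, window_idx) pairs.

        A midpoint in the overlap of two consecutive windows yields one pair
        per containing window (it is counted in both, matching independent
        per-window summation).
        """
        rel = np.asarray(rel_positions)
        # window k contains x iff starts[k] <= x < starts[k] + width;
        # with starts[k] = -flank + k*step the candidate ks form a short run.
        k_hi = np.floor((rel + self.flank) / self.step).astype(np.int64)
        n_cand = int(np.ceil(self.width / self.step))
        pos_idx: list[np.ndarray] = []
        win_idx: list[np.ndarray] = []
        for d in range(n_cand):
            k = k_hi - d
            ok = (k >= 0) & (k < self.n_windows)
            inside = np.zeros_like(ok)
            s = self.starts[np.clip(k, 0, self.n_windows - 1)]
            inside[ok] = (s[ok] <= rel[ok]) & (rel[ok] < s[ok] + self.width)
            keep = ok & inside
            pos_idx.append(np.nonzero(keep)[0])
            win_idx.append(k[keep])
        return np.concatenate(pos_idx), np.concatenate(win_idx)


def build_window_grid(
    flank: int = DEFAULT_FLANK, width: int = DEFAULT_WIDTH, step: int = DEFAULT_STEP
) -> WindowGrid:
    """Build the sliding-window grid covering ``[-flank, flank]``.

    Defaults give 124 windows [-500,-490), [-492,-482), ..., [484,494).
    """
    if width <= 0 or step <= 0:
        raise ValueError("window width and step must be positive")
    if flank < width:
        raise ValueError("flank must be at least the window width")
    starts = np.arange(-flank, flank - width + 1, step, dtype=np.int64)
    return WindowGrid(flank=flank, width=width, step=step, starts=starts)


@dataclass
class VPlotMatrix:
    """Fragment counts indexed by (fragment size, position window).

    Row i corresponds to fragment size ``min_size + i``; column k to window
    k of ``grid``. ``n_fragments`` counts distinct fragments binned — because
    windows overlap, ``counts.sum()`` may exceed it.
    """

    counts: np.ndarray
    grid: WindowGrid
    min_size: int
    max_size: int
    n_features: int
    n_fragments: int

    def __post_init__(self) -> None:
        expected = (self.max_size - self.min_size + 1, self.grid.n_windows)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != expected {expected}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def size_axis(self) -> np.ndarray:
        return np.arange(self.min_size, self.max_size + 1)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VPlotMatrix):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and np.array_equal(self.grid.starts, other.grid.starts)
            and (self.grid.width, self.grid.step) == (other.grid.width, other.grid.step)
            and (self.min_size, self.max_size) == (other.min_size, other.max_size)
            and (self.n_features, self.n_fragments) == (other.n_features, other.n_fragments)
        )


def select_features(
    features: list[FeatureInterval], min_separation: int = 500
) -> list[FeatureInterval]:
    """Drop features closer than ``min_separation`` bp (center-to-center) to
    any other feature on the same chromosome; both members of a violating
    pair are removed to avoid V-plot interference from neighbours.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, f in enumerate(features):
        by_chrom.setdefault(f.chrom, []).append((f.center, i))
    drop: set[int] = set()
    for entries in by_chrom.values():
        entries.sort()
        for (c1, i1), (c2, i2) in zip(entries, entries[1:]):
            if c2 - c1 < min_separation:
                drop.add(i1)
                drop.add(i2)
    return [f for i, f in enumerate(features) if i not in drop]


def collect_relative_fragments(
    features: list[FeatureInterval],
    fragments: list[FragmentRecord],
    grid: WindowGrid,
    min_fragment_size: int = DEFAULT_MIN_SIZE,
    max_fragment_size: int = DEFAULT_MAX_SIZE,
) -> list[np.ndarray]:
    """Collect (relative_midpoint, size) pairs per feature.

    The relative midpoint is ``fragment.midpoint - feature.center``, sign-
    flipped for minus-strand features so every feature is oriented 5'->3'
    (strand "." is treated as "+"). Fragments outside ``[-flank, flank]`` or
    the size bounds are dropped.

    Returns one ``(n_i, 2)`` integer array per feature, columns
    (relative_midpoint, size).
    """
    if not fragments:
        return [np.empty((0, 2), dtype=np.int64) for _ in features]
    frag_chrom = np.array([fr.chrom for fr in fragments])
    frag_mid = np.array([fr.midpoint for fr in fragments], dtype=np.int64)
    frag_size = np.array([fr.size for fr in fragments], dtype=np.int64)
    size_ok = (frag_size >= min_fragment_size) & (frag_size <= max_fragment_size)
    order = np.argsort(frag_mid, kind="stable")
    frag_chrom, frag_mid, frag_size, size_ok = (
        frag_chrom[order],
        frag_mid[order],
        frag_size[order],
        size_ok[order],
    )
    # index midpoints per chromosome for windowed lookup
    per_chrom: dict[str, np.ndarray] = {}
    for c in np.unique(frag_chrom):
        per_chrom[c] = np.nonzero(frag_chrom == c)[0]
    out: list[np.ndarray] = []
    for f in features:
        idx = per_chrom.get(f.chrom)
        if idx is None:
            out.append(np.empty((0, 2), dtype=np.int64))
            continue
        mids = frag_mid[idx]
        lo = np.searchsorted(mids, f.center - grid.flank, side="left")
        hi = np.searchsorted(mids, f.center + grid.flank, side="right")
        sel = idx[lo:hi]
        sel = sel[size_ok[sel]]
        rel = frag_mid[sel] - f.center
        if f.strand == "-":
            rel = -rel
        out.append(np.column_stack([rel, frag_size[sel]]).astype(np.int64))
    return out


def aggregate_vplot(
    per_feature_fragments: list[np.ndarray],
    grid: WindowGrid,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> VPlotMatrix:
    """Aggregate per-feature (relative_midpoint, size) pairs into the V-plot
    count matrix. Each window is summed independently, so a midpoint in the
    overlap of consecutive windows contributes to both.
    """
    n_sizes = max_size - min_size + 1
    counts = np.zeros((n_sizes, grid.n_windows), dtype=np.int64)
    n_fragments = 0
    if per_feature_fragments:
        pooled = np.concatenate(
            [a for a in per_feature_fragments if len(a)] or [np.empty((0, 2), dtype=np.int64)]
        )
    else:
        pooled = np.empty((0, 2), dtype=np.int64)
    if len(pooled):
        rel, sizes = pooled[:, 0], pooled[:, 1]
        keep = (sizes >= min_size) & (sizes <= max_size)
        rel, sizes = rel[keep], sizes[keep]
        pos_idx, win_idx = grid.window_indices(rel)
        np.add.at(counts, (sizes[pos_idx] - min_size, win_idx), 1)
        # a fragment is counted once even if binned in two overlapping windows
        n_fragments = int(np.count_nonzero(np.bincount(pos_idx, minlength=len(rel)) > 0))
    return VPlotMatrix(
        counts=counts,
        grid=grid,
        min_size=min_size,
        max_size=max_size,
        n_features=len(per_feature_fragments),
        n_fragments=n_fragments,
    )


def downsample_for_display(
    per_feature_fragment_sets: dict[str, list[np.ndarray]],
    total_fragments: int = 250_000,
    rng: np.random.Generator | int | None = None,
) -> dict[str, list[np.ndarray]]:
    """Equalise feature and fragment numbers across V-plot inputs for visual
    comparison (never for CIE / f-VICE computation).

    For every input set, the top ``k`` features ranked by fragment count are
    kept, where ``k`` is the smallest feature count among the inputs, and the
    pooled fragments are then downsampled without replacement to
    ``total_fragments``.
    """
    if len(per_feature_fragment_sets) < 2:
        raise ValueError("need at least two V-plot inputs to match")
    rng = np.random.default_rng(rng)
    k = min(len(v) for v in per_feature_fragment_sets.values())
    out: dict[str, list[np.ndarray]] = {}
    for label, feats in per_feature_fragment_sets.items():
        order = np.argsort([-len(a) for a in feats], kind="stable")[:k]
        kept = [feats[i] for i in sorted(order)]
        n_avail = sum(len(a) for a in kept)
        if total_fragments > n_avail:
            raise ValueError(
                f"{label}: requested {total_fragments} fragments but only {n_avail} available"
            )
        lengths = np.array([len(a) for a in kept])
        owner = np.repeat(np.arange(len(kept)), lengths)
        within = np.concatenate([np.arange(n) for n in lengths]) if len(kept) else np.array([], int)
        chosen = rng.choice(len(owner), size=total_fragments, replace=False)
        sub: list[np.ndarray] = [np.empty((0, 2), dtype=np.int64)] * len(kept)
        for fi in range(len(kept)):
            take = within[chosen[owner[chosen] == fi]]
            sub[fi] = kept[fi][np.sort(take)]
        out[label] = sub
    return out
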