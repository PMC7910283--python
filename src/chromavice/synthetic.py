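"""Synthetic ATAC-seq-like data with controllable TF/nucleosome structure.

Every pipeline stage is exercisable without external data. The fragment
generator emulates the stereotyped "V" pattern around a bound TF with
well-phased flanking nucleosomes: short sub-nucleosomal fragments protected
by the TF near the feature center, mononucleosome-sized fragments at phased
offsets, and a position-independent background. A single organization
parameter ``theta`` interpolates between fully unstructured chromatin
(position and size independent; CIE ~ 0) and fully phased chromatin
(strong V; high f-VICE). The background draws its sizes from the same
marginal mixture as the structured fragments, so varying ``theta`` changes
the position-size coupling without changing the marginal size histogram.

What this does NOT emulate: Tn5 sequence bias, GC effects, read-level noise,
chromosome-scale coverage variation, or real nucleosome repeat-length
heterogeneity — conclusions from these simulations are about the estimators,
not about any particular genome.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import FeatureInterval, FragmentRecord, PeakSet

__all__ = [
    "PhasingModel",
    "SyntheticTruth",
    "simulate_vplot_fragments",
    "simulate_asymmetric_features",
    "simulate_bmo_genome",
]


@dataclass(frozen=True)
class PhasingModel:
    """Generative model of fragment (position, size) pairs around a feature.

    ``theta`` is the organized fraction. Structured fragments are a mixture
    of TF-protected short fragments at the center and mononucleosomal
    fragments at the phased ``nucleosome_offsets`` (+/-115 and +/-305 bp
    mimic a ~190 bp repeat flanking a ~30 bp protected core). Background
    fragments have uniform positions in [-flank, flank] and sizes drawn
    from the pooled structured marginal.
    """

    theta: float = 0.5
    short_size_mean: float = 80.0
    short_size_sd: float = 20.0
    short_size_bounds: tuple[int, int] = (41, 120)
    mono_size_mean: float = 185.0
    mono_size_sd: float = 25.0
    nucleosome_offsets: tuple[int, ...] = (-305, -115, 115, 305)
    positional_jitter_sd: float = 15.0
    short_fraction: float = 0.5  # of structured fragments
    flank: int = 500
    min_size: int = 41
    max_size: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must be in [0, 1], got {self.theta}")


def _truncated_normal_int(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.rint(rng.normal(mean, sd, size=2 * (n - filled))).astype(np.int64)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _sample_sizes(rng: np.random.Generator, is_short: np.ndarray, model: PhasingModel) -> np.ndarray:
    n = len(is_short)
    sizes = np.empty(n, dtype=np.int64)
    n_short = int(is_short.sum())
    lo_s, hi_s = model.short_size_bounds
    sizes[is_short] = _truncated_normal_int(
        rng, n_short, model.short_size_mean, model.short_size_sd, max(lo_s, model.min_size), hi_s
    )
    sizes[~is_short] = _truncated_normal_int(
        rng, n - n_short, model.mono_size_mean, model.mono_size_sd, model.min_size, model.max_size
    )
    return sizes


def _sample_feature(
    rng: np.random.Generator, n: int, model: PhasingModel, left_prob: float = 0.5
) -> np.ndarray:
    """Draw n (relative_position, size) pairs for one feature.

    ``left_prob`` biases the position sign of structured fragments (0.5 is
    symmetric); used by :func:`simulate_asymmetric_features`.
    """
    structured = rng.random(n) < model.theta
    is_short = rng.random(n) < model.short_fraction
    sizes = _sample_sizes(rng, is_short, model)
    pos = np.empty(n, dtype=np.int64)
    # background: position independent of size
    bg = ~structured
    pos[bg] = rng.integers(-model.flank, model.flank + 1, size=int(bg.sum()))
    # structured: size-position coupling
    st = structured
    n_st = int(st.sum())
    jitter = rng.normal(0.0, model.positional_jitter_sd, size=n_st)
    anchors = np.empty(n_st)
    st_short = is_short[st]
    anchors[st_short] = 0.0
    offsets = np.asarray(model.nucleosome_offsets, dtype=float)
    n_nuc = int((~st_short).sum())
    anchors[~st_short] = np.abs(rng.choice(offsets, size=n_nuc))
    # assign sides: short fragments sit at the center (side irrelevant for
    # anchor 0 but the jitter sign carries the bias); nucleosomal anchors
    # are mirrored to the left with probability left_prob.
    side = np.where(rng.random(n_st) < left_prob, -1.0, 1.0)
    raw = side * anchors + side * np.abs(jitter)
    pos[st] = np.clip(np.rint(raw), -model.flank, model.flank).astype(np.int64)
    return np.column_stack([pos, sizes])


def simulate_vplot_fragments(
    n_features: int,
    n_frag_per_feature: int,
    model: PhasingModel,
    rng: np.random.Generator | int | None = None,
) -> list[np.ndarray]:
    """Per-feature lists of (relative_midpoint, size) pairs under ``model``."""
    if n_features <= 0 or n_frag_per_feature <= 0:
        raise ValueError("n_features and n_frag_per_feature must be positive")
    rng = np.random.default_rng(rng)
    return [_sample_feature(rng, n_frag_per_feature, model) for _ in range(n_features)]


def simulate_asymmetric_features(
    n_features: int,
    n_frag_per_feature: int,
    bias: float = 0.0,
    model: PhasingModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[np.ndarray]:
    """Fragment lists with a left/right structural imbalance.

    A fraction ``(1 + bias)/2`` of structured fragments is placed left of
    the center; ``bias = 0`` is symmetric, positive bias enriches the left.
    """
    if not -1.0 <= bias <= 1.0:
        raise ValueError("bias must lie in [-1, 1]")
    rng = np.random.default_rng(rng)
    model = model or PhasingModel()
    left_prob = (1.0 + bias) / 2.0
    return [
        _sample_feature(rng, n_frag_per_feature, model, left_prob=left_prob)
        for _ in range(n_features)
    ]


# ---------------------------------------------------------------------------
# BMO genome


@dataclass
class SyntheticTruth:
    """Ground-truth bound labels and the generating parameters."""

    bound: dict[str, bool]
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def simulate_bmo_genome(
    n_motifs: int = 1000,
    frac_bound: float = 0.2,
    mu_bound: float = 20.0,
    mu_bg: float = 2.0,
    size_nb: float = 5.0,
    cooccur_rates: tuple[float, float] = (1.0, 0.05),
    peak_min_count: float | None = None,
    motif_width: int = 10,
    spacing: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[FeatureInterval], list[FragmentRecord], PeakSet, SyntheticTruth]:
    """Synthetic single-PWM genome for end-to-end BMO testing.

    Motif anchors are placed with >= ``spacing`` bp separation on one
    chromosome; each is bound with probability ``frac_bound``. With
    probability ``cooccur_rates[label]`` (bound, background) a same-PWM
    partner instance is planted within +/-100 bp (sharing the anchor's
    label). Each instance receives NB(mu_label, size_nb) flanking fragments
    whose Tn5 integration sites avoid the motif body. Peaks cover anchors
    whose drawn count reaches ``peak_min_count`` (default: the midpoint of
    the two means), mimicking accessibility peak calls.
    """
    if mu_bound <= mu_bg:
        raise ValueError("mu_bound must exceed mu_bg")
    if not 0.0 <= frac_bound <= 1.0:
        raise ValueError("frac_bound must lie in [0, 1]")
    rng = np.random.default_rng(seed if rng is None else rng)
    if peak_min_count is None:
        peak_min_count = (mu_bound + mu_bg) / 2.0
    chrom = "chrS"
    rate_bound, rate_bg = cooccur_rates

    motifs: list[FeatureInterval] = []
    labels: dict[str, bool] = {}
    anchor_info: list[tuple[FeatureInterval, bool]] = []
    for i in range(n_motifs):
        center = spacing // 2 + i * spacing
        bound = bool(rng.random() < frac_bound)
        start = center - motif_width // 2
        anchor = FeatureInterval(chrom, start, start + motif_width, f"m{i:05d}",
                                 float(rng.uniform(5, 15)), "+")
        motifs.append(anchor)
        labels[anchor.name] = bound
        anchor_info.append((anchor, bound))
        if rng.random() < (rate_bound if bound else rate_bg):
            # plant a co-occurring partner 30-90 bp away
            d = int(rng.integers(30, 91)) * (1 if rng.random() < 0.5 else -1)
            pstart = start + d
            partner = FeatureInterval(chrom, pstart, pstart + motif_width,
                                      f"m{i:05d}p", float(rng.uniform(5, 15)), "+")
            motifs.append(partner)
            labels[partner.name] = bound
            anchor_info.append((partner, bound))

    frag_size = 36
    fragments: list[FragmentRecord] = []
    peaks_iv: list[FeatureInterval] = []
    nb_p = size_nb / (size_nb + mu_bound)
    nb_p_bg = size_nb / (size_nb + mu_bg)
    for m, bound in anchor_info:
        k = int(rng.negative_binomial(size_nb, nb_p if bound else nb_p_bg))
        # fragment start offsets relative to the motif center such that the
        # fragment overlaps the +/-100 bp window and both integration sites
        # (start, end-1) miss the motif body
        c = m.center
        allowed_lo = c - 100 - frag_size + 1
        allowed_hi = c + 100 - 1
        placed = 0
        while placed < k:
            s = int(rng.integers(allowed_lo, allowed_hi + 1))
            e = s + frag_size
            cut5, cut3 = s, e - 1
            if (m.start <= cut5 < m.end) or (m.start <= cut3 < m.end):
                continue
            fragments.append(FragmentRecord(chrom, s, e))
            placed += 1
        if k >= peak_min_count:
            peaks_iv.append(FeatureInterval(chrom, max(0, c - 200), c + 200,
                                            f"peak_{m.name}"))
    truth = SyntheticTruth(
        bound=labels,
        params={
            "n_motifs": n_motifs,
            "frac_bound": frac_bound,
            "mu_bound": mu_bound,
            "mu_bg": mu_bg,
            "size_nb": size_nb,
            "cooccur_rates": list(cooccur_rates),
            "peak_min_count": peak_min_count,
        },
        seed=seed,
    )
    return motifs, fragments, PeakSet(peaks_iv, dialect="bed3"), truth
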