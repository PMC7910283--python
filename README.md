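# chromavice

Chromatin information metrics and TF occupancy prediction from ATAC-seq
fragments.

Most transcription factors (TFs) do not leave a detectable accessibility
"footprint" at their binding sites, which limits footprint-based occupancy
inference. What bound TFs often *do* leave is structure: a characteristic
organization of ATAC-seq fragment sizes around the motif — short,
TF-protected fragments over the site and mononucleosomal fragments at
phased flanking positions, the familiar "V" pattern of a V-plot. This
package quantifies that organization and uses it, together with a simple
occupancy model, to analyze TF–chromatin interactions:

- **V-plots** — 2-D histograms of fragment midpoint position (±500 bp,
  10-bp windows sliding by 8 bp) versus fragment size around oriented
  feature sets.
- **CIE (chromatin information enrichment)** — per window, the normalized
  Shannon information of the fragment-size distribution,
  `I(x) = 1 − H(x)/H_max`, compared against the information expected when
  fragment sizes are independent of position (size labels permuted against
  positions): `CIE = log2(I_obs / I_exp)`. This controls for the coverage
  dependence of raw information.
- **f-VICE** — a scalar summary of CIE at landmark positions,
  `Σ_{i=−25..25} CIE_i + (Σ_{−70..−50} CIE_i + Σ_{50..70} CIE_i)/2`
  (negative per-bp values clamped to zero), high when nucleosomes are
  well phased around the feature; plus the cross-motif normalizations
  (residuals of `f-VICE ~ log10(m) + log10(f)`, scaled to CTCF = 1).
- **BMO** — a bound/unbound predictor for motif instances combining two
  negative-binomial upper-tail tests (flanking ATAC fragments within
  ±100 bp, ignoring fragments that integrate in the motif; and same-PWM
  co-occurrence within ±100 bp) via Stouffer's Z, with Benjamini–Yekutieli
  correction and bound calls at adjusted p < 0.05.
- **Downstream statistics** — CIE left/right asymmetry (sign-flip
  permutation test with normal extrapolation), TSS direction bias and its
  exact binomial concordance test, Gaussian-mixture splitting of f-VICE
  distributions, rank-sum group enrichment (e.g. DNA-binding domains),
  quantile-matched downsampling, canonical k-mer utilities and the decile
  symmetry permutation test, F1/AUPR evaluation helpers.
- **Synthetic data** — a generator with a single organization parameter
  `theta` (plus a planted-truth BMO genome) so the whole pipeline is
  testable without any external data.

Intended for computational biologists working with ATAC-seq who want
footprint-free measures of TF–chromatin organization, or a light-weight,
testable reimplementation of these statistics for methods work.

## Worked example

```python
import numpy as np
from chromavice import build_window_grid, compute_cie, fvice, bmo_predict
from chromavice.synthetic import (
    PhasingModel, simulate_vplot_fragments, simulate_bmo_genome,
)

grid = build_window_grid()          # 124 windows, [-500, -490) ... [484, 494)
for theta in (0.0, 0.8):
    frags = simulate_vplot_fragments(n_features=100, n_frag_per_feature=500,
                                     model=PhasingModel(theta=theta), rng=1)
    profile = compute_cie(frags, grid, rng=2)
    print(f"theta={theta:.1f}  f-VICE={fvice(profile):6.2f}  "
          f"peak CIE={np.nanmax(profile.cie):.3f}")

motifs, fragments, peaks, truth = simulate_bmo_genome(n_motifs=500, seed=3)
scores = bmo_predict(motifs, fragments, peaks, rng=4)
pred = np.array([s.bound for s in scores])
y = np.array([truth.bound[s.motif_id] for s in scores])
tp = (pred & y).sum()
print(f"BMO: {pred.sum()} of {len(scores)} instances called bound, "
      f"precision={tp/pred.sum():.3f}, recall={tp/y.sum():.3f}")
```

Output:

```
theta=0.0  f-VICE=  1.70  peak CIE=0.126
theta=0.8  f-VICE= 41.60  peak CIE=0.856
BMO: 228 of 629 instances called bound, precision=1.000, recall=0.991
```

With unorganized chromatin (`theta=0`: fragment size independent of
position) CIE hovers near zero and f-VICE is small; with strong TF
protection and nucleosome phasing (`theta=0.8`) the windows near the
feature center carry ~0.86 bits of log2 enrichment and f-VICE rises to
~42. On the planted-truth genome, BMO recovers the bound instances almost
perfectly because they are both accessible and clustered.

The same stages are exposed as a CLI for file-based workflows — each
subcommand writes its outputs plus a JSON manifest of parameters, seeds
and input checksums:

```bash
chromavice simulate vplot --seed 3 --theta 0.8 --out-dir sim/
chromavice vplot --features sim/features.bed --fragments sim/fragments.bed --out matrix.tsv
chromavice cie   --features sim/features.bed --fragments sim/fragments.bed --out cie.tsv
chromavice fvice --features sim/features.bed --fragments sim/fragments.bed --out fvice.tsv
chromavice bmo --motifs motifs.bed --fragments frags.bed --peaks peaks.bed --out scores.tsv
```

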