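# Methods

This note records the model, the numerical choices, and the simulation
design implemented in `ecdna3d`, including where defaults were chosen and
why.

## Notation

An ecDNA cycle tiled at resolution `res` (default 5 kb) yields `Ne`
expanded bins `a = 0..Ne-1` (one per copy of each genomic bin, in cycle
order) and `Nc` collapsed bins `i` (one per distinct genomic location),
with copy sets `R_i` and multiplicities `|R_i|`. Coordinates are
`X ∈ R^{Ne×3}`, spatial distances `d_ab = ||X_a - X_b||`, circular
genomic distance `g_ab = min(|a-b|, Ne-|a-b|)`.

## Matrix assembly and normalization

The expanded-shape matrix is looked up per bin pair from a whole-genome
contact store (.cool/.mcool via a minimal h5py reader, or an in-memory
store). '-'-oriented segments reverse bin order only; counts need no strand
handling because the matrix is symmetric. Segment boundaries are snapped to
the grid by flooring the start and ceiling the end (logged). Collapsing
keeps the first copy of each location.

Generalized ICE: multiplicative diagonal balancing `N = C / (b bᵀ)` with
`b ← b·sqrt(rowsum/target)` iterated until every active row sum is within
`1e-5` of its target `|R_i|` (cap 1000 iterations; all-zero rows excluded
and logged). The balanced matrix is rescaled by `r = ΣC / Nc` so the
interaction scale is preserved; `r` is reported. Plain ICE (target 1) is
used when re-balancing expanded matrices.

## Reconstruction

Poisson model: collapsed entry `C_ij` has rate
`λ_ij = β Σ_{a∈R_i} Σ_{b∈R_j} d_ab^α`. The likelihood support is all
unordered pairs `i < j` plus the diagonal entries of duplicated bins
(`i = j`, summing over ordered distinct copy pairs `a ≠ b`); self-distances
are never modeled. The objective is

```
F(X, α, β) = Σ (λ_ij − C_ij ln λ_ij) + γ · Var({d_{a,a+1}})
```

with `γ = 0.05·Ne` by default. The printed form of the regularizer in the
source publication is dimensionally inconsistent with a variance; the
standard variance is the default and a `literal_regularizer` flag
reproduces the printed formula. The circular closing edge `(Ne-1, 0)` is
excluded from the spacing chain by default (flag available): circularity
is learned from the contacts themselves.

Optimization alternates two bounded L-BFGS-B steps — over `(α, β)` with
`α ∈ [−10, −0.01]`, `β ∈ (1e−6, ∞)`, and over `X` with each axis in
`[−1, 1]` — accepting a round only if the objective decreases, until the
relative objective change over a 10-round window falls below `1e-4` (cap
1000 rounds). Analytic gradients are used throughout (finite-difference
checked to ~1e−10 relative in tests). `β` is initialized at its
closed-form conditional MLE, `α` at −3. Five restarts by default; restart
seeds derive deterministically from one master seed; consensus mode
returns the best objective, ensemble mode all restarts.

Initialization: collapsed counts are first spread over copy pairs with
circular-distance weights `g^−3` (conserving collapsed sums exactly);
within-bin copy pairs take the average count of unique-bin pairs at the
same circular distance (nearest available distance as fallback, logged).
Wish distances `δ_ab = (E_ab/β₀)^{−1/3}` then drive a joint stress
minimization over `X` and, where duplication exists, free per-copy counts
`E` tied to the collapsed entries by a conservation penalty.

## Expansion and significant interactions

After fitting, collapsed counts are redistributed over copy rectangles in
proportion to `d_ab^α` with the *fitted* distances and decay, within-bin
copy pairs filled as in initialization, and the expanded matrix re-balanced
by plain ICE.

Interaction calling stratifies bin pairs by genomic distance and
moment-fits a negative binomial per stratum (`r = μ²/(σ²−μ)`,
`p = μ/σ²`) after removing Tukey-fence outliers (`[Q1−1.5·IQR,
Q3+1.5·IQR]`); strata with `σ² ≤ μ` fall back to Poisson (the NB limit).
Continuous normalized counts are assessed at their ceiling:
`p = P(e ≥ ⌈count⌉)`. Benjamini–Hochberg correction is applied jointly
across all pairs of a run; `q < 0.05` by default, optionally restricted to
strict 4-neighborhood local maxima. Distance models:

- **ref** — reference-genome distance, clamped at the ecDNA size
  (different chromosomes are maximally distant); strata merged greedily to
  at least `Ne/2` pairs.
- **circ** — circular distance; every stratum already holds `Ne` pairs.
- **spatial** — the ratio `g_ab / d_ab` per circular-distance stratum,
  scaled by a fixed constant (10 / median ratio) and rounded onto the NB
  support. Calls flag pairs spatially closer than the consensus structure
  explains.

Rows with outlier-low numbers of non-zero entries are excluded from
calling (ICE inflates their counts). A rescaling experiment re-runs
calling on `f·E` for factors 0.25–4; a factor is valid only if `σ² > μ`
at ≥90% of distinct distances, since variance scales with `f²` but the
mean with `f`. Louvain communities of the SI graph (networkx, seeded) and
crossing pairs `(x,z),(y,w)` with `x<y<z<w` summarize the topology.

## Simulation benchmark

Ground-truth geometry (construction version 1, constants frozen after
calibration):

1. **Base curve.** A random closed Fourier curve (harmonics 1–20, flat
   amplitude spectrum, amplitude 1.2) projected onto the unit sphere,
   resampled to uniform arc length at `ne` points. The spherical shell
   makes independently drawn bases genuinely dissimilar; a low-order
   radial-modulation hook exists but is off (amplitude 0).
2. **Constrictions.** `k ∈ {1,2,3}` pairs of arcs (width `ne/20`, centers
   ≥ `ne/8` apart genomically) pulled together to a small spatial gap with
   tapered displacements.
3. **Local folds.** ~`ne/5` windows of 5–15 bins displaced and re-projected
   to their original centroid distance ("shell sliding"), so folds change
   conformation without shrinking the global envelope; windows overlapping
   constriction arcs are protected. Fold seeds are separate from base
   seeds, so one base yields many fold variants; duplicated copies can
   share or differ in local substructure.
4. **Excluded volume.** Points closer than half the mean consecutive
   spacing are iteratively pushed apart; this keeps the power-law rates
   finite and the sampled matrices balanced (without it, near-coincident
   points dominate the likelihood and ICE degrades reconstruction).
5. **Sampling.** One Poisson draw per unordered pair with mean
   `β d^α`, `α ~ U[−3,−0.75]`, `β ~ U[1,10]`; duplication collapses via
   the exact indicator identity `C = A E Aᵀ`.

The full suite is 10 bases per `(k, ne)` cell over `k ∈ {1,2,3}`,
`ne ∈ {250,500,750}` (90 bases, 180 structures at 2 variants). The two
free amplitude constants were calibrated once, at full suite scale, so
that the same-base / different-base random-pair RMSD medians land in the
published regime (0.338 / 0.573); across seeds this implementation gives
≈ 0.33–0.35 and ≈ 0.51–0.53. The construction replaces unpublished
supplementary geometry and is versioned so results stay comparable.

## Evaluation

Alignment is Kabsch–Umeyama: centroid removal, rescale by the maximum
pairwise diameter, optimal orthogonal rotation by SVD. Reflections are
allowed by default (Hi-C cannot resolve chirality) with a flag to force
proper rotations. PCC is the Pearson correlation of off-diagonal pairwise
distances. The permutation test compares two equal-length windows against
`n` random circularly-wrapped windows with a +1 pseudocount. Bounding
boxes: PCA frame, or rotating calipers over convex-hull-face-flush frames
(PCA frame included among candidates, so calipers ≤ PCA always); the shape
ratio is min/max edge (0 for degenerate inputs). The flatness test refits
with `β` fixed under shrinking first-axis bounds; a genuinely 3D fold pays
a likelihood price below its true extent (we require a >0.5% relative
objective increase as a practical-significance threshold on top of a
one-sided rank-sum, because refit noise alone is detectable at ~0.01%).
`α` recovery is reported as mean `|α̂−α|/|α|`.

## Problem sizes and limitations

Defaults and test scales (Ne up to 750 in the suite, fits demonstrated at
Ne=250) were chosen to run on one CPU in minutes; they are this package's
choices, not prescribed constants. Known limitations: no .hic ingest
(no offline converter), no whole-genome or copy-number-aware
normalization beyond multiplicity targets, single consensus species per
matrix (no deconvolution of coexisting conformations), and the spatial-SI
scaling constant is a convention (see decisions ledger).
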