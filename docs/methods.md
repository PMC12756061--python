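# Methods

## Model and pipeline

`pseudogrn` reconstructs a directed, signed gene regulatory network from a
genes × cells expression matrix in four stages.

**1. Pseudotime and smoothing.** Cells are assigned a scalar pseudotime
and sorted (ties broken lexicographically by cell id, so runs are
deterministic). Expression is then averaged over a sliding window of
`window_width` consecutive sorted cells advanced by `window_step`
(defaults 5 and 1), producing `T = floor((n − width)/step) + 1` smoothed
profiles; trailing partial windows are dropped so every window averages
the same number of cells. The windows are the method's effective time
points. Only the cell *order* matters downstream: any strictly increasing
relabelling of pseudotime leaves the smoothed trajectory unchanged.

Two native pseudotime backends are provided, plus import of precomputed
values:

- *PCA*: each cell's coordinate on the first principal component of the
  gene-centred matrix, oriented so the root cell sits at the low end and
  shifted to start at 0. Appropriate when the trajectory is approximately
  linear in expression space.
- *Diffusion map*: a Gaussian-kernel affinity on the k-nearest-neighbour
  graph with per-cell adaptive bandwidth (distance to the k-th neighbour,
  default k = 15), made tie-inclusive — every neighbour within the
  boundary radius joins, and the kernel's unit self-affinity is kept — so
  duplicated cells remain exactly indistinguishable. The affinity is
  row-normalised to a transition operator; cells are embedded on the top
  `n_comps` (default 10) non-trivial eigenvectors, each weighted by
  λ/(1 − λ), the accumulated weight of that mode over all diffusion
  times. Weighting by λ alone lets the fast, high-frequency modes (whose
  eigenvalues decay slowly on kNN graphs) swamp the slow mode that
  carries the trajectory; the accumulated weight concentrates the
  embedding on the slow modes and makes distance-from-root a usable
  pseudotime. Pseudotime is the Euclidean distance from the root cell in
  this embedding.
- *Precomputed*: a two-column (cell, value) table from any external tool
  (Slingshot, PHATE, PAGA, ...), re-aligned to the matrix cell order.
  Branching trajectories must be reduced to a single lineage upstream;
  the pipeline consumes one linear ordering.

If no root cell is given, the cell with the smallest first-component
coordinate (after a deterministic sign convention: the dominant loading
entry is made positive) is the root. The root choice fixes the direction
of "time" and therefore which way the lag points; for real data the root
should be set explicitly from biological knowledge.

Optional preprocessing (median-library-size scaling per cell followed by
log1p) defaults on for the native backends — raw counts distort Euclidean
geometry — and off for precomputed pseudotime.

**2. Time-lagged divergence.** For every ordered pair (X, Z) of candidate
regulator and gene, the score is a divergence between X's windows
1..T−lag and Z's windows 1+lag..T (lag defaults to 1 window, a first-order
Markov assumption; no lag search is performed). The f-divergence families
(forward KL, symmetric KL, Jensen–Shannon, Pearson χ², symmetric Pearson,
Neyman χ²) are evaluated in discrete form Σ q·f(p/q), natural logs, on a
shared histogram: equal-width bins spanning the pooled sample range
(default 10 bins), counts smoothed with an additive pseudocount (default
0.5) and renormalised. The pseudocount is mandatory, not cosmetic: the
ratio divergences are undefined on empty bins. A zero-width pooled range
degenerates to uniform distributions for both samples, making constant
profiles score 0 against each other rather than crashing. Symmetric
variants average the two directions (½ of each), keeping them on the same
scale as their directional forms.

The IPMs act on the raw samples. Wasserstein-1 is ∫|F − G| dv (for
equal-size samples, the mean absolute difference of the sorted samples).
Energy distance is the all-pairs V-statistic 2·E|X−Z| − E|X−X′| − E|Z−Z′|,
computed via its CDF form 2∫(F − G)² dv. The Cramér distance is the
*unweighted* sum Σ_j (F(v_j) − G(v_j))² over the distinct pooled sample
values — deliberately a different estimator from energy (they coincide up
to the factor 2 only on unit-spaced supports, an identity the test suite
exploits to validate both), and its magnitude grows with the number of
distinct values. `--cramer-weighted` switches to the spacing-weighted
Cramér–von Mises integral for users who want a scale-equivariant form.

Note a structural property of all these scores: they compare the
*marginal* distributions of the two windowed samples. They are sensitive
to regulation because regulation shifts a target's value distribution,
but when several TFs have similar marginals the score cannot tell which
of them drives a given target. See "Known limitations".

**3. Penalized non-redundant selection.** For each target Z the candidate
set is the TF list minus Z itself (all genes when no TF list is given).
The first regulator is argmax D(X‖Z) and records its raw divergence;
thereafter each remaining candidate is scored as
D*(X‖Z) = D(X‖Z) − (λ/|S|)·Σ_{Y∈S} D(X‖Y) and the argmax joins the
selected set S, until every candidate is ranked. The recorded D* is the
value at the moment of selection and is never revised; the first pick's
penalty is defined as 0 (the only continuous completion of λ/|S| at
S = ∅). Ties break lexicographically by gene id. Edges are retained iff
the recorded D* is strictly positive. Larger λ (default 1.5) yields
sparser networks; with the selection order held fixed, each recorded D*
is non-increasing in λ, and the top-ranked regulator survives every λ
whenever its raw divergence is positive.

**4. Signing.** Each retained edge X → Z is labelled by the partial
correlation between X's lagged and Z's led window samples, conditioning
on the lagged samples of Z's other retained parents — the minimal
causally motivated set that stays well-posed at T ≈ 100 windows.
Residualisation is ordinary least squares with intercept; a 1e-6 ridge
is added when the normal equations are near-singular, and samples shorter
than |C| + 3 fall back to the unconditional correlation with a warning.
Positive → activation, negative → inhibition; an exact zero is labelled
activation with a warning.

## Evaluation

AUROC and AUPRC are computed over the universe of all ordered TF → gene
pairs on the reference gene set, minus self-pairs; candidate pairs absent
from the score table rank with score 0. The ranking score is the recorded
D* of *every* candidate (each candidate receives one), so the metrics do
not depend on the D* > 0 cutoff. AUROC uses midrank tie handling; AUPRC
is non-interpolated average precision with tied scores processed as one
block.

## Synthetic benchmark

The generator plants a signed network (edges drawn uniformly over
TF → gene pairs; weight magnitudes uniform on [0.5, 1.5], inhibitory with
probability 0.3) and integrates additive-sigmoidal dynamics

    g_{t+1} = clip≥0( g_t + η·(W·σ(g_t) + b − γ·g_t) + ε_t ),

with logistic σ, step η = 0.1, decay γ = 0.3, basal production b = 0.2,
and Gaussian process noise ε. All genes start at 0 (a differentiation
onset convention: unregulated genes then share one relaxation trajectory
toward b/γ, so divergence between genes isolates the effect of
regulation). The trajectory runs 40 steps by default, covering the
relaxation transient at these rates; cells are drawn at uniformly random
integer trajectory times *with replacement*, so pseudotime inference has
real work to do, and observations add Gaussian noise (default sd 0.1)
clipped at 0. The initial state is exposed (`init_state`) because some
mechanisms are only observable from particular starting points — a
repressed gene pinned at 0 from birth shows no sign signal, whereas one
started high visibly decays.

What the generator emulates: snapshot sampling along one differentiation
trajectory with hundreds of cells, lag-1 signed regulatory influence,
measurement noise. What it does not: dropout/zero-inflation, branching
lineages, batch effects, transcriptional bursting. Passing recovery tests
therefore demonstrate correctness of the pipeline's mechanics on clean
lag-1 dynamics, not performance on real scRNA-seq pathologies.

The recovery benchmark (20 genes, 5 TFs, 15 edges, 600 cells, process
noise 0.05, observation noise 0.1, Cramér, λ = 1.5, five replicate seeds)
runs the full pipeline per replicate and reports mean AUROC/AUPRC, a
shuffled-label null (a size-matched random edge set over the same
universe), and sign accuracy over true-positive edges. Problem sizes
throughout the tests (tens of genes, hundreds of cells) are chosen to
exercise every code path at interactive speed.

## Numerical choices

- Deterministic everywhere: SVD/eigh-based embeddings with fixed sign
  conventions (dominant loading positive), lexicographic tie-breaks in
  sorting and selection, seeded generators in simulation. Identical
  inputs, configuration and seed give byte-identical output files.
- Histogram bins are right-closed at the top edge; pseudocount
  guarantees strict positivity, so every f-divergence is finite.
- Diffusion-map eigenvalues are capped just below 1 before the
  λ/(1 − λ) weighting to avoid division blow-up on disconnected-like
  spectra (a genuinely disconnected kNN graph is a hard error advising a
  larger neighbourhood).
- Partial-correlation residualisation adds a 1e-6 ridge only when the
  conditioning design is near-singular (condition number > 1e8).
- Network files print scores with 6 significant digits and order rows by
  (target, selection rank) for reproducible diffs.

## Known limitations

- The divergence scores compare marginal window distributions and carry
  no pairing information; they detect *that* a target's distribution is
  shifted (i.e., that it is regulated) far better than *which* TF shifts
  it. On planted random networks this caps ranking performance well below
  what paired statistics (e.g., time-delayed mutual information) could
  reach: replacing inferred pseudotime with the true simulation time
  changes recovery AUROC only marginally (≈ 0.59 either way at the
  benchmark settings), showing the ceiling lies in the statistic, not in
  trajectory inference. The recovery benchmark reports this honestly
  rather than tuning around it.
- Sign labels rely on lag-aligned (partial) correlation, which matches
  the mechanistic weight sign reliably only in near-linear, single-parent
  contexts; feedback chains and targets clipped at zero scramble it.
- One linear ordering is assumed; branching trajectories are out of
  scope, as are dropout imputation and time-varying (changepoint)
  networks.
- λ is a configuration parameter; no cross-validation routine is
  provided (no unsupervised fold/loss definition is adopted here).
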