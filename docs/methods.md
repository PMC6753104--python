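# Methods

## Problem and model

Structural connectomes mapped from diffusion MRI are undirected: a weight
matrix `W ∈ ℝ^{N×N}`, `W_ij ≥ 0`, `W = Wᵀ`, with node coordinates giving
the Euclidean positions of region centroids. Centralized routing (shortest
paths) is perfectly symmetric on such networks, so it can say nothing about
directionality. Decentralized communication models are not: the route a
signal takes depends on the local topology and geometry around the *current*
node, which differs between the two endpoints. `netcomm` quantifies this
send-receive asymmetry and uses it to infer putative directions of neural
signalling.

### Weight-to-length remapping

All path-based measures operate on connection lengths
`L = −log10(W / (max(W) + min(W_>0)))`, where `min(W_>0)` is the smallest
positive weight. The transform is strictly monotonically decreasing
(strong = short), compresses heavy-tailed weight distributions, and the
offset keeps the strongest connection at a strictly positive length.
Non-edges are `+inf` internally (written as `0` in weight files and `inf`
in length files, so round-trips are unambiguous). When a network is
thresholded to a target density, the transform is applied *after*
thresholding, i.e. `max` and `min_>0` are taken over the retained weights;
the alternative order is a defensible reading of the source material, and
this one is documented here as the package's choice.

### Density thresholding

`threshold_to_density` keeps the `⌊ρ·N(N−1)/2⌋` largest-weight undirected
edges (typical connectome practice uses ρ = 0.10–0.20; cohort pipelines
default to no thresholding unless asked). Ties at the cutoff are broken by
(row, column) lexicographic order — an arbitrary but platform-stable rule;
with continuous weights ties essentially never occur.

### Communication measures

- **Navigation.** From the current node, move to the neighbor with the
  smallest Euclidean distance to the target; success on arrival, failure on
  the first revisit of any node. Because the successor of a (node, target)
  pair is fixed, a revisit implies an infinite loop, so this detection is
  exact. Ties between equidistant neighbors go to the lowest node index
  (determinism). Failed pairs get `Λ = ∞`, efficiency `1/∞ = 0`, and are
  *included* as zeros in downstream means; a strict mode that drops them is
  available in the regional statistics via masking beforehand.
- **Diffusion.** Mean first-passage times of the random walk with
  transition matrix `T_ij = W_ij/Σ_n W_in` solve, for each target `j`, the
  restricted linear system `(I − T_{−j}) h = 1` over the nodes that can
  reach `j` (reachability is computed on the reversed support graph, so
  weakly connected directed networks are handled; unreachable pairs get
  `H = ∞`, efficiency 0). This is algebraically identical to summing the
  geometric series of the absorbing chain; the full-matrix form is kept as
  an independent oracle in the test suite. Dense solves are limited to
  N ≤ 2048 (O(N⁴) work overall).
- **Search information.** `P(Ω_ij)` is the *product* of transition
  probabilities along the canonical shortest path; `SI = −log2 P`,
  `E_si = −SI ≤ 0`. The canonical path is reconstructed greedily from the
  Dijkstra distance field by the optimality condition
  `L(u,v) + dist(v,j) = dist(u,j)` (relative tolerance 1e-12), lowest next
  index first — deterministic without reimplementing the search. An
  `all_paths` mode instead sums the follow probability over all co-optimal
  paths by dynamic programming in ascending-distance order.

### Asymmetry statistics

The pairwise test is a one-sample t-test (df = K−1, two-sided) of
`Δ(i,j,·)` against zero; the regional test applies the same machinery to
`δ(i,k) = S(i,k) − R(i,k)`. `S` and `R` average over the N−1 *other* nodes:
the self-pair `C(i,i,k)` is undefined under every measure, so divisors are
N−1 even though a sum over all N is the more common shorthand. Bonferroni
factors are `N(N−1)/2` (pairwise) and `N` (regional); `p_corr =
min(1, p·m)` exactly. Degenerate samples are handled explicitly: all-zero
`Δ` → statistic 0, p = 1; constant nonzero `Δ` → statistic `±inf`, p = 0
(reachable on tiny or noiseless fixtures, and `±inf` preserves exact
antisymmetry).

A non-parametric variant uses the Wilcoxon signed-rank test on `Δ` — the
paired analog appropriate for a location test against zero, which is how
the control analysis is interpreted here; an unpaired rank-sum comparison
of two groups (`group_comparison_ranksum`) is provided separately. The
signed-rank statistic is reported as `W₊ − W₋` so that antisymmetry
`A(i,j) = −A(j,i)` holds exactly.

For a single directed network, the normalized index
`(E_ij − E_ji)/(E_ij + E_ji) ∈ [−1,1]` replaces the cohort test; directly
connected pairs can be masked out (under navigation-like measures they are
trivially symmetric), and the per-node reduction uses admitted pairs only.

Subsystem downsampling averages `E` over all (i ∈ u, j ∈ v) pairs,
excluding `i = j` on diagonal blocks, and commutes with averaging over
subjects (it is linear).

Correlations between two asymmetry matrices are Pearson over the strict
upper triangle, by default over all finite pairs; restricting to pairs
significant in the first matrix is a flag, since the choice is ambiguous
in the source analyses.

## Null models

- *Degree-preserving*: double-edge swaps, weights travelling with edges;
  10 accepted swaps per edge by default (standard mixing heuristic).
- *Cost-preserving*: the same swaps, accepted only if the total Euclidean
  wiring cost stays within a relative tolerance (default 0.025) of the
  original, or moves toward it (annealed acceptance). The exact tolerance
  used in prior work is unpublished; it is exposed as a parameter and the
  achieved deviation is always reported.
- *Repositioning*: a random permutation of the existing coordinate rows —
  the most conservative reading of "spatially repositioned", since it
  preserves the coordinate multiset and distance distribution; uniform
  resampling in the bounding box is available behind a flag.

Empirical p-values use the add-one estimator
`p = (1 + #{nulls ≥ observed})/(1 + n)`.

## Synthetic data: what it emulates, and what it does not

The cohort generator places N nodes uniformly in the unit cube, samples
edges with probability proportional to `exp(−λ·distance)` topped up to an
exact target density, assigns log-normal weights inversely rank-associated
with distance (long connections weak — the qualitative structure of real
connectomes), and derives subjects by multiplicative log-normal weight
noise on a shared topology. Defaults — N = 60, K = 20, density 0.15,
λ = 2, log-normal(0, 1) weights, 5% weight noise — describe a small but
realistic cohort; density 0.15 matches the focal thresholding density used
with empirical connectomes. The directed generator adds planted senders
and receivers (extra one-way connections) to a geometric substrate for
recovery benchmarks.

These generators reproduce the *statistical structure the analyses
assume*, not brain data: there are no hemispheres, no community structure,
no empirical degree or weight distributions, and subject noise is
independent across edges. Passing tests therefore demonstrate that the
machinery is correct and calibrated under its own assumptions — not that
any particular empirical finding generalizes.

The six-node demonstration network is defined by a small set of
constraints (degrees 3/4/1 at nodes i/b/j, greedy routes i-c-b-j and
j-b-i, unique fewest-hop path i-b-j, uniform 1/3 exit probabilities at i);
topological quantities are independent of the particular coordinates, and
the greedy routes pin down the geometry that matters.

## Verification strategy and problem sizes

Analytic quantities are checked against independent oracles: mean
first-passage times against the full-matrix geometric-series inverse
(exact, 1e-9), closed forms (`H = 4` on the 3-node path ends, `H = n−1` on
`K_n`), and Monte-Carlo walker simulation (10⁵ walkers, within 2% on random
N ≤ 12 graphs); `2^{−SI}` against the empirical fraction of walkers
following the canonical shortest path (5σ binomial tolerance). Statistical
calibration uses 200 no-directionality cohorts (N = 20, K = 20), giving a
false-positive rate within binomial tolerance of α = 0.05. Recovery
benchmarks use N = 30, K = 20 cohorts at 5% noise (Spearman ρ > 0.9
between cohort t-statistics and the noiseless single-network index) and
N = 100 directed networks with 20 planted one-way connections per planted
node (sender/receiver AUC > 0.9). The rewiring null benchmark uses
navigation on N = 24 networks, where asymmetry is geometry-driven and
degree-preserving rewiring genuinely destroys it; diffusion asymmetry, by
contrast, is strength-driven and partially survives rewiring — visible in
the package as a higher null correlation under `dif` than `nav`. These
sizes were chosen as the smallest at which the statistical properties under
test are stable.

## Known limitations

- Diffusion efficiency's per-target dense solve is O(N⁴); fine for
  parcellations up to ~1000 nodes, not for voxel-level graphs.
- Navigation assumes coordinates in a common Euclidean space; no
  great-circle or geodesic surface distances.
- The pairwise t-test treats subjects as exchangeable and Δ as
  approximately normal; the signed-rank variant is provided where that is
  doubtful, and zero-variance pairs produce sentinel statistics rather
  than an error.
- Pearson correlations of t-statistic matrices are sensitive to
  heavy-tailed t values that arise when per-pair noise variance is tiny
  (e.g., direction-correlated measurement noise); rank correlations of the
  same matrices are stable, and both are available.
- Subject-level (single-individual) asymmetry scores are out of scope; the
  cohort tests are inherently group-level.
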