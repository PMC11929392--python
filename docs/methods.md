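# Methods

## Model

The package builds representations of discrete state spaces — grid-world
positions or vocabulary words — from a single co-occurrence principle.
Under a fixed default policy (a uniform random walk over available moves,
or the raw token stream), the successor representation

    SR(s, s') = E[ Σ_t γ^t 1{s_t = s'} | s_0 = s ]       (t = 0 included)

measures discounted expected future occupancy. Successor information
normalises its log by the destination's self-information,

    SI(s, s') = log SR(s, s') − log P(s'),

and the positive part PSI = max(SI, 0) discards weak long-range
associations. SI is, up to a constant factor, the value function of
goal-directed navigation in linear reinforcement learning with s' as the
goal, and simultaneously a PMI-like association measure between words
(the discounted, asymmetric-kernel analogue of pointwise mutual
information; PSI is the analogue of PPMI). Natural logarithms are used
throughout; the base only rescales both interpretations.

Representations are obtained by factorizing the PSI matrix into paired
nonnegative D-dimensional vectors, PSI(s,s') ≈ x(s)·w(s'), by gradient
descent on

    L = Σ_{s,s'} (PSI − x·w)²  +  β Σ_{k<l} corr(X_k, X_l)²  +  ρ₂(‖X‖² + ‖W‖²)

for the **decorr** variant (corr is the Pearson correlation between unit
columns of X across states), or with the decorrelation term removed and
the L2 norms replaced by ρ₁(‖X‖₁ + ‖W‖₁) for the **sparse** variant. A
**decorr-nonneg-off** ablation disables the nonnegativity projection.
X rows act as state (place/word) codes; W rows act as goal codes, since
x(s)·w(g) approximates the navigation value of s with goal g.

## Estimation choices

SR can be estimated from a trajectory two ways:

* `sr_empirical` — Monte-Carlo discounted forward counting (the
  definition, averaged over visits, truncated at segment ends). Its
  estimate converges to the closed form but with high variance at
  γ = 0.99: the per-visit discounted sums have an effective horizon of
  ~100 steps, and the log transform amplifies the noise for small SR
  entries.
* `sr_from_counts` (default for training) — the closed form
  (I − γT̂)⁻¹ of the transition matrix counted from the same walk. This
  is the fixed point that temporal-difference SR learning converges to
  on the data. Measured on the 30×30 fixture, the Monte-Carlo estimator's
  noise floor (even at 2×10⁶ steps) suppresses grid emergence and makes
  movement-conditional decoding unusable, while the count-based estimator
  preserves both; all headline pipelines therefore use it.

Occupancy P(s') is the empirical visit frequency (the stationary
distribution of T is available for analytic work). Entries with SR = 0 or
P = 0 are zeroed and counted. An ε-floor of 1e-12 guards the logs.

Document boundaries in token streams break the trajectory into segments;
neither discounted counts nor transition counts cross a break.

## Optimisation

Projected Adam (β₁ = 0.9, β₂ = 0.999) with a constant step; nonnegativity
enforced by clipping at zero after each update. Initialisation is seeded
uniform on [0, 2c) with c matched to the mean PSI magnitude. A unit whose
X or W column stays identically zero for more than 10% of the iterations
is re-initialised once. Divergence (loss exceeding 10× its initial value)
raises an error suggesting a smaller step. The optimisation runs in
float32 (the returned embedding is float64); the objective and its
analytic gradient are validated against central finite differences at
1e-6 in float64.

Spatial defaults (30×30 room, D = 100, γ = 0.99, walk length 10⁶ states):
decorr β = 6000, ρ₂ = 2.5, step 0.02, 6×10³ iterations; sparse ρ₁ = 1,
step 0.03, 6×10³ iterations. The constraint weights are not identifiable from
first principles; they were chosen on the open-room fixture as the regime
that jointly produces hexagonal unit maps at the reported rate and
supports accurate movement-conditional decoding — the defining
qualitative behaviour of the model. Step sizes ≥ 0.05 intermittently
collapse decoding margins (seed-dependent), hence the smaller default.
The trade-off that governs this calibration: stronger smoothing (larger
ρ₂, smaller step, deeper convergence) produces cleaner hexagonal maps in
both X and W but erodes the cosine margin between neighbouring state
vectors that movement-conditional decoding relies on.
Word defaults (D = 30, γ = 0.9): β = 100, ρ₂ = 0.5, step 0.02, 4×10³
iterations; sparse ρ₁ = 3. The word-scale weights differ because the
word PSI objective is two orders of magnitude smaller than the spatial
one.

## Gridness analysis

A unit's rate map is its embedding column laid out on the room grid
(barrier cells masked). The spatial autocorrelogram is the Pearson
correlation of the map with itself at every 2-D offset over the
overlapping unmasked cells (FFT-accelerated; offsets with fewer than 20
overlapping cells are undefined). The annulus for rotation analysis runs
from the end of the central peak — the first radius where the radially
averaged correlogram drops below 0.2, or its first local minimum,
whichever comes first — to 2.5× the radius of the first ring peak (a
local maximum above 0.1). Maps without a ring peak fall back to the
central peak's decaying flank up to the profile's first zero crossing.
The annulus is compared with itself rotated by 30°–150° (bilinear
resampling at 3° × 0.5-px polar resolution), and

    gridness = min(r60, r120) − max(r30, r90, r150).

A unit counts as a grid cell when its score exceeds both 0 and the 95th
percentile of a pooled shuffling null: 100 random permutations of each
unit's free-cell values (value-multiset preserving). A circular shift of
the raster-flattened free-cell order was considered and rejected: on an
open rectangular room it acts as a near-toroidal translation, which
preserves grid structure and makes the null track the signal.

## Path integration and navigation

Per-action D×D matrices M_a are fitted by ridge least squares
(λ = 1e-6) over all legal transitions, minimising Σ‖x(s') − M_a x(s)‖².
Path integration propagates v ← M_a v from x(start), decodes the state by
cosine similarity against all state vectors (deterministic argmax), and
snaps v to the decoded state's vector after every step (attractor-style
denoising; both the metric and snapping are configurable). A trial of the
success protocol (1,000 trials × 10 uniformly random legal moves) counts
only if every decoded step matches the true path. Decoding errors
concentrate at room boundaries, where field distortion breaks the global
linear-translatability of the code — the main accuracy limit of this
component.

Goal-directed navigation moves over the current state's neighbours by
the value proxy x(s')·w(goal), with a step cap of 8× the BFS shortest
path. The default rule is greedy (ties uniform at random); it is exactly
BFS-optimal on the open room, where the exact value proxy decreases
monotonically with goal distance. Next to barriers, however, the
rectified value field contains strict greedy two-cycles even for the
exact kernel (≈2% of state–goal pairs measured on a one-wall room), so
barrier-context benchmarks use the model's own stochastic decision rule
— neighbours sampled with probability ∝ exp(value/T), the form of the
optimal policy in linear reinforcement learning — at temperature
T = 0.1. Path lengths are reported normalised by the BFS distance (1.0
when start = goal); trials that hit the cap enter the mean at their
capped length.

## Barrier contexts and composition

Contexts Φ (open), A and B place disjoint, non-touching straight walls
on a shared 30×30 footprint: A spans row 10, columns 4–14; B spans row
20, columns 16–26 (11 cells each, so paths can round either end — the
weak-barrier-interaction regime in which additive composition is
expected to work). Context training is continual: Φ is learned from
scratch, then A and B fine-tune Φ's solution on their own walks with a
proximal anchor μ(‖X−X_Φ‖² + ‖W−W_Φ‖²), μ = 10, at half the base
iteration count. Continual training is what gives "unit k" a meaning
across contexts — independently trained factorizations have arbitrary
unit bases and their difference vectors are noise — and the anchor
concentrates the contextual change on the units the new layout actually
requires (the top-4 units carry ≈60% of the total B↔Φ representational
distance). Cells free in every context align by position, and vectors
for the unseen two-wall context A+B are composed per position and unit
as max(x_A + x_B − x_Φ, 0) — clipping preserves the nonnegativity the
rest of the pipeline assumes — applied to both X and W (navigation in
A+B needs goal vectors). Partial composition applies this rule only to the
k units with the largest representational distance
d_k = Σ_i (x_k(i;B) − x_k(i;Φ))² between B and Φ, copying the remaining
units from A. Navigation trials in the composed context sample the start
from the top five rows and the goal from the bottom five rows, so paths
must negotiate both walls. Grid/non-grid unit labels for the
grid-only-composition contrast come from the gridness classification in
context Φ.

## Synthetic corpora

The categorical generator emulates topical text at desk scale: 10
categories × 10 words plus 50 background words; each 200-word document
activates one category and samples tokens with weight 30 on its words
(200k tokens over 1,000 documents). The boost and single-active-category
design are calibrated so that the planted block structure survives into
PSI strongly enough for the decorr variant to recover category-aligned
units — with weaker contrast only the strongly sparse variant finds them.
The relational generator plants two-factor words (2 families × 4 entity
pairs, e.g. country↔capital): each document boosts either one entity's
two role-words or one role across the family's entities, coupling words
that share either factor, and every consistent analogy quadruple is
emitted as ground truth. The ground-truth similarity oracle for
specificity returns 1.0 within a category and a smooth positive value
0.5·exp(−3|z₁−z₂|) otherwise (per-word latent z), giving the random-pair
null a continuous distribution with a meaningful 95th percentile.

What these corpora do not emulate: Zipfian frequencies, grammar,
polysemy, or document length variation. Passing tests show the mechanism
— planted co-occurrence structure becomes concept-aligned units and
recombinable factors — not performance on natural language.

## Evaluation statistics

Concept specificity of a unit: s_unit is the mean oracle similarity over
the 45 pairs of its TOP-10 words; the null is 1,000 random word pairs;
the unit is significant if s_unit exceeds the null's 95th percentile, and
specificity = s_unit/s_null − 1. Analogy a:b::c:? ranks candidates
(excluding a, b, c) by cosine to x(c) + x(b) − x(a); the partial variant
adds only the k/2 largest and k/2 smallest dimensions of x(b) − x(a)
(max side favoured when k is odd), clipping at 0.

## Problem sizes and determinism

Headline pipelines use 10⁶-state walks, D = 100, five seeds for the
open-room battery, one seed (three trainings) for the context
experiment, and 1,000 navigation or path-integration trials per
condition; corpora are 200k tokens. All randomness flows through
explicit integer seeds; identical configuration and seed reproduce
results bit-for-bit on one platform.

## Known limitations

* Path-integration accuracy saturates below the ideal regime because a
  single linear map per action cannot capture boundary field distortion;
  see above.
* The grid-cell fraction depends on the shuffling-null threshold; the
  permutation null used here is the weakest (spatially white) choice,
  and fractions under smoothness-preserving nulls would be lower.
* Monte-Carlo SR estimation is provided for completeness but is not
  usable for representation learning at γ close to 1 (variance).
* The A+B−Φ composition assumes weak interaction between barriers;
  connected-barrier layouts are expected to defeat it and are not an
  evaluated configuration.
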