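# Methods

## Model and procedure

The package operationalizes a concept as a point in a distributional
semantic space and estimates it from open-ended verbal responses in three
steps: (1) collect responses to the target concept (free association, word
substitution, or feature generation); (2) map each response to a word
embedding; (3) average those embeddings — the centroid is the concept
estimate. The underlying generative assumption is spreading activation: the
cue activates the target concept, activation spreads isotropically, and
semantically nearby words surface as responses, so the activation source is
recoverable as the center of the responses (the earthquake-epicenter
analogy). Evaluation treats the target word's own embedding as the gold
standard and asks how close the centroid lands: the target's neighborhood
rank among the N most frequent words, summarized as Hit@k.

Assumptions worth keeping in mind: the population-level embeddings of
targets and responses are taken as adequate proxies for the (group or
individual) representations being measured, and as shared across speakers.
For individual-level analyses the gold standard is itself a group-level
average, so measured accuracy is a lower bound.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| weighting | `token` | token = count-weighted mean (responses enter as often as produced); type = each unique response once. Which wins is data-dependent: token tends to help multi-response tasks, type single-response tasks. |
| lexicon sizes | 20 000 / 50 000 / 100 000 / 250 000 | competitor set = the N most frequent words (file row order, overridable by an explicit frequency list). Hit@k necessarily declines as N grows. |
| k | 1..20 | Hit@k thresholds. Chance Hit@1 is 1/N. |
| `drop_target_equal_response` | on | echo responses are excluded before aggregation: in the taboo task the target is forbidden by design, and echoes would trivially inflate recovery. |
| `normalize_before_average` | off | responses are averaged raw. The target's rank is invariant to centroid *scale*, but averaging unit vectors can change the centroid's *direction* when response norms vary; the flag exposes the alternative. |
| loess `span` / `degree` / `iterations` | 0.75 / 1 / 4 | see below. |
| outlier threshold | 4 SD | z-score rule on the response-count variable (sample SD, n−1). |
| `noise_sd` (simulator) | 0.05 | per-coordinate SD of the isotropic perturbation; the spreading-activation breadth. |

## Ranking conventions

Rank = 1 + the number of competitors whose cosine to the centroid strictly
exceeds the target's, with ties declared at absolute cosine difference
≤ 1e-12 and resolved optimistically (a tie does not increment the rank);
ties have measure zero for real embeddings. The target itself is removed
from the competitor set, and a target outside the top-N words still
receives a rank relative to that lexicon. Response strings are excluded
from the competitor set by exact normalized-string match (multi-word
responses can only exclude identical multi-word lexicon entries, which
effectively never occur); at the individual level exclusion is per
(target, participant) pair. Cosines are computed against a cached
row-normalized copy of the lexicon matrix; correctness against direct
unnormalized evaluation is asserted in tests.

Token normalization everywhere: Unicode NFC, lowercase, outer whitespace
stripped, internal whitespace runs collapsed. Quartiles are type-7 (linear
interpolation), stated for comparability.

## Robust loess and plateau detection

Rank-vs-response-count curves use locally weighted regression evaluated on
a 100-point grid over the observed count range: at each grid point the
⌈span·n⌉ nearest data points (by |x−x₀|) get tricube weights
w = (1−(d/h)³)³ with h the window half-width, and a degree-1 weighted fit
supplies the value. `family="symmetric"` runs 4 robustness passes that
reweight points by the bisquare of residuals scaled by 6·median|residual|,
down-weighting rank outliers; `family="gaussian"` skips the passes. Count
outliers are removed beforehand by the 4-SD z-score rule — the split is
deliberate: the z rule handles outliers in the *count* variable, the
symmetric family handles outliers in *rank*. Degenerate windows (all x
equal) fall back to the local weighted mean; fewer than max(3, ⌈span·n⌉)
points is an error.

The "responses per target needed" plateau is the first grid point at which
the fitted curve drops to or below a rank threshold (3, 5, 18 by default),
reported with the grid step as its resolution; eyeballed plateaus are not
reproducible, a first-crossing rule is. Note that wide spans smooth over
curve kinks and shift the apparent crossing rightward; the span is a
genuine analyst choice (0.75 is the de facto default of reference loess
implementations) and the plateau should be read at the grid resolution, not
finer.

## The synthetic world

`make_space` draws V i.i.d. unit vectors uniform on the sphere (Gaussian,
L2-normalized); frequency rank is generation order (arbitrary, but it is
what lexicon truncation cuts on). `simulate_responses` draws each response
as the vocabulary word nearest by cosine to v_target + ε, ε ~ N(0, σ²I),
excluding the target itself by default (mirroring both the taboo design and
the rank-exclusion rule; a flag allows echoes). This is the *minimal*
quantitative model consistent with isotropic spreading activation: noise is
added in the raw space and then discretized to a word, reproducing the
discretization real tasks impose. Duplicate draws arise naturally and give
token counts. Randomness is a single global seed with counter-based
per-target stream splitting, so worlds and experiment tables are
byte-reproducible and parallelizable.

What the simulator does **not** emulate: frequency-weighted response
availability (real speakers prefer frequent words), asymmetric or
multimodal activation spread, participant-level response styles, polysemy,
or the heavy-tailed response distributions of real association norms.
Passing recovery tests on synthetic worlds therefore validates the
*pipeline algebra* (centroid, ranking, exclusion, monotonicity, base
rates), not the empirical accuracy of centroid analysis on human data,
which depends on real embeddings and real response statistics.

## Problem sizes and numerical choices

The validation experiments run at vocabulary 1000–2000, dimension 25–50,
100 targets, 10 responses per target, σ = 0.05 — chosen so each experiment
is a desk-scale computation while leaving the base-rate (1/N) and
monotonicity regimes clearly observable. All averaging is double precision;
rank comparisons ride on small cosine differences, so centroids are never
recomputed through lossy round-trips (the vector writer's default float
format round-trips IEEE doubles exactly). Exact nearest-neighbor
computation only — at N ≤ 250 000 and d ≤ 400 a matrix product is cheap and
approximate indexes would blur ranks 1–20, which are the entire signal.

## Known limitations

- Subword-capable models (fastText .bin) are not read natively; the
  vectorizer is a pluggable `word -> vector | UNMAPPED` callable, which is
  the extension point for out-of-vocabulary inference.
- No spell-checking or lemmatization of raw responses; feature phrases are
  handled by the `token-average` policy or an upstream "translated" column.
- Published plateau counts depend on unstated smoothing parameters (span,
  grid); with the defaults here they are reproducible only qualitatively.
- Whether count-outlier removal should use sample or population SD is a
  genuine open choice; sample SD (n−1) is used and documented.
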