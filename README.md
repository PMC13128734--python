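# centroidlex

Centroid analysis of open-ended word responses in distributional semantic
spaces — for cognitive scientists and psycholinguists who collect free
associations, single-word substitutions (taboo-game data), or feature
generations and want to measure the *concept* behind those responses as a
point in a pre-existing word-embedding space.

## The method

Given a target concept that elicited responses r₁ … rₘ (with production
counts c₁ … cₘ), the concept estimate is the **centroid** of the responses'
embedding vectors v(rᵢ):

- **type-level**:  ĉ = (1/m) Σᵢ v(rᵢ) — each unique response counted once;
- **token-level**: ĉ = Σᵢ cᵢ v(rᵢ) / Σᵢ cᵢ — each response counted as often
  as it was produced.

The rationale is a spreading-activation account of production: a cue
activates its concept, activation spreads evenly in all directions of
semantic space, and nearby words surface as responses — so the source
concept is recoverable as the geometric center of what it activated.

Recovery is scored by the target's **neighborhood rank**: against the N
most frequent words of the space (the reference lexicon, N ∈ {20 000,
50 000, 100 000, 250 000} canonically),

    rank = 1 + #{lexicon words w : cos(ĉ, w) > cos(ĉ, target)}

with the responses themselves (which by task design cannot be the target)
and the target removed from the competitor set. **Hit@k** is the fraction
of targets with rank ≤ k (k = 1 … 20); the chance level of Hit@1 is the
base rate p = 1/N.

The package also provides the surrounding evaluation machinery: crossed
sweeps over spaces × weightings × lexicon sizes, robust loess
(family="symmetric": tricube weights + bisquare robustness iterations) of
rank against the number of unique/total responses per target with 4-SD
z-score count-outlier removal and plateau detection, individual-level
Hit@k curves using only each participant's first m = 1…10 responses, and a
spreading-activation simulator so the whole pipeline is testable without
downloading any embeddings.

## Worked example

Simulate a 1000-word semantic space, draw 10 spreading-activation responses
for each of 100 targets at noise SD 0.05, and recover the targets from the
token-level response centroids:

```python
from centroidlex import (SyntheticConfig, make_world, aggregate,
                         centroid_batch, make_vectorizer, hit_curve)
from centroidlex.ranking import rank_batch

world = make_world(SyntheticConfig(vocab_size=1000, dim=50, n_targets=100,
                                   responses_per_target=10, noise_sd=0.05, seed=1))
vec = make_vectorizer(world.space)
sets = aggregate(world.records, "group")
cents = centroid_batch(sets, vec, weighting="token")
table = rank_batch(cents, world.space, [200, 1000],
                   exclusions={s.target: set(s.items) for s in sets})
for n, sub in table.groupby("N"):
    curve = hit_curve(sub["rank"].to_numpy(), k_max=20)
    print(f"N={n:5d}  Hit@1={curve.fractions[1]:.2f}  "
          f"Hit@5={curve.fractions[5]:.2f}  Hit@20={curve.fractions[20]:.2f}  "
          f"mean rank={sub['rank'].mean():.2f}")
```

prints

```
N=  200  Hit@1=0.98  Hit@5=1.00  Hit@20=1.00  mean rank=1.02
N= 1000  Hit@1=0.98  Hit@5=1.00  Hit@20=1.00  mean rank=1.03
```

At this low activation noise the centroid of just ten responses puts the
true target first among 1000 candidate words for 98 of 100 targets (chance:
1/1000), and ranks are essentially unchanged when the lexicon grows —
recovery of the generating concept from the response centroid is nearly
perfect. Real behavioral data are noisier; the `noise_sd` and
`responses_per_target` knobs let you map how recovery degrades.

The same pipeline runs from the shell on real vector/response files:

```sh
centroidlex simulate --config sim.yaml          # or bring your own .vec + TSV
centroidlex rank --vectors space.vec --responses records.tsv \
    --weighting token -N 20000 --out-dir out/
centroidlex curve --ranks out/ranks_token.tsv --count-kind unique
centroidlex sweep --config sweep.yaml
```

Vector tables are read in word2vec text format (header `"<vocab> <dim>"`)
or headerless GloVe text; row order is taken as descending corpus
frequency. Response tables are long-format CSV/TSV with columns
`target, response, participant_id, response_position` (the latter two
optional; column names remappable).

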