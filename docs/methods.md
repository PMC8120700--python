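# Methods

## Model and assumptions

`jdcnet` ranks proteins of an undirected simple PPI graph by a score that
rewards membership in densely connected, co-expressed clusters. The model
behind the score makes three assumptions: (1) essential proteins sit in
dense clusters of the interaction network; (2) the biologically meaningful
part of an expression profile is its "active"/"inactive" switching pattern,
not its continuous level, which is fluctuation-prone; (3) two interacting
proteins in the same functional cluster switch on and off together.

Topology enters through the edge clustering coefficient
ECC(i,j) = z⁽³⁾ᵢⱼ / min(kᵢ−1, kⱼ−1) — triangles through the edge over the
maximum possible. Expression enters through per-gene binarization at the
dynamic threshold G(i) = U(i) + 2·σ(i)·V(i) with V(i) = 1/(1+σ²(i)),
followed by Jaccard similarity of the Boolean activity vectors. The protein
score sums the product over neighbours. DC, NC, PeC and WDC are provided as
comparison rankers; PeC and WDC use the Pearson correlation of the raw
(continuous) rows where JDC uses Boolean co-activity, which is exactly the
contrast the evaluation battery is designed to expose.

## Numerical and convention choices

- **Population variance** (divisor n) in σ²(i): the threshold definition is
  taken literally as printed in the defining formula, not with Bessel's
  correction. For the sample counts this tool targets (tens of samples) the
  difference is well under the noise level, but tests pin the convention.
- **Strict inequality at the threshold**: expression equal to G(i) is
  inactive. Consequently a zero-variance (constant) gene, where G = U,
  binarizes to all-zero.
- **ECC degree-1 convention**: min(kᵢ−1, kⱼ−1) = 0 ⇒ ECC = 0. A degree-1
  endpoint can form no triangle, and the 0 convention preserves
  JDC ≤ NC ≤ DC.
- **Jaccard empty-union convention**: two all-zero vectors give 0, not 1 —
  two never-active genes are no evidence of co-membership.
- **Missing expression row** for a network protein: treated as an all-zero
  activity vector, so all its edges carry Jaccard 0 but the protein remains
  scoreable (and rankable) rather than being dropped. PeC/WDC analogously
  use PCC = 0 for such edges.
- **PCC clamping** for PeC/WDC: negative or undefined (zero-variance)
  correlations become 0, the convention of the methods these baselines
  reproduce; applied identically to both for fairness.
- **Ranking tie-break**: descending score, then ascending protein ID —
  deterministic top-k sets without fabricating resolution.
- **Metrics cutoff**: confusion metrics are computed at k = |essential ∩
  ranked|. With that choice TP+FP = TP+FN, forcing SN = PPV and SP = NPV,
  the signature pattern of accuracy tables in this literature.
- **ROC ties**: the sweep uses one threshold per distinct score value, so
  tied proteins enter together and produce diagonal segments; the
  trapezoidal AUC then equals the tie-corrected Mann–Whitney statistic
  P(s_ess > s_non) + ½·P(equal), which the tests verify pairwise to 1e−12.
  The ROC machinery is scikit-learn's; the pairwise statistic in the tests
  is computed independently.
- **Top-percentage sets** use ceiling sizes ⌈p·P/100⌉, nonempty even for
  small networks.
- **Essential-list IDs absent from the network** are dropped (with a logged
  count) before any metric: all evaluation runs over the single universe of
  ranked network proteins.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `wdc_lambda` | 0.5 | WDC's mixing weight between ECC and PCC (unitless); the benchmark value is not fixed by the method's source, so it is exposed as a flag |
| `top_percents` | 1, 5, 10, 15, 20, 25 | top-percentage cutoffs for recovery counts |
| `overlap_top_n` | min(100, universe) | set size for cross-method overlap tables |
| top fraction for truncated ROC | 0.2 | fraction of the ranking used for the top-restricted ROC variant |

## Synthetic benchmark generator

The generator (`jdcnet.synthetic`) emulates the data regime the score
assumes, at desk scale. A `SyntheticSpec` fixes: 3 clusters × 10 proteins +
30 background proteins; planted-partition edges with p_in = 0.8 within
clusters and p_out = 0.02 elsewhere; 40 expression samples in which each
cluster is "on" with probability 0.5 per sample; per-gene state bit-flips at
rate 0.05; expression levels 8.0 (on) / 2.0 (off) — a log2-microarray-like
scale — with Gaussian level noise of SD 0.5; background genes always off.
All randomness flows from one integer seed through a single generator, so a
spec reproduces its instance byte-for-byte.

Essential labels default to *all* planted-cluster members
(`essential_fraction_in_clusters = 1.0`). The fraction knob can dilute
labels, but the default keeps labels identical to the planted structure:
with diluted labels, which cluster members are "essential" is pure label
noise that no ranker can see, every method hits the same AUC ceiling, and
the comparison between rankers degenerates into that shared noise. With
labels = cluster membership, differences between rankers reflect exactly
what they are designed to differ on — a background protein has zero
co-activity, so JDC pins it to score 0, while degree-based scores can rank
a spuriously connected background protein above a cluster member.

What the generator does **not** emulate: realistic degree distributions
(no hubs, no scale-free tail), distinct verified/false-positive edge
labels, time-series structure in samples, probe-level noise, or partial
overlap between the expression and network universes beyond isolated
proteins. Passing the recovery tests therefore shows the pipeline is
correct and that co-activity weighting behaves as designed under the
assumed regime — not that JDC attains any particular accuracy on real
organism data.

## Problem sizes

Tests and the acceptance script use 60-protein instances (≈130 edges, 40
samples), 20–25 replicate seeds for averaged properties, 100 random
instances for the AUC/Mann–Whitney equivalence and 1,000 random confusion
matrices for metric identities. These sizes make every oracle check
exhaustive (triangle enumeration, naive double-loop scoring, all-pairs AUC)
while the whole suite runs in seconds.

## Known limitations

- Edge-list serialization cannot represent isolated proteins; proteins with
  no surviving interaction drop out of the scored universe when a network
  round-trips through a file.
- The score has no free parameter to trade topology against expression; if
  the expression matrix is uninformative (e.g. constant), JDC collapses to
  the all-zero ranking rather than falling back to topology.
- Confusion metrics at k = |essential| describe one operating point; the
  ROC/jackknife outputs carry the threshold-free picture.
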