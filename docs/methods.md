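# Methods

`cgenet` implements coordinated gene expression (CGE) network analysis: a
functional-connectivity-style treatment of regional immediate-early-gene
(IEG) expression. Regional *cfos* or *arc* mRNA levels measured in the same
animals are correlated across subjects; region pairs whose expression
covaries form edges of a network whose modular structure and drug-induced
rewiring are then analyzed. This note documents the model, the estimators,
the synthetic test bed, and the numerical choices the implementation makes.

## Correlation networks

For each analysis cell — one gene, one age group, one treatment — expression
is arranged as an n-subjects × 27-regions matrix and the adjacency matrix is
the sample Pearson correlation of every region pair across subjects. The
design anticipates n = 6–7 subjects per cell; fewer than 4 is refused
outright because the downstream Fisher comparison requires n > 3, and the
pipeline logs a warning outside the 6–7 range.

Subjects missing any region are dropped listwise (opt-in via
`allow_missing`), never pairwise: the Fisher comparison assumes a single n
per network, and pairwise-complete correlations would silently break that.
Zero-variance regions produce r = 0, p = 1 edges and a logged warning rather
than NaNs.

Edge significance uses the conventional two-tailed t-test with
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom; thresholding zeroes all
edges with p ≥ α (default 0.05), preserving the sign and magnitude of the
rest. At n = 7 this keeps only |r| > 0.7545. A one-tailed option and a
subject-relabeling permutation p (used as a cross-check in the tests) are
available. No multiple-testing correction is applied at this stage — the
threshold is a visualization and community-detection substrate; formal
inference happens at network comparison.

## Community structure

Thresholded networks are weighted and signed. Modularity of a partition is
computed as the asymmetric signed composite

    Q* = Q⁺ − (m⁻/(m⁺+m⁻))·Q⁻,

where Q± are standard Newman–Girvan weighted modularities (resolution γ,
default 1) of the positive and negative sub-networks and m± their total
edge weights. Positive edges dominate the objective; negative edges — which
are typically sparse after thresholding — penalize partitions that bury
them inside communities instead of letting them dominate. A
`positive_only` fallback zeroes negative weights first. Both the variant
and the parameters are recorded in output metadata.

Maximization is a Louvain-style greedy agglomeration (local moves +
aggregation of both sign layers) taking the best of `restarts` seeded
randomized runs. Two details matter for correctness on signed objectives:

- Candidate moves consider **all** current communities, not only those a
  node touches: the negative-layer null-model term can reward joining a
  community the node has no edges to. With neighbor-only candidates the
  optimizer matched the exact optimum on barely half of random signed
  graphs; with full candidates it matches on effectively all of them.
- Determinism: node sweep order comes from a seeded generator, ties in the
  move gain break toward the smallest community id, ties across restarts
  break toward higher Q, then fewer communities, then the lexicographically
  smallest canonical label vector. Identical inputs give bit-identical
  partitions.

An exhaustive set-partition search (≤ 10 nodes, Bell-number enumeration)
provides the exact oracle used by the test suite. Empty networks score
Q = 0 with an all-singleton partition; isolated nodes stay singletons.

## Network comparison

Drug-vs-baseline contrasts use the *unthresholded* correlation matrices.
Each edge's correlations are Fisher-transformed (z = atanh r, with |r|
clamped at 1−10⁻⁷ and logged when degenerate) and compared with

    Z = (z_a − z_b) / √(1/(n_a−3) + 1/(n_b−3)),

referred to a standard normal, two-tailed. The 351 unique edges of one
contrast form a single correction family (contrasts are corrected
independently of each other), adjusted by Benjamini–Hochberg step-up at
q = 0.35 by default — deliberately liberal, prioritizing sensitivity in
small-n networks — with Benjamini–Yekutieli behind a flag.

Significant edges are classified by their thresholded states read
baseline → drug: null→pos `gain_positive`, pos→null `loss_positive`,
null→neg `gain_negative`, neg→null `loss_negative`, pos↔neg
`sign_reversal`. This state-transition rule is an explicit reconstruction:
the figure grammar it mirrors defines only gain/loss of positive/negative
CGE, so a significant edge whose thresholded sign is unchanged receives no
class and is reported in a supplementary `strength_change` column instead.

## Synthetic data generator

The generator emulates the study conditions: 24 groups (2 genes × 2 ages ×
6 treatments), 27 regions, n = 7 subjects per group, and subject-level
values in arbitrary optical-density units (mean 100, sd 15 by default, so
draws are effectively never negative). Correlation structure is specified
as blocks — by default the five anatomical territories — with a target
within-block correlation (0.75), a cross-block correlation (0.15), and
per-edge overrides for planted effects.

The target matrix is built directly (blocks + overrides, unit diagonal),
then certified positive semi-definite. If overrides make it indefinite it
is projected to the nearest PSD matrix by eigenvalue clipping and
re-normalized to unit diagonal; if that moves any entry by more than 0.05
the spec is rejected as infeasible rather than silently distorted. This
makes a real constraint explicit: a node cannot be strongly correlated with
a block its own block-mates ignore, so single strong cross-block edge
overrides on tight blocks are often infeasible. The default design
therefore plants its drug effect (in the two D1+D2 combination groups) as
node-level rewiring — BNST drops from 0.75 to 0.35 coupling with its
amygdala/hypothalamus block while gaining 0.5/0.45 coupling with
prefrontal and accumbens regions, and M2 decouples from sensorimotor
cortex to 0.3 — values chosen so the target matrix is exactly PSD.

Sampling is multivariate normal through an eigendecomposition transform
(PSD-safe, no Cholesky failures), deterministic given the design seed via
spawned per-group streams. An optional log-normal mode
(value = mean·exp(0.25·z)) provides skewed marginals for robustness
checks; Pearson targets are defined on the latent Gaussian scale and are
attenuated on the observed scale in that mode.

What the generator does *not* emulate: autoradiography noise physics,
spatial autocorrelation between anatomically adjacent regions, shared-animal
correlation between the two genes, or non-stationary group differences
beyond the planted covariance. Passing tests therefore demonstrate that the
estimators recover known covariance structure from Gaussian data at the
study's sample sizes — not that any particular biological result is
reproduced.

## Calibration results and a known limitation

With both groups drawn from the same correlation structure (n = 7, 27
regions), the per-edge raw rejection rate at p < 0.05 is calibrated
(≈ 0.049, within Monte-Carlo error of 0.05). The FDR level is not: the
normal approximation to the z-difference is anticonservative in the far
tail at n = 7 (about 1.7× at p = 0.001, 3× at p = 0.0001, by direct Monte
Carlo of the null statistic), and Benjamini–Hochberg's behavior on a
complete null is driven precisely by p-values near q/m ≈ 0.001. The
realized complete-null FDR at q = 0.35 is therefore ≈ 0.40 rather than
≤ 0.35. This is a small-sample property of the normal-theory z-difference
test itself — the corresponding acceptance test states the nominal bound
and fails honestly, and the test suite documents it rather than hiding it.
Users needing strict control at n = 7 should prefer the `by` correction
(whose heavier penalty more than absorbs the tail inflation) or larger
groups; the raw 0.05-level edge inference is unaffected.

## Rendering and export

Networks render in a fixed pseudoanatomical layout (cortex top, striatum
center, hippocampus/septum left, amygdala/hypothalamus bottom); the
coordinates are an arbitrary packaged constant. Positive edges are black,
negative red; stroke width is w_min + (w_max−w_min)·|r| with w_min = 0.5,
w_max = 4.0 points; node borders take a fixed qualitative palette in
community-label order; difference maps draw gains solid and losses dashed,
with an embedded legend. SVG output is byte-deterministic (fixed hash
salt, stripped date metadata) and every edge carries a group id naming its
region pair, so renders can be audited element-by-element against the
matrices. GraphML, TSV edge-list, and square-CSV exports round-trip the
weighted edge set.

## Pipeline

`cge run --config config.yaml` (or `run_pipeline` in code) executes
simulate/load → per-group networks → thresholding → communities →
contrasts → renders, writing full-precision matrices, partitions,
difference maps, and a manifest with parameters, per-group n, and SHA-256
checksums of every artifact. Default contrasts pair each drug group with
the same-gene, same-age saline group (20 contrasts in the full factorial);
cross-gene or cross-age contrasts are rejected. Reruns with the same
config and seed are byte-identical, and stage outputs are sufficient to
regenerate deleted renders exactly.

## Problem sizes used in validation

The shipped validation suite runs the full factorial (24 groups, 27
regions, n = 7), 1500-replicate null calibration, 1000-replicate Fisher-z
coverage, a 10,000-subject convergence check, 100 random ≤ 8-node graphs
against the exact modularity oracle, and a 9-region/200-subject planted
block recovery — sizes chosen so the whole suite completes in a few
minutes on one CPU while leaving Monte-Carlo error well below the
tolerances being asserted.
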