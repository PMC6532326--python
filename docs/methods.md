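# Methods

This note documents the models and procedures behind `herbnet`, the
parameters that matter, the numerical choices, and what the synthetic-data
tests do and do not demonstrate about real data.

## The inference chain

The pipeline is a chain of set operations over typed containers, with two
statistical components (a per-gene two-group test and a hypergeometric
over-representation test) and one centrality rule.

### ADME screening and source merging

ADME-scored compounds are kept when oral bioavailability (OB, percent)
and drug-likeness (DL, unitless in [0, 1]) pass their thresholds.
Defaults are OB ≥ 30 and DL ≥ 0.18 with **inclusive** comparison;
`ScreenConfig.inclusive=False` switches to strict `>`. Both conventions
circulate in the ADME-screening literature and the boundary behavior is
unit-tested, so a user can match either reading exactly. Curated
bioactivity sources carry no ADME scores and bypass the screen — their
entries are literature-validated rather than ADME-predicted.

The two sources are merged by canonicalized compound name (trimmed,
lower-cased, internal whitespace collapsed). Name is the only key shared
across heterogeneous herbal databases; no synonym resolution is attempted,
so two names for the same chemical stay distinct. Herb memberships union
across sources; a compound present in both is marked `source="both"`.

### Target compendium

Predicted associations are filtered at similarity > 1.0 and prediction
score > 0 (both strict). The similarity score of the upstream 3D-shape
search is not capped at 1, so a strict bound at 1.0 is meaningful; on a
[0, 1]-normalized similarity this filter would be empty, which is why the
bound is exposed as `sim_min`. Duplicate (ingredient, gene) pairs collapse
to one association with validated evidence winning — curated evidence is
stronger than a similarity prediction, and the same rule is reused when
classifying candidate targets later, so the two stages cannot disagree.

### Differential expression

Per-gene two-sided t-test on log2 intensities, Welch by default
(`equal_var=True` gives Student's t). A gene is called when raw
*P* < 0.05 and max(FC, 1/FC) ≥ 1.5. Design notes:

- **Fold-change scale.** Default `fc_scale="log"` computes
  FC = 2^(mean case − mean control) from log2-scale means; `"linear"`
  uses the ratio of linear-scale means. Both readings of a "|FC| ≥ 1.5"
  cut-off exist in practice and both are reachable; they agree in sign and
  approximately in magnitude for the noise levels simulated here.
- **No multiple-testing correction in the call.** Small two-group designs
  are commonly thresholded on raw p; BH q-values are computed and reported
  alongside every call but do not enter the cut.
- **Degenerate genes.** A gene with zero variance in both groups gets
  p = 1 (never significant, never a crash). P-values are clipped away
  from 0 so −log10 p is always finite.
- Welch's test at n = 6/6 is mildly conservative (measured type-I rate
  ≈ 0.047 at α = 0.05 under an equal-variance Gaussian null); Student's t
  is exact under that null. The calibration tests assert exactness for
  Student and one-sided conservatism for Welch.

### Candidates, interactors, network, hubs

Candidates are the intersection of the target universe with the disease
genes. PPI edges are kept at combined score strictly > 0.9 when at least
one endpoint is a candidate (neighborhood-query semantics); edges between
two introduced interactors are kept by default
(`include_interactor_interactor=False` restricts to candidate-touching
edges only). Scores arriving in the 0–999 integer dialect are divided by
1000 at load (`scores_0_999=True`).

The tripartite network links each ingredient to its candidate targets and
overlays the kept PPI edges. Ingredients with no candidate target are
excluded — they would be isolated nodes and would only depress the mean
degree. The graph is simple and undirected; the handshake identity
Σdeg = 2E is asserted on every constructed network. Key nodes satisfy
deg(v) > 2·(2E/N) strictly. Graph-viewer tools sometimes report a
"mean neighbors" statistic that differs from 2E/N on multigraphs; both
numbers are emitted in `network_stats.json` so either convention can be
compared. Reported hub-target lists conventionally pool candidate targets
and interacting proteins, so a pooled `key_targets` view is emitted next
to the per-layer lists. Ties in all rankings break lexicographically.

### Enrichment and kappa grouping

For query size n against a background of size N, a term with K genes in
the background and overlap k gets p = P[X ≥ k], X ~ Hypergeom(N, K, n).
Terms are intersected with the background before testing and k = 0 rows
are omitted. BH runs within each category (pathways and molecular
functions are separate analyses). The default background is the target
universe plus the interactors — the set of genes the analysis could
possibly nominate — configurable to any annotated universe; enrichment
against a background the query cannot reach would be anti-conservative.

Significant terms (q < 0.05 by default) are clustered by pairwise Cohen's
kappa of their binary gene memberships, computed over the union of
query-hit genes of the category — the genes driving the signal, not the
full background, matching the convention of kappa-grouping enrichment
tools. Terms with κ ≥ 0.4 are linked and groups are connected components,
each labelled by its lowest-p ("leading") term; `group_share` is the
group's fraction of the category's significant terms. When chance
agreement is exactly 1 (both memberships constant over the universe),
kappa is defined as 1 for identical memberships and 0 otherwise.

## Synthetic data: what it emulates, what it does not

The generator draws one deterministic "plan" per (params, seed) — named
substreams are spawned from a single seed, so each generator function
writes byte-identical files independently and adding a stream never
shifts an existing one.

Default sizes follow a realistic 12-herb formula study: ~480 ADME-scored
compounds of which ~130 pass the screen, 39 curated compounds, a 900-gene
target universe, a 2000-gene expression matrix with 6 case / 6 control
samples, 23 + 28 planted DEGs at |log2FC| ~ U(1.0, 2.5) over N(0, 0.3²)
noise, a 59-gene curated disease pool split over five sources, ~100
interaction partners and 15 annotation terms per category.

Planted structure:

- **Hubs** (3 by default) are forced through the ADME screen and wired to
  a ~300-gene fan-out that covers ~90% of the plantable disease genes, so
  the degree rule must recover them; their predicted associations always
  pass the similarity filter so score filtering cannot erode the planted
  fan-out. Hub associations mix evidence classes (30% validated) so the
  candidate set shows a realistic validated/predicted split.
- **DEGs** follow log2 intensity = gene baseline N(8, 1.5²) + group shift
  (cases only) + N(0, 0.3²) noise.
- **PPI scores** are a two-component Beta mixture (35% Beta(50, 2), mode
  ≈ 0.96; else Beta(2, 8)), giving a high-confidence mode above the 0.9
  cut as in combined-score exports.
- **One pathway term** draws 65% of its genes from the disease-reachable
  part of the universe, so the key-target query over-represents it.

What passing these tests shows: the set operations, thresholds, centrality
rule and enrichment machinery behave correctly and recover known structure
at realistic scale. What they do not show: robustness to real microarray
artifacts (probe effects, normalization, batch), to identifier ambiguity
across real databases (synonyms, merged gene symbols), or to the
correlation structure of real PPI networks — generated intensities are
i.i.d. Gaussian per gene and edges are sampled independently.

## Problem sizes in the test suite

Simulation-based tests use sizes chosen for statistical power, not to
mirror any particular dataset: type-I calibration pools 50 replicates of
2000 null genes (the exact binomial 99% interval at this size resolves a
±0.25 percentage-point deviation); planted-DEG recall uses 100 replicates
of 40 planted genes at |log2FC| = 1, where the design's power is ≈ 0.99;
pathway recovery uses a 300-gene background with 12 competitor terms and
a 40-gene query, where a 5× enrichment ranks first with probability
> 0.99; hub recovery runs 100 full paper-scale replicates. The whole
suite runs in well under a minute on one core.

## Known limitations

- Name-keyed merging cannot reconcile chemical synonyms; counts from real
  database exports will depend on upstream name hygiene.
- The pipeline consumes exported tables only; it does not query live
  services, compute 3D similarity, or render networks (SIF/GraphML are
  written for external viewers).
- `group_share` is a share of *terms*; a share of associated genes is a
  different statistic and is not computed.
- With fewer than ~8 significant terms per category, kappa groups are
  dominated by single-term components and group shares are coarse.
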