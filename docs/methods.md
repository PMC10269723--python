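# Methods

This note describes the models and procedures `opucore` implements, the
defaults it ships, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the conventions of the field
leave room.

## OPU delineation

Queries (OTU representatives) and references (named 16S sequences with a
taxonomy and a type-strain flag) are tips of one rooted tree. For each
query tip the *anchor* is its closest ancestor whose subtree contains at
least one reference tip; queries sharing an anchor node form one OPU, so
an OPU is exactly the smallest monophyletic clade holding those queries
and ≥1 reference. This ascent is the deterministic automation of what is
traditionally done by manual inspection of a neighbour-joining tree, and
it is validated in the test suite against an independent brute-force
oracle that enumerates every clade of the tree (scikit-bio traversal, a
separate code path from the dendropy implementation) on random trees of up
to 20 tips.

Practical choices:

* **Rooting.** The ascent needs a root. Input whose basal node is a
  polytomy is treated as unrooted and midpoint-rooted when branch lengths
  are available; otherwise it is used as given.
* **Multifurcations** are allowed anywhere; a node "contains" a reference
  iff any descendant tip is one.
* Duplicate tip labels and trees without reference tips are errors.

## OPU classification

Let *I* be the best identity of the OPU's representative (its most
frequent OTU; ties to the smallest label) to any **type strain** —
identities to non-type references never trigger a known-species call.
With defaults `species_identity = 98.7`, `genus_identity = 94.5` (percent):

1. *I* ≥ 98.7 → `KNOWN_SPECIES` of that type strain;
2. 94.5 ≤ *I* < 98.7 → `NEW_SPECIES` in the type strain's genus;
3. *I* < 94.5 (or no type-strain identity at all) → the anchor clade
   decides: take the most specific rank shared by all anchor references
   and call the OPU a new lineage one level below it (shared family →
   `UNCULTURED_GENUS`, shared order → `UNCULTURED_FAMILY`, shared class →
   `UNCULTURED_ORDER`, shared phylum → `UNCULTURED_CLASS`). If the
   references share a **genus**, clade evidence outranks the weak identity
   and the OPU is a `NEW_SPECIES` of that genus — the same precedence of
   phylogenetic embedding over distance used for genome rank assignment.

Boundary equalities are resolved as half-open intervals toward the more
specific call (exactly 98.7 is known; exactly 94.5 is a new species),
giving total, consistent coverage of [0, 100]. Anchors that share no named
rank at all are clamped to `UNCULTURED_CLASS` with an empty taxon — the
deepest novelty the category set can express.

## Amplicon QC

The in-scope slice of read QC is the length window: full-length 16S
amplicons are kept iff 1,200 ≤ L ≤ 1,600 bp (inclusive at both ends — the
convention removes reads strictly outside the window). The retention
summary reports `100·retained/raw` rounded **half-even** to two decimals,
which reproduces the percentages surveys print next to their read counts
(e.g. 1,035,221 of 1,408,058 reads → 73.52 %).

## Community profile

* Relative abundance is per-sample row normalisation.
* Prevalence is the fraction of samples with count > 0.
* Core detection defaults to the strict reading "present in **more than**
  90 % of samples"; a non-strict (≥) toggle covers the other convention in
  circulation. Both the threshold and the comparison are configurable
  because both conventions appear in practice.
* The core set's abundance is summarised per sample (sum of core OPUs'
  relative abundances) and reported as mean ± sd across samples — the way
  stacked-bar figures are read.
* Richness is the per-sample count of OPUs with count > 0, reported as
  mean ± sd. All "±" summaries use the sample (n−1) standard deviation,
  the usual convention for such figures; a single sample reports sd 0.

## SGB quality, clustering and rank

* **Quality score** `completeness − 5·contamination +
  contamination·(SH/100) + 0.5·log10(N50)` — the dRep scoring formula;
  the logarithm is base 10, matching dRep's use of log₁₀(N50). The score
  is strictly increasing in completeness and N50 and strictly decreasing
  in contamination (the effective coefficient −5 + SH/100 ≤ −4).
* **Tiers**: near-complete (≥90 % completeness, ≤5 % contamination),
  medium (≥70 %, ≤10 %), partial (≥50 %, ≤5 %), else fail — evaluated in
  that order.
* **Strict filter** for clustering input: completeness − 5·contamination
  ≥ 50, completeness > 50 %, contamination < 10 %.
* **Clustering** at an ANI threshold is single-linkage: connected
  components of the graph with edges where ANI ≥ threshold. The threshold
  semantics are delegated to by dRep without a printed algorithm; single
  linkage is the simplest threshold-faithful choice and is checked against
  a connected-components oracle. Missing matrix cells count as below
  threshold; conflicting asymmetric cells (difference > 0.1) are an input
  error. Representatives maximise the quality score, ties to the smallest
  id. The two-stage workflow (99 % dereplication, then 95 % species
  clustering of representatives) is equivalent to direct 95 % clustering
  when ANI bands are separated, and the 99 % clustering always refines the
  95 % clustering.
* **Rank cascade** (defaults 95 ANI / 95, 65, 50 AAI): (1) ANI ≥ 95 →
  known species; (2) AAI ≥ 95 → known species; (3) 65 ≤ AAI < 95 → novel
  species in the nearest named genus; (4) AAI < 65 but the SGB is embedded
  in a known genus clade → novel species with the override flag set; (5)
  50 ≤ AAI < 65 → novel genus (family-level placement); (6) AAI < 50 →
  order-level novelty. AAI rank bands overlap in nature; the
  most-specific-rank-first order of the cascade plus the clade override
  resolves them, mirroring the precedence of phylogenetic embedding.
  Boundary equality goes to the more specific rank (AAI exactly 65 is the
  genus band). Clade membership is an externally supplied label (e.g. from
  a phylogenomic placement tool); tree inference itself is out of scope.
  Evidence maps may be partial; an SGB with no ANI, no AAI and no clade
  label is unclassifiable and raises.

## Synthetic data generator

The generator's defaults are the package's reference study conditions:
30 samples, 200 query OTUs, 5 core OPUs, 3 species clusters × 2 strains,
and a 24-species backbone (2 phyla / 3 classes / 4 orders / 6 families /
12 genera). What it emulates, and how:

* **Backbone**: taxa at each rank are distributed round-robin over the
  rank above and sibling subtrees joined into ladders, giving a rooted
  bifurcating tree whose tip lineages realise `lineage_shape` exactly;
  every species tip is a type strain.
* **Queries** are grouped into planted OPUs of 1–3 members cycling through
  the known / new / uncultured categories. Known and new OPUs are grafted
  sister to a random type-strain tip; uncultured OPUs basal to a clade
  whose references share exactly a family, order or class (so the planted
  category is the fine-grained uncultured rank). Pendant branches are
  short, so planted membership equals the minimal-anchored-clade answer by
  construction, and stacked grafts on the same anchor nest without merging.
* **Identities** are drawn from per-category bands — (98.9, 100] known,
  (94.7, 98.5] new, (85, 94.3) uncultured — that keep ε = 0.2 percentage
  points clear of the 98.7/94.5 thresholds (avoiding float ties);
  identities to all other references sit at least one point lower.
  Identity values are independent of branch lengths, as in the real
  procedure where identities come from alignment, not the tree.
* **Abundance**: core OPUs are present in ≥ ⌈0.95·n⌉ samples (default
  `core_prevalence = 0.95`, safely above the 0.9 detection threshold under
  both the strict and non-strict conventions); every other OPU in strictly
  fewer samples than the detection threshold's worth. Counts are rounded
  log-normal draws (σ = 1); core OPUs get a higher median (150 vs 10) so
  the planted core carries roughly two-thirds of each sample's reads — the
  prevalence–abundance structure typical of wild-mammal gut communities.
  A configuration whose `core_prevalence` does not exceed the detection
  threshold warns that recovery is not guaranteed.
* **Genomes**: within-cluster ANI from (95.5, 99.9), between-cluster from
  (80, 90) — disjoint around the 95 % boundary by ε. Each cluster's AAI to
  its nearest named taxon comes from the band of its planted rank
  (novel species (70, 90), novel genus (52, 63), order-level (40, 48));
  clusters listed in `clade_override_clusters` additionally carry a known
  genus clade label, so the expected call becomes novel species with the
  override flag. Quality metrics are uniform draws from `quality_ranges`.
* **Read lengths** are normal around 1,445 bp (sd 120) — plumbing so the
  QC stage has input; no sequences, chimeras or error models are ever
  generated.

Same config and seed give byte-identical artifacts (fixed float formats,
one `numpy` generator per stage seeded from `(seed, stage)`).

**What passing tests show — and don't.** Exact recovery on this generator
demonstrates that the algorithms implement their definitions correctly
under separated evidence bands. Real surveys violate those separations:
identities cluster near thresholds, trees contain alignment and inference
error, ANI/AAI matrices are incomplete and noisy, and reference taxonomies
have gaps. Recovery rates on real data will be lower, and the boundary
behaviour documented above (half-open intervals, clade precedence) then
matters materially.

## Pipeline

`run_all` executes simulate → qc → opu → core → sgb from one JSON/YAML
document; every threshold is a named key with the defaults above. Outputs
are plain text (Newick, TSV, JSON); the manifest hashes inputs and lists
outputs but carries no timestamps, so identical config + seed reproduce
identical runs. Stage failures raise with the stage name; the CLI maps
config errors to exit 1 and stage failures to exit 2. The abundance
table's columns are joined to called OPU categories either directly (when
columns are OPU ids) or through an explicit OTU-grouping file; a column
whose members span multiple called OPUs takes the majority category.

## Problem sizes

Defaults throughout (200 queries on a 24-reference backbone, 30 samples,
6 genomes, 1,000 random oracle trees of ≤ 20 tips) were chosen so the full
test suite and the acceptance script each complete in seconds while still
exercising nested anchors, every category, both clustering stages and
every rank band.

## Known limitations

* Alignment, OTU clustering, tree inference, chimera detection, CheckM,
  GTDB-Tk, OrthoANI/comparem are upstream tools whose outputs this package
  consumes; none is reimplemented.
* Single-linkage clustering can chain distinct species through
  intermediate genomes when ANI bands are not separated; this is inherent
  to threshold semantics, not a defect of the implementation.
* The uncultured category set stops at `UNCULTURED_CLASS`; deeper novelty
  (new phyla) is clamped to it.
* The generator plants at most one nearest named taxon per genome cluster
  and gives all members of a cluster identical AAI rows; real AAI matrices
  vary within clusters.
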