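# Methods

`mirclust` implements the statistical layer of a curated miRNA–disease
expression analysis: genomic cluster calling, study-design concordance
scores, a cluster expression-homogeneity permutation test, and log-odds
(LOD) cluster-enrichment statistics with a global shuffling null.  This
note records the models, the choices made where the procedures were
genuinely open, and what the synthetic validation does and does not show.

## Input model

The analysis is driven by two inputs:

* a **curated annotation table** (TSV): one row per data point, i.e. one
  deregulated miRNA in one published study entry, with the disease term,
  the study design (`in_vivo` = patient material, `in_vitro` = cell
  culture), the detection method (`microarray`, `rtpcr`, `northern`,
  `other`), the direction of deregulation (`up`/`down`), and optional
  fold-change and cohort size;
* **miRNA gene coordinates** in GFF3 (e.g. a miRBase genome annotation),
  1-based inclusive, one locus per `miRNA_primary_transcript` record.

miRNA names are normalized to the lowercase precursor stem: species
prefixes (`hsa-`), mature-arm suffixes (`-5p`, `-3p`, `*`) and the
`miR`/`mir` case distinction are collapsed, while letter-suffixed paralogs
(`mir-125a` vs `mir-125b`) remain distinct, because clusters are
precursor-level genomic units.  This is a declared convention — curated
literature data do not record how mature and precursor designations were
reconciled — and an alias table can override individual mappings.
Duplicate data points (same entry, miRNA and direction) keep their first
occurrence, deterministically.

## Cluster calling

A **miRNA cluster** is a set of miRNAs in which each member lies within a
distance threshold (default 5 kb; 10 kb and 50 kb are common alternatives)
of at least one other member on the same chromosome: the connected
components, of size ≥ 2, of the pairwise "within threshold" relation,
computed by single-linkage chaining per chromosome.  Everything else is a
singleton; clusters and singletons partition the input.

Two conventions are configurable because "within d kb" underdetermines the
anchor:

* `anchor="gap"` (default): the separation is the gap between nearest
  ends, zero when loci overlap — the conservative reading of "within";
* `anchor="start"`: start-to-start distance.

Strand is ignored by default (clusters are defined by chromosomal location
only); `respect_strand=True` restricts linkage to same-strand pairs.
Cluster identifiers are deterministic (`<chrom>:<leftmost member>`), so
outputs are stable across runs and input orderings.

## Consistency scores

Within one disease, the **intra-consistency score** of a design is the
fraction of miRNAs, among those annotated by at least two study entries in
that design, whose calls are unanimous.  Groups are keyed by
`(entry, direction)` so that exact curation duplicates do not inflate
evidence.

For the **cross-consistency score**, each miRNA receives a per-design
consensus: unanimous multi-entry groups and single-entry groups carry
their direction; conflicting groups are `inconsistent`.  Among miRNAs with
a defined consensus in *both* designs, the score is the fraction whose
directions agree.  miRNAs that are `inconsistent` in either design are
excluded from the denominator by default — no direction comparison is
possible — but `strict_denominator=True` keeps them as non-consistent, as
a sensitivity analysis.  miRNAs observed in only one design are never
comparable and are always excluded.  A coverage gate (default: at least 3
cross-eligible miRNAs) flags diseases whose scores rest on very little
data; they are reported, not dropped.

## Cluster expression homogeneity

Per disease, each miRNA's observations (all designs and methods pooled)
collapse to a majority-vote direction; tied votes drop the miRNA from that
disease.  A cluster is **present** in a disease when at least half of its
members carry a consensus there — both members, for two-member clusters —
and **homogeneous** when all present members share one direction.  The
presence rule is applied as "present ≥ half" (a cluster with exactly half
its members annotated is kept); the complementary reading (discard at
exactly half absent) differs only at even cluster sizes and is noted here
because published descriptions of this filter are ambiguous.  The
**homogeneous-fraction** of a cluster is T/(T+F) over the diseases where
it is present.

**Permutation null.**  Within every disease independently, the observed
up/down labels are redistributed uniformly at random over that disease's
annotated miRNAs — cluster members and non-members alike — preserving the
disease's up/down totals; the cluster's homogeneous fraction is recomputed
over the same present-sets.  Implementation note: under this label
shuffle, the number of "up" labels landing on a cluster's k present
members is exactly hypergeometric in the disease's (up, down) totals, so
the Monte-Carlo draws use `Generator.hypergeometric` per disease rather
than materializing label vectors; this is an exact, not approximate,
equivalence, and the test suite checks it against brute-force enumeration
of label placements.

Two tie rules are provided for the p-value over `n_permutations` (default
10,000) draws:

* `strict` (default): the fraction of sampled homogeneous fractions
  *strictly exceeding* the observed one.  This matches the historical
  definition but yields p = 0 for any cluster with observed fraction 1.
* `inclusive`: counts ties, giving a valid (conservative) test level;
  recommended for inference and used in the type-I calibration tests.

No multiple-testing correction is applied by default (the historical
procedure applied none at its 0.05 threshold); Benjamini–Hochberg
q-values are available behind a flag.  Per-cluster RNG streams are
derived from the root seed and a CRC of the cluster id, so per-cluster
p-values do not depend on cluster iteration order.

## Cluster enrichment (LOD scores)

Only patient-study microarray data enter by default (`design=in_vivo`,
`method=microarray`): profiling platforms survey most known miRNAs, so
targeted assays (RT-PCR, northern) would bias the clustered fraction.
Disease association is a set property — a miRNA reported up in one study
and down in another still counts once.

With genome-wide background counts x_overall (clustered miRNAs),
y_overall (non-clustered) and n_loci (clusters), and per-disease counts
x_d / y_d:

    LOD_d       = log2( (x_d /(x_d +y_d)) / (x_overall/(x_overall+y_overall)) )
    LOD_d,locus = log2( (l_d /(l_d +y_d)) / (n_loci  /(n_loci  +y_overall)) )   l_d = distinct clusters hit
    LOD_d,non   = log2( (y_d /(x_d +y_d)) / (y_overall/(x_overall+y_overall)) )

x_d = 0 (resp. l_d = 0, y_d = 0) yields a negative-infinite sentinel,
excluded from means and counted as non-positive in the global test.  Note
the non-cluster score is computed from its explicit formula; it is *not*
algebraically equal to −LOD_d, although historical descriptions state so.
Diseases are classified as **enriched** (LOD > 0), **depleted** (fewer
cluster miRNAs than `min_cluster_mirnas`, default 1, i.e. none), or
**neutral** otherwise.

**Global shuffle test.**  "Shuffling the genomic positions of each
disease's miRNAs" is operationalized as label shuffling: each shuffle
re-draws, per disease, which of its n_d associated miRNAs are cluster
members by sampling without replacement from the genome-wide pool of
x_overall cluster / y_overall non-cluster labels (a hypergeometric draw of
x_d).  This preserves exactly the quantities entering the LOD.  Per
shuffle the number of diseases with positive LOD is counted; the p-value
is the fraction of `n_shuffles` (default 100,000) shuffles with *at least
as many* positive LODs as observed (inclusive rule — deliberately
different from the homogeneity test's strict rule; each follows its
source definition).  Positivity is decided in integer arithmetic
(x·total > x_overall·n_d) to avoid floating-point ties at the background
ratio.

Because "average fold enrichment" is ambiguous, three summaries are
reported over enriched diseases: the mean LOD, 2^(mean LOD), and the mean
of per-disease 2^LOD.

## Synthetic data generator

The generator plants known ground truth for every stage:

* **Genome**: `round(n_mirnas × clustered_fraction)` miRNAs are laid out
  in clusters (sizes from a truncated geometric law on 2–6, or an explicit
  size list), members separated by `intra_cluster_gap_bp` (1 kb) and loci
  by `inter_locus_gap_bp` (100 kb), spread round-robin over chromosomes.
  Deterministic gaps make cluster recovery exact at any threshold between
  the two, isolating the statistics under test from clustering edge cases;
  `randomize_placement=True` draws the gaps randomly for clustering stress
  tests.  Defaults (695 miRNAs, clustered fraction 0.345) mirror the human
  miRNA complement at a 5-kb threshold.
* **Disease associations**: candidates are visited in random order; a
  clustered candidate recruits its whole cluster with one shared direction
  with probability ρ (cluster co-deregulation), otherwise — and always for
  singletons — it enters alone with an independent direction
  (Bernoulli(`direction_up_prob`), default 0.5).  Accumulation stops at
  `mirnas_per_disease`; whole-cluster recruitment can overshoot by at most
  one cluster.  Recruiting clusters as units makes clustered miRNAs
  over-represented relative to the uniform background in proportion to ρ,
  which is what the enrichment analysis should detect; at ρ = 0 the
  selection is uniform without replacement, i.e. exactly the hypergeometric
  null of the global test.
* **Study entries**: each disease receives `entries_per_design` patient
  entries (microarray, with cohort sizes) reporting the planted
  directions, and the same number of cell-culture entries.  One in-vitro
  direction per miRNA is drawn — the planted one with probability κ,
  flipped otherwise — and shared by that disease's in-vitro entries, so
  measured cross-consistency estimates κ directly.  (Independent per-entry
  flips would make the agreement among eligible miRNAs a nonlinear
  function of κ.)  Fold-changes are log-normal placeholders; they exercise
  the column, not any real effect-size distribution.

What the generator does **not** emulate: real disease-size and
fold-change distributions, within-design measurement noise
(intra-consistency is 1.0 by construction), correlated study biases,
annotation errors, or the uneven coverage of a curated database.  Passing
the synthetic validation therefore shows the procedures are implemented
correctly and calibrated under their own null, not that any particular
biological dataset will reproduce specific published values.

## Validation summary

* Cluster calling is checked against a brute-force transitive-closure
  oracle on random genomes, plus partition/order-invariance and threshold
  monotonicity properties.
* Both Monte-Carlo tests are checked against exhaustive enumeration on
  small fixtures (≤ 8 miRNAs per disease) to within 3 standard errors.
* LOD identities: zero at the background ratio, strict monotonicity in
  x_d, agreement with an independent evaluation to 1e-12 relative error.
* Parameter recovery: mean cross-consistency within ±0.05 of planted
  κ ∈ {0, 0.5, 0.75, 1} at 300 miRNAs/disease; at ρ = 0.8 and 200
  miRNAs/disease ≥ 80% of diseases classify enriched with global
  p < 0.01; at ρ = 0, over 200 simulated datasets, ≤ 8% of clusters reach
  inclusive p < 0.05 and the global test rejects at most 8% of the time.
  The calibration runs use 2,000 permutations/shuffles per dataset and
  reduced dataset sizes (150 miRNAs, 8 diseases of 50); these sizes were
  chosen as the smallest at which the Monte-Carlo error is negligible
  against the 0.05/0.08 margins.
* Determinism: identical configuration and seed reproduce every
  statistical output byte-exactly; per-cluster results are independent of
  cluster iteration order.

## Known limitations

* The strict tie rule reports p = 0 for perfectly homogeneous clusters;
  use the inclusive rule when a valid test level matters.
* The homogeneity null conditions on each disease's up/down totals; in
  strongly unidirectional diseases the null homogeneity probability is
  close to 1 and the test has essentially no power — by design, since
  that is exactly the confounder the conditioning removes.
* Consensus building (majority vote, tie-drop) is one of several
  defensible collapsing rules; with heavily conflicting curation the
  homogeneity and enrichment inputs depend on this choice.
* Locus-level LOD treats any cluster with ≥ 1 associated member as "hit";
  no partial-credit weighting is attempted.
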