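# Methods note

This note records the model assumptions, parameter choices, numerical
conventions, and scope limits behind `siptraits`.

## 1. Labeled-contig identification

A contig is called ¹³C-labeled in a treatment when all three hold:

- assembly length strictly greater than 1,000 bp (short contigs have
  unstable coverage estimates);
- raw mean depth in the ¹³C library at least 5× (inclusive);
- normalized fold enrichment at least 1.5 (inclusive), where the
  normalized coverage is depth divided by the library's total read count
  and the fold is the ¹³C-to-¹²C ratio of normalized coverages, paired
  by harvest day.

Zero conventions: a contig absent from the ¹²C control but present in
the ¹³C library has infinite fold (passes the fold criterion); absent
from both gives fold 0. No pseudocounts are added anywhere in the
filter — the raw-depth floor already guards against low-coverage
ratio instability. All three thresholds are configurable
(`LabelingThresholds`); the inclusive readings (≥) are the operative
defaults.

## 2. Feature census

Eight features are counted per unit (genome, MAG, or labeled-contig
pool). Seven are gene-level and classified from normalized product
strings (whitespace collapsed; case-insensitive by default) plus
precomputed annotation flags:

- **MCP** — methyl-accepting chemotaxis protein terms.
- **MT** — transporter terms (transporter, antiporter, symporter,
  channel, efflux/uptake/translocating ATPase and pump terms) AND at
  least one predicted transmembrane helix. The bare string "transport
  protein" is deliberately not a term; term matching is substring-based
  but the term list is curated to avoid such generic strings.
- **ADH** — adhesion. Default mode `exact`: the full product name must
  equal one of 11 curated names. Mode `terms`: substring match on
  adhesion/adhesin, for externally annotated collections whose product
  vocabulary differs.
- **TF** — transcription factor / regulator / repressor / activator /
  sigma factor terms, plus the family wildcard
  `transcriptional <word> regulator`, plus an optional upstream
  sequence-based TF predictor flag (`tf_pred`).
- **OSM** — osmotic stress terms (osmotically inducible, osmolarity
  sensor, osmoprotectant, ectoine synthesis, OmpR, etc.).
- **DOR** — dormancy machinery: sporulation regulators,
  resuscitation-promoting factors, and toxin/antitoxin systems.
- **SE** — secreted depolymerizing enzymes: a CAZy family in class
  GH/PL/CE, a protease hit, or an α/β-hydrolase hit, AND a predicted
  secretion signal peptide. GT and CBM families do not count. Signal
  peptides should be predicted with the gram-positive model for
  Firmicutes/Actinobacteria lineages; a recorded mismatch is logged and
  the gene kept.
- **SM** — secondary metabolite biosynthetic gene clusters (SMBCs).
  Cluster detection is an upstream annotator's job; the package takes
  per-genome cluster counts, total genes in clusters, and the count of
  genes that are simultaneously SE hits (for de-duplication).

Frequencies are percent of protein-coding genes, except SM, whose
abundance is clusters per protein-coding gene (not percent). A unit
with zero genes has undefined frequencies and raises rather than
returning 0. The rule lists live in `rules/default.yaml` and are fully
overridable.

Two classification routes exist on purpose: `classify_gene` is a pure
per-record reference implementation; `classify_table` is the vectorized
production path. Property tests enforce their equivalence.

## 3. Activity characteristics and MAG↔OTU mapping

Per OTU:

- **max LFC** = log₂((max abundance + ε) / (abundance at t₀ + ε)),
  maximum over all time points including t₀ (so a series peaking at t₀
  gives 0). ε defaults to 0; a zero baseline then raises instead of
  silently producing ∞.
- **bioavailability** = arithmetic mean of the operational
  bioavailability scores of the distinct assimilated substrates (a
  substrate assimilated at several time points counts once).
- **latency** = first labeling day − substrate mineralization peak day,
  averaged over substrates (mean by default, median selectable).
  Negative latency means labeling before the mineralization peak.
  First labeling days default to the earliest labeled treatment day per
  substrate when no explicit labeling time course is supplied.

MAGs carry no amplicon identity, so a MAG inherits activity from OTUs
that (a) share its taxon name at the MAG's deepest assigned rank
(exact name match, no fallback to shallower ranks) and (b) are labeled
in the MAG's treatment of origin. Characteristics are averaged over the
matched set. An empty match is a discard signal (`None`), not an
error: inventing activity for an unmatched MAG would be worse than
dropping it.

## 4. Statistics

- Pearson correlation and its t-test, Kruskal-Wallis (tie-corrected),
  rank utilities, and normal/χ² tails come from scipy; Benjamini-
  Hochberg and Holm adjustments from statsmodels. A fully tied
  Kruskal-Wallis data set returns H = 0, p = 1.
- The Dunn post hoc test is implemented in the package (no maintained
  dependency provides it): pooled mid-ranks,
  z_ij = (R̄_i − R̄_j) / √((N(N+1)/12 − T)(1/n_i + 1/n_j)) with tie
  term T = Σ(t³ − t) / (12(N − 1)), two-sided normal p-values, BH
  adjustment across pairs by default.
- The feature–activity screen tests every (feature, characteristic)
  pair across aligned units and adjusts within characteristic. The BH
  family size defaults to the number of features tested but can be
  pinned larger (`bh_family`), in which case the p-vector is padded
  with 1.0 so adjusted values behave as if that many tests were run.

## 5. Life history clustering

Trade-off axes: `tf_per_gene` = TF count / gene count, and
`acquisition_ratio` = (SE + SM genes − overlap) / MT. The overlap
(genes both secreted-enzyme and inside an SMBC) is subtracted once so
no gene is counted twice. Units with MT = 0 have an undefined ratio
and are excluded with a warning rather than mapped to infinity.

Clustering is k-means (k = 3 default) on z-scored axes — Lloyd's
algorithm, Euclidean distance, best of 25 seeded random restarts; the
seed is mandatory. Scaling uses the training mean and standard
deviation (ddof = 1) and is stored in the model; prediction projects
new units with the TRAINING scaling and assigns the nearest centroid,
ties to the lowest cluster index. Strategy names for k = 3 come from
the unscaled centroids: S (scarcity specialist) is the lowest
tf_per_gene centroid; of the remaining two, C (competitor) has the
higher acquisition ratio and R (ruderal) the lower. Exact centroid
ties break to the lowest cluster index with a warning. Cluster
characterization applies Kruskal-Wallis per value column with Dunn
pairs where the omnibus p < α.

## 6. Synthetic community generator

The generator exists to give every stage a planted ground truth; its
defaults are the package's study conditions and are not fit to any
external data set.

- **Genomes.** Three archetypes (C, S, R) with mean feature
  frequencies per 100 genes chosen so the trade-off axes separate by
  ≥ 3 pooled standard deviations at the default count dispersion
  (C: TF 3.0, SE 2.0, MT 2.0, SM genes 1.0; S: TF 1.2, SE 1.2,
  MT 2.5, SM 0.30; R: TF 3.2, SE 0.5, MT 4.0, SM 0.25; plus MCP, ADH,
  OSM, DOR at archetype-specific rates). Mean genome size 4,000 genes;
  one contig per 100 genes at 1,000 bp per gene. Product strings are
  drawn from the census rule vocabularies plus near-miss decoys
  ("transport protein", "chemotaxis protein CheY", "surface
  adhesion-like protein", …) that a sloppy matcher would miscount, and
  inert filler. Planted per-genome counts are recorded as truth.
- **Counts.** All counts are negative binomial with variance
  (1 + dispersion) · mean (r = mean/dispersion, p = 1/(1+dispersion)),
  a parameterization in which depth noise shrinks with coverage.
  Dispersion 0 switches every stochastic quantity to its deterministic
  expectation, which the exact-recovery tests exploit. Default
  dispersion 0.3.
- **Design.** Eight ¹³C treatments across five harvest days with
  day-shared ¹²C controls → 13 libraries. Base depth 50× at the
  reference read count (2 × 10⁶), planted fold 3 for contigs of
  labeled genomes. Base depth was chosen by an upfront
  operating-characteristics sweep: at pure negative-binomial dispersion
  0.3 it yields labeling specificity ≈ 0.958 and sensitivity ≈ 1.0;
  lower depths fail the specificity target. Two optional realism knobs
  — lognormal per-contig base-depth spread (σ = 0.3) and read-count
  variation (cv = 0.2) — are on by default and cost roughly half a
  point of specificity; the operating-characteristics tests use the
  pure negative-binomial condition.
- **Substrate use.** Each genome's assimilated substrates are chosen
  by proximity of the substrate's bioavailability score to the
  archetype's preferred bioavailability (deterministically closest when
  noise is off), with archetype-specific breadth. This yields the
  labeling map used by both the coverage simulator and the OTU table.
- **OTU activity.** One OTU per genome; the abundance series rises
  log-linearly from baseline to exactly baseline · 2^maxLFC at the peak
  day and decays 30% per subsequent sampling point, so the computed
  characteristic recovers the planted value exactly when noise is off.
  First labeling days sit at substrate peak + archetype latency.
- **Screen generator.** For screen operating characteristics the
  planted feature's frequencies form a fixed, evenly spaced design
  across the treatment units (feature abundances are fixed properties
  of the pooled contigs, not resampled per replicate); the
  characteristic is that design plus Gaussian noise scaled to the
  target population correlation ρ. At n = 8 units, ρ = 0.9, BH family
  8, α = 0.05 this fixed design gives ≈ 0.89 power, whereas random
  bivariate resampling of x would give ≈ 0.75.

### Generator limits

The generator plants structure; it does not model assembly, binning,
chimeric contigs, strain heterogeneity, compositionality of relative
abundances, GC/mappability coverage biases, cross-feeding beyond the
latency dial, or genome incompleteness. Conclusions about the
pipeline's behavior on real data are limited accordingly.

## 7. Problem sizes and runtime

Chosen for desk-scale verification on one CPU: recovery experiments use
~50 genomes (≈ 200k genes, ≈ 2,000 contigs) × 13 libraries and run in
seconds; screen and characterization power use 50–100 replicates of
8-unit designs; clustering recovery uses 60 genomes × 20 seeds. The
whole pytest suite runs in well under two minutes; the acceptance
script in under ten seconds. Scaling to realistic inputs (10⁵–10⁶
contigs) is linear in contigs for the filter and in genes for the
census (vectorized pandas string matching).

## 8. Numerical conventions

- Explicit seeds are required by every stochastic entry point; derived
  sub-seeds are drawn below 2³¹.
- Standard deviations use ddof = 1 throughout scaling.
- Mid-ranks for ties in all rank statistics.
- Frequencies reported in percent; SM abundance per gene.
- TSV everywhere, `#` comments, UTF-8; the depth-table reader accepts
  the jgi_summarize_bam_contig_depths dialect (`contigName`,
  `contigLen`, `totalAvgDepth`, per-sample `.bam` columns with `-var`
  columns ignored).
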