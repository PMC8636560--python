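# Methods

## Scope and data model

The pipeline starts at a sample × OTU table of nonnegative integer read
counts, with a taxonomy assigning every OTU to one category from a closed,
config-declared vocabulary (family level or coarser), per-sample metadata
(gut vs. water, predator group and species, feeding habit, station), and an
elimination-rule set. Everything upstream — read QC, merging, OTU
clustering, taxonomic classification — is the province of existing amplicon
workflows and is deliberately out of scope.

## Filtering and standardization

**Elimination.** For each gut sample, counts of OTUs whose category is in
the predator group's eliminated set are zeroed. The shipped default config
(`src/trophonet/data/default_rules.yaml`) covers 22 mesozooplankton groups:
every group eliminates its own taxon (host DNA) plus the global
contaminants Craniata and Fungi, and the strictly carnivorous groups
(Chaetognatha, Candaciidae, Euchaetidae, Hydrozoa, Amphipoda) additionally
eliminate the `Phytoplankton` macro-category. The macro-category expands to
the autotroph categories listed under `phytoplankton_categories`
(dinoflagellates and chlorophytes by default). Dinoflagellates are treated
as phytoplankton even though many are heterotrophic; this is an assumption
of the default config and editable there. Water samples always pass through
unchanged, and OTUs left without reads anywhere are dropped.

**Dominant-OTU selection.** Each sample keeps its *k* = 10 highest-count
prey OTUs (fewer if fewer are nonzero), ties at the cut broken by ascending
OTU id for determinism. Selection runs *after* elimination, so the ten
slots are spent on genuine prey; this ordering is a design choice.

**Standardization.** Retained counts are divided by their sum, giving
proportions over the selected dominant OTUs ("standardized sequence
reads"). The denominator is the sum over the *selected* OTUs — so the
displayed proportions total 100% — rather than over all prey OTUs; both
conventions are defensible and the narrower one matches how such profiles
are plotted. Samples with no prey reads left are flagged in a QC table and
excluded from group means and frequencies rather than silently dropped.

**Group summaries.** Mean proportions are arithmetic means over a group's
non-empty profiles; the appearance frequency of a category is the fraction
of non-empty profiles where it exceeds `min_presence` (default 0: any
nonzero standardized reads — no minimum-read cutoff is imposed, and the
threshold is exposed for sensitivity analysis). Appearance frequency is by
construction invariant to per-sample read depth.

## Similarity, clustering, ordination

Profiles are square-root transformed (damping dominant prey) and compared
with percent Bray–Curtis similarity. Pairs of all-zero items have undefined
similarity; they are set to 0 and flagged. Clustering is group-average
linkage (UPGMA) on dissimilarity `100 − S`, computed with scipy; a cut at
threshold *t* yields the maximal clusters merged at similarity ≥ *t*. Items
enter the linkage in lexicographic order so exact merge ties resolve
deterministically, and output labels are numbered 1… in order of first
appearance. Default cut levels are 30, 40 and 50 percent.

NMDS is a nonmetric SMACOF implemented in-package: alternating Guttman
majorization steps with an isotonic (PAVA, via
`scipy.optimize.isotonic_regression`) fit of configuration distances to the
dissimilarity rank order. Tie handling is the *primary* (weak) approach —
within blocks of equal dissimilarity the distances are pre-sorted, so ties
impose no order constraint. Stress is Kruskal's stress-1. Each run uses one
classical-scaling (Torgerson) start plus `n_restarts − 1` = 19 seeded random
starts; within a run, only stress-improving iterations are accepted (an
iteration that would raise stress-1 terminates the restart), iteration stops
when the improvement falls below `tol` = 1e-6 or at `max_iter` = 500, and
the best restart is reported, centered and rotated to principal axes with a
deterministic sign convention. On a 30-item five-blob benchmark the
implementation matches scikit-learn's nonmetric MDS to five decimals of
stress-1 (both ≈ 0.219 — blob structures genuinely do not embed with low
stress in two dimensions; NMDS preserves only rank order, so rank-equivalent
items may coincide). By default the pipeline ordinates group-mean profiles
(as such plots are usually drawn); per-individual ordination is a config
switch (`ordination_level: individuals`). All-zero profiles are excluded
from ordination with a warning instead of being given arbitrary positions.

## Trophic networks and PageRank

One node per predator group and per prey category, merged (role `both`)
when labels coincide. Edges point predator → prey — the direction of energy
flow — so random-walk mass accumulates on widely eaten prey, which is what
makes staple prey the top-ranked hubs; a `--reverse-edges` flag serves the
opposite convention. Edge weight is the group's mean proportion of the prey
(reads mode, default threshold 0.01 to suppress numerically-trace
fractions) or its appearance frequency (frequency mode, threshold 0).

PageRank uses power iteration on the column-stochastic matrix of
weight-normalized out-edges, uniform teleportation with damping 0.85 (the
default of the igraph function commonly used for this analysis), uniform
redistribution of dangling-node mass, and L1 convergence tolerance 1e-12.
Scores sum to 1 at every iteration. Weighted mode is the default;
unweighted mode collapses weights to 1. Hub ranking is by descending score
with lexicographic tie-break.

## Synthetic-data generator

Each gut individual's diet is `Dirichlet(c · mean_diet)` around its group's
mean with concentration `c` = 20 — the simplest overdispersed model for
individual-level diet variation; smaller `c` means noisier individuals. The
read-generating composition adds `host_read_fraction` = 0.30 on the host's
own category and contaminant fractions 0.27 (Fungi) and 0.29 (Craniata),
mirroring the contamination levels typical of gut-content 18S libraries;
prey mass is re-weighted by per-category rDNA copy-number multipliers
(18S read share ∝ cells × copies, applied multiplicatively before
renormalization; default 1) and split over 3 OTUs per category with a
geometric 0.3 decay so each category has a clearly dominant OTU. Reads are
one multinomial draw per sample — fixed depth, as no per-individual depth
distribution is assumed; the read count is a plain config field if a
distribution is wanted. Water samples draw from a calanoid-dominated
ambient profile without host or contaminants. Every sample derives its own
RNG stream from `(seed, crc32(sample_id))`, so subsetting groups never
changes the remaining samples.

The bundled five-guild scenario plants five omnivorous copepod-family
guilds × 12 individuals at 14,286 reads each (≈ 2,000 expected prey reads
after host and contaminants), every guild sharing a 25% Calanoida staple
plus two guild-specific prey (45% + 30%), and designates Calanoida the
universal-prey hub. Recovery is judged against the *realized* planted
diets (the Dirichlet draws stored in `GroundTruth`), since with 12
replicates the Dirichlet sampling error alone (≈ 0.1/√12 per category)
exceeds any sensible tolerance on the prior mean; what the pipeline can and
should recover is what was actually planted. Under these conditions the
group means recover the planted diets to within ~0.01 absolute, a UPGMA cut
between the within- and between-guild similarity levels recovers the guild
partition exactly, and Calanoida wins the frequency-mode PageRank — the
verification study sizes run in seconds and are the package's standard
desk-scale configuration.

What the generator does **not** emulate: sequence-level artifacts (PCR
chimeras, sequencing error, index hopping), rank-correlated taxonomy errors,
compositional correlations between prey beyond the Dirichlet, station or
seasonal structure, and depth variation between individuals. Passing the
recovery tests therefore demonstrates correctness of the analysis chain on
its own model assumptions, not robustness to upstream artifacts.

## Numerical conventions and degenerate inputs

- Counts are validated as nonnegative integers on input; all downstream
  arithmetic is on float proportions. Round-trips are exact for integers
  and ≤ 1e-12 relative for floats.
- Bray–Curtis of two all-zero items is defined as 0 and flagged; the
  diagonal is always 100.
- An empty prey profile is represented as an empty mapping with
  `n_prey_reads` = 0, never as NaNs.
- PageRank rejects non-positive edge weights; non-convergence returns
  `converged=False` rather than raising.
- The pipeline writes plain TSV/GraphML/JSON with sorted keys and no
  timestamps, so identical config + seed reproduce the output directory
  byte for byte (the manifest hashes the configuration minus input/output
  paths).

## Known limitations

- Standardized proportions are compositional; no log-ratio treatment or
  rarefaction is applied (by design — the analysis chain under test uses
  simple proportioning), so cross-category correlations are partly
  artifactual.
- rDNA copy-number bias is simulated but not corrected; the estimator
  recovers the *biased* composition when multipliers differ from 1.
- NMDS minimizes a non-convex objective; with 20 restarts the reported
  stress matched an independent optimizer on every fixture tried, but
  global optimality is not guaranteed.
- The Phytoplankton macro-category treats all dinoflagellates as
  autotrophs; heterotrophic dinoflagellates eaten by carnivores are
  eliminated with them under the default config.
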