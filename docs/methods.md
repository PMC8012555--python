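# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, the parameters that matter, and what the synthetic
data does and does not emulate.

## Annotation model

Annotation is homology transfer guarded by domain evidence.  The candidate
stage keeps hits with e-value ≤ `max_evalue` (default 0.001) and local
identity ≥ `min_identity` (default 30%), where identity is computed over
the aligned columns of the matching region (gaps in the denominator), not
globally.  The single best hit per protein — maximal bit score, ties broken
by lower e-value, then higher identity, then lexicographically smallest
subject id — is the only annotation source; there is no rescue from
second-best hits.  The filter stage demands a shared catalytic-domain
family between query and best reference and, for that family, domain-in-
match coverage ≥ `min_domain_coverage` (default 0.80) on both sides, where
coverage is the 1-based inclusive overlap between the domain span and the
match region divided by the domain length.  "Same catalytic domain" is read
as same family label, existentially over multi-domain proteins, since a
protein with several domains should be creditable through any of them.
Both filters are conjunctive and evaluated identically wherever they occur,
so a threshold sweep can recycle one expensive search and replay only the
cheap filters; the sweep reports accepted sets, not just counts, so
monotonicity is checkable by set inclusion.  (Monotonicity in the identity
axis is guaranteed only while the best hit is stable — removing a best hit
can in principle promote a different reference that passes the domain rules
— but on data where the true source reference dominates the ranking the
accepted set shrinks monotonically, and the suite verifies this on the
generated bundles.)

Filter order (e-value before identity or vice versa) does not affect the
result set; both are applied conjunctively.  Coordinates are 1-based
inclusive everywhere, matching the 15-column tabular dialect (`qseqid
stitle pident qcovs qlen slen length mismatch gapopen qstart qend sstart
send evalue bitscore`) that the parser and writer treat as the interchange
format.  Query coverage (`qcovs`) is parsed and reported but not
thresholded: the candidate filter is about local identity at the matching
region only.

### Internal aligner

The built-in provider computes optimal Smith–Waterman local alignments
under BLOSUM62 with BLAST-convention affine gaps (a length-k gap costs
11 + k).  Bit scores use the standard gapped Karlin–Altschul parameters for
this scoring system (λ = 0.267, K = 0.041); e-values are computed over the
m·n search space of the single sequence pair.  That is smaller than a
database-wide e-value, which makes the internal filter slightly more
permissive than an external search at the same cutoff — immaterial here
because acceptance is decided by the identity and domain rules, and decoy
exclusion additionally rests on the absence of a domain scan.  The test
suite cross-checks the aligner against an independently written full-matrix
Gotoh dynamic program on random sequence pairs.

## Quality control

All comparisons follow the stated inequalities literally: N50 ≥ 50,000,
completeness ≥ 95.0, contamination ≤ 5.0 and exactly 31 marker genes pass.
A missing metric is itself a rejection reason (`missing-metric:<name>`),
and every rejection lists all failed criteria, so the filters are
order-independent and auditable.  N50 is the largest contig length whose
at-least-that-long contigs cover half the assembly.  The marine screen is a
case-insensitive substring match of an editable keyword list
(`src/marinepde/data/marine_words.txt`) against the free-text isolation
source; substring (rather than whole-field) matching was chosen because
real isolation-source strings are unstructured ("Deep-sea sediment, Pacific").
Deduplication keeps, per strain, the assembly with the highest N50, ties
broken by the lexicographically greatest assembly id — an arbitrary but
deterministic rule, recorded in the rejection log.

## Trait matrices and aggregation

A genome is trait-positive for an enzyme when ≥ 1 of its proteins is
accepted for that type; gene counts are kept alongside the binary view for
heatmap-style exports.  Genomes with an unknown label at a rank contribute
no taxon at that rank and are excluded from ratio denominators there.
Genus-level ratio reporting defaults to taxa with ≥ 25 genomes, the same
cutoff the correlation networks use, below which per-taxon proportions are
too noisy to interpret.  Fold expansion divides the number of distinct
annotated taxa by the number of distinct reference-source taxa per enzyme;
an enzyme absent from the reference ranges reports `"new"` rather than a
number.

## consenTRAIT

The implementation walks the rooted tree in pre-order and accepts an
internal node as a clade root when its positive-tip fraction strictly
exceeds `fraction_threshold` (default 0.9, the "more than 90%" reading; a
≥ variant is available via `strict=False`) and it has ≥ 2 tips; the walk
never descends below an accepted node, so accepted clades are maximal.
Positive tips left uncovered become singleton genotypes.  Multifurcating
nodes are scored as-is.  Clade depth is the mean branch-length distance of
the clade's *positive* tips to the clade root; τ_D is the unweighted mean
of clade depths, singletons included; mean clade size is total positive
tips in clades divided by the number of genotypes, so an all-singleton
trait reports exactly 1.

Singleton depth has no universally agreed convention.  The default is half
the terminal branch length; `full-branch` and `half-nearest-positive`
(half the patristic distance to the nearest other positive tip) are
selectable.  Published all-singleton depth values cannot discriminate
between these without the underlying tree, which is why the convention is a
parameter rather than a constant.

No bootstrap-support requirement is imposed on clade roots.  Trees must be
rooted (a midpoint-rooting helper is provided); tips missing from a trait
matrix are treated as trait-negative, and matrix genomes missing from the
tree are dropped with a log message, mirroring marker-gene subsets that
cover only part of a genome panel.  τ_D values from trees with different
total lengths are not comparable and the package never compares them.

The 16S conversion identity% = (1 − 2 τ_D)·100 is reported to one decimal;
depths above 0.5 produce negative identities and trigger a warning rather
than an error, since the arithmetic is still well-defined.

## Correlation networks

Pearson r on binary vectors equals the phi coefficient of the 2×2 table
(verified to 1e-12 in the suite); p-values come from the exact t-transform
with n−2 degrees of freedom, two-sided, with a seeded permutation
alternative for small panels.  Raw p-values are the default because the
analysis this package reproduces reports them raw; Benjamini–Hochberg
adjustment is available (`bh_correct=True`) but off.  Constant columns
within a scope (enzyme present everywhere or nowhere in a genus) have no
defined correlation and are excluded pairwise with a debug log.  Edges
require |r| strictly greater than the threshold (0.4) and p below 0.05.
Jaccard distance ignores double absences; two all-absent vectors are
flagged undefined.  Edge identity for cross-threshold comparisons is the
(scope, pair, sign) triple, so a pair that flips sign between runs counts
as different evidence.

## Synthetic data

The generator's job is to produce inputs whose correct outputs are known by
construction.

* **References** are random flanks around a per-family conserved domain
  block (60 residues); references of one family differ by ~5% inside the
  domain and are unrelated outside, references of different families are
  unrelated everywhere (mean cross-family block identity ~6%, checked in
  the suite).  Family labels follow the real GH/PL associations of the ten
  enzyme types so outputs read naturally.
* **Planted homologs** are point-substituted copies of a reference hitting
  a target identity within ±2 points.  Substitution placement is a profile:
  `flank-first` spares the domain (separating the coverage rule from raw
  identity), `uniform` spreads mutations everywhere so local identity
  tracks the target (a genuinely distant homolog), `domain-first`
  concentrates damage in the domain.  Intact-domain plants get a synthetic
  domain-scan row at the unchanged coordinates; scrambled plants and decoys
  get none, emulating a failed HMM scan.  Decoys are full shuffles —
  composition preserved, order destroyed — so their rejection tests the
  homology signal, not amino-acid composition.
* **Trees** are Yule (pure-birth) trees built by an explicit birth process
  (each lineage splits at rate λ; after the n-th tip the process is
  observed one further holding time later), giving positive terminal
  branches and the closed-form expected root-to-tip depth
  Σ_{k=2..n} 1/(kλ) that the suite checks; a Kingman coalescent via
  dendropy is the alternative model.  The Yule construction is in-package
  so that bundles regenerate byte-identically from (config, seed).
* **Bundles** graft per-genus Yule subtrees (branch lengths scaled by 0.08
  so genera are shallow clades) onto a genus-level backbone; genera are
  therefore exactly tree-contiguous.  Traits are planted on contiguous
  blocks of each genus's tip order, which makes exclusion (disjoint blocks
  covering the genus: r = −1, Jaccard = 1) and co-occurrence (shared
  block: r > 0, small Jaccard) exact.  The default bundle has 160 genomes
  in six genera (40/40/30/26/16/8) — one exclusion genus (alginate lyase
  vs chitinase), one co-occurrence genus (agarase + carrageenase), two
  background genera, one genus below the n ≥ 25 network cutoff and one
  fully cellulase-positive clade — plus six constructed QC failures, two
  redundant assemblies and one non-marine record.  Planted identities are
  uniform on 40–95% (all above the 35% band where acceptance is
  guaranteed), with 40% of plants using the `uniform` profile so the
  identity-threshold sweep has genuine shrinkage at 50%.  Three references
  per type and three decoys per genome keep a full search + annotation run
  around 20 s on one core — the scale used throughout the suite and the
  analysis scripts.

What the generator does **not** emulate: indels and realistic substitution
processes (no alignment-length variation between homologs), paralogous
gene families, HMM score distributions (domain rows are presence/absence
with arbitrary scores), contamination inside assemblies, or NCBI metadata
quirks.  Passing tests therefore demonstrate that the pipeline's logic is
correct under its stated assumptions, not that the thresholds are optimal
for real proteomes.

## Numerical conventions

* Coordinates: 1-based inclusive in every table; overlap length is
  `max(0, min(end_a, end_b) − max(start_a, start_b) + 1)`.
* All tie-breaks (best hit, dedup, clade ordering) are lexicographic and
  deterministic; re-running any stage on the same inputs reproduces
  byte-identical outputs.
* Randomness flows from numpy `SeedSequence([seed, stream])` generators,
  one stream per logical component, so adding draws to one component never
  perturbs another.
* Floating-point table round-trips use pandas' `round_trip` parser where
  bit-exactness matters (domain e-values).
* Degenerate inputs: empty proteomes annotate to empty lists; an enzyme
  with zero positive tips yields an empty conservation report (n = 0)
  rather than an error; constant trait vectors and all-absent Jaccard
  pairs return NaN and are excluded from networks.

## Known limitations

* The internal aligner's pairwise e-values are not database-calibrated
  (see above); for genome-scale work against large reference sets an
  external search feeding the 15-column dialect is the intended route.
* consenTRAIT depths depend on the singleton convention for sparse traits;
  report the convention alongside τ_D when comparing across studies.
* Identity-threshold monotonicity of the accepted set is empirical, not a
  theorem, under best-hit re-ranking (see Annotation model).
* The correlation stage reports raw p-values by default; with many genera
  and enzyme pairs, callers interested in discovery control should enable
  the built-in Benjamini–Hochberg option.
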