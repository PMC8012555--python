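# marinepde

Tools for studying the phylogenetic distribution of polysaccharide-degrading
enzymes (PDEs) in bacterial genomes — who can break down cellulose, chitin,
agar, alginate, carrageenan and friends, how strongly that ability tracks
the phylogeny, and which abilities co-occur or exclude one another.

The package is aimed at comparative genomicists working with marine isolate
collections: it chains reference-guided enzyme annotation, genome quality
control, trait-matrix construction, consenTRAIT conservation analysis and
binary-trait correlation networks into one tested pipeline, and ships a
synthetic-data generator so every stage can be validated against planted
ground truth without touching external databases.

## The methods at its core

**Annotation.** A protein is called a PDE when (1) a local-alignment search
against a curated set of experimentally verified enzymes yields a best hit
with e-value ≤ 0.001 and local identity ≥ 30% over the matching region, and
(2) the protein shares a catalytic-domain family (GH/PL) with that
best-matched reference and ≥ 80% of the catalytic domain falls inside the
alignment region on *both* the candidate and the reference side.  The
accepted protein inherits the reference's enzyme type.  Hit tables use the
standard 15-column tabular search dialect, so an external `blastp -outfmt 6`
run can be dropped in; a built-in Smith–Waterman provider (BLOSUM62, affine
gaps 11/1) makes the pipeline self-contained.

**Quality control.** Assemblies pass when a marine keyword matches the
isolation source, N50 ≥ 50 kb, completeness ≥ 95%, contamination ≤ 5%, all
31 universal marker genes are present, and only one assembly per strain is
retained.

**Conservation.** For each enzyme, consenTRAIT walks a rooted tree from the
root and accepts maximal clades in which more than 90% of tips carry the
enzyme; uncovered positive tips are singletons.  The mean trait depth

τ_D = mean over detected clades of the average tip-to-clade-root branch length

measures how deep the conserved clades are; on a 16S rRNA tree it converts
to sequence identity as identity% = (1 − 2 τ_D) × 100, so τ_D = 0.02 means
clades of roughly 96% 16S identity.

**Correlation.** Each enzyme is a presence/absence vector over genomes;
pairs are scored with the Pearson correlation (equal to the phi coefficient
on binary data) with a two-sided t-test p-value, plus the Jaccard distance.
Networks are built per genus (≥ 25 genomes) and overall, keeping edges with
|r| > 0.4 and p < 0.05.

## Worked example

The `analysis/` scripts run the whole study on a generated bundle of 160
genomes in six genera (plus constructed QC failures), 30 curated references
across 15 CAZy families, and 159 planted homologs among 480 shuffled decoys:

```sh
python analysis/01_simulate_study.py
python analysis/02_quality_control.py
python analysis/03_annotate_pdes.py
python analysis/04_trait_distribution.py
python analysis/05_conservation.py
python analysis/06_correlation_networks.py
```

Stage 2 reports `169 assemblies: 1 non-marine, 6 failed QC, 2 redundant,
160 retained` — the generator's constructed rejects are caught and nothing
else.  Stage 3 accepts `159 PDE genes` (exactly the planted homologs, no
decoys) and prints the threshold sweep

```
min_domain_coverage  0.6  0.8  0.9
min_identity
25.0                 159  159  159
30.0                 159  159  159
35.0                 159  159  159
50.0                 150  150  149
```

— raising the identity cutoff to 50% loses the diverged homologs while the
domain-coverage cutoff barely matters, the qualitative pattern expected
when domains are the conserved cores.  Stage 5 summarises conservation,
e.g.

```
enzyme_type  n_genotypes  pct_singletons  mean_clade_size    tau_d
chitinase              3           33.33             9.67  0.106537
carrageenase           6           50.00             4.00  0.080304
```

(chitinase sits on few, large, deep clades; carrageenase is scattered), and
stage 6 finds exactly the correlation structure planted by the generator:

```
scope   enzyme_a        enzyme_b      n   r       p         jaccard  sign
all     agarase         carrageenase  160 0.8039  1.7e-37   0.2857   positive
GenusA  alginate lyase  chitinase     40  -1.0000 0.0       1.0000   negative
GenusB  agarase         carrageenase  40  0.5833  7.8e-05   0.2857   positive
```

— a mutually exclusive pair shows a strong negative correlation with
Jaccard distance 1, a co-occurring pair a positive correlation with small
Jaccard distance.  All three edges are supported when the annotation is
repeated at 25% and 50% identity.

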