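# Methods

This note documents the models, conventions, and numerical choices behind
`starterdyn`, and what the synthetic-data validation does and does not
demonstrate about real data.

Coordinates are 0-based half-open everywhere in memory and in truth
tables; VCF-flavoured exports are 1-based and BED exports 0-based, each
stated in the file header.

## Synthetic community model

`build_community` assembles a toy-scale analogue of a thermophilic
starter culture: a dominant host species ("stherm", default 50 kb, three
CRISPR arrays, four strain lineages) and a minor species ("ldelb",
default 50 kb, two arrays, one lineage) at cell fractions 0.8/0.2; a
temperate phage of the dominant host (10 kb) present free at
`copies_per_bacterium` (default 10) and integrated at known attB sites in
`integrated_cell_fraction` of host cells (default 0.05); a low-copy phage
of the minor species (0.1 copies per cell); and a plasmid at a
configurable copy number (default 3.2). Default lineage fractions are
(0.4, 0.3, 0.2, 0.1), held stable across the default 11 samples; per
sample overrides allow a lineage to dip below the 0.05 detection limit.
These defaults mirror the study system this package models — two species
at unequal abundance, 4+1 lineages, 11 samples — at roughly 1/40 genome
scale so that a full simulate–map–estimate cycle runs in seconds.

Strain lineages are derived from the base genome by planting disjoint SNV
sets in CDS (≥ 80%, by construction ~90%, non-synonymous changes in
single-copy genes, the remainder synonymous — so the downstream
annotation filter is exercised in both directions) and by inserting
private spacers at the leader of one array per lineage (acquisition adds
repeat+spacer next to the leader). A configurable number of host array
spacers are replaced by phage subsequences so that spacer/protospacer
quantification has planted matches. Gene "copy class" is an annotation
input, not inferred from depth.

Read simulation draws fragment counts multinomially across source
molecules — strain chromosomes, full recombinant lysogen molecules
(host…attL + phage + attR…host, so junction-spanning pairs arise
naturally), free phage, plasmids — with weights proportional to
depth × length. `depth` is defined as the mean per-base depth of the
dominant host chromosome; every other replicon scales by relative cell
abundance and copy number. Inserts are Normal(insert_mean, insert_sd)
(defaults 350 ± 50 at read length 100), clipped to at least one read
length; errors are uniform substitutions only (the SNV filter discards
indels anyway, so an indel error model would only exercise the aligner).
All randomness flows from one `numpy` generator; identical config + seed
gives byte-identical FASTQ (gzip written with zeroed mtime).

What the generator does **not** emulate: real base-quality profiles, GC
or positional coverage bias, indels and structural variants beyond the
planted insertions, strain-level gene content differences, and
contaminating taxa. Passing recovery tests therefore demonstrates the
estimators are correct under their stated models, not that they are
robust to every artefact of real sequencing.

## Read mapping

The built-in aligner is a k-mer-seed (k = 21, three seed offsets, sparse
fallback scan) plus full-length ungapped extension, with candidate
windows scored by mismatch count and accepted at ≥ 90% identity.
Multi-mapping ties break deterministically: lowest edit distance, then
forward strand, then lexicographically smallest reference id, then
leftmost position. This is sufficient for substitution-only synthetic
data; downstream code sees only the alignment-record contract (read, ref,
position, strand, edit distance, mate linkage), so a production aligner
could be substituted behind the same surface. Reads straddling an
insertion junction (private spacers, prophage attB) do not ungapped-align
and are dropped — a known, intended limitation that the junction
estimators exploit rather than suffer.

## SNV calling and strain deconvolution

The caller reproduces pooled-continuous gating: a site is emitted when at
least one sample has depth ≥ 10, alternative count ≥ 5, and alternative
allele frequency ≥ 0.05 (all boundaries inclusive); per-sample AAF is
then reported at every emitted site. The per-sample interpretation of the
0.05 gate was chosen because the pooled alternative is not testable
without the original caller. The base-quality gate (Q30) is a no-op on
simulated reads, which carry uniform high qualities. Annotation is
strand-aware codon substitution under the standard genetic code; the
analysis filter keeps non-synonymous SNVs in single-copy genes.

Phase clustering uses average-linkage hierarchical clustering of AAF
trajectories (values below the 0.05 detection limit zeroed first). The
distance between two trajectories is the per-sample RMS difference,
i.e. Euclidean distance divided by √n_samples, cut at 0.10; clusters with
fewer than 5 SNVs are reported as unexplained leftovers rather than
phases. The per-sample normalization makes the threshold independent of
how many samples were sequenced; 0.10 sits between the within-lineage
spread of binomial AAF noise at depth ~100 (RMS ≈ 0.07) and the distance
between lineages separated by 0.1 in abundance (RMS ≈ 0.12), which is the
regime the default community occupies. The number of phases is data
driven, never preset, and phases may be all-zero in some samples and
persist (the transiently-vanishing-phase scenario).

Lineage abundance is the mean AAF of lineage-diagnostic SNVs (present in
every isolate of the lineage, absent from all others), reported with the
number of SNVs used; samples in which no diagnostic SNV reaches the depth
gate yield NaN ("not determined") rather than 0. pN/pS follows
(N_obs/N_sites)/(S_obs/S_sites) with sites counted by enumerating all
three substitutions at each codon position, unweighted (no
transition/transversion weighting), so N_sites + S_sites equals the gene
length and the counts are checkable by exhaustive enumeration; genes
without synonymous observations are undefined (NaN), never infinite.

## CRISPR arrays and spacers

Array detection seeds on exact 20-mers recurring with CRISPR-like
spacing (period 40–120), extends a column-majority consensus while column
conservation stays high, rescans the neighbourhood for all copies at
≤ 10% mismatch, then refines the repeat boundaries using every recovered
copy (conservation threshold 0.7). Arrays need ≥ 3 repeat copies with
regular 15–70 nt alternation. Leader side cannot be inferred from
sequence alone; detected arrays order spacers by genome coordinate, and
leader distances are known only where the truth (or an annotated array)
provides them.

Metagenomic spacer fishing scans both read orientations for full or
edge-partial repeat matches (≤ 10% mismatches, ≥ 10 bp flank) and emits
the sequence between two anchors when it is 20–60 nt, assigned to the
matching array and oriented to its repeat consensus; reads matched by
repeats of two different arrays are skipped and counted as ambiguous.
Dereplication is greedy longest-first clustering (ties lexicographic) at
≥ 90% ungapped identity over the shorter sequence, both orientations —
the cd-hit convention, deterministic by construction. Denoising by a
dedicated amplicon error model is intentionally replaced by this
clustering: on exact-extracted spacers from synthetic reads the two
routes coincide at the dereplicated-cluster level. Rarefaction to the
smallest per-sample count is available (seeded) but off by default.

Shared-spacer fractions default to the Jaccard form (shared clusters /
union clusters), chosen for symmetry and boundedness; a per-genome
variant (|shared|/|A|) is exposed behind a flag. ANI is fragment mapping:
1 kb tiles aligned by edit distance (edlib, both strands), fragments
≥ 80% identity averaged, and the two directions averaged. Turnover is the
mean of per-sample rates (new clusters / generations, each new cluster
counted once in the sample where first seen), with the sample SD.
Spacer ages, age = leader_distance / rate, are minimum estimates: loss of
distal spacers is not modelled, and the rate is an explicit parameter
because an independently measured rate (e.g. from a propagation
experiment) is the appropriate clock.

## Phage state

Copies per bacterium is the phage/host mean-depth ratio. Spanning pairs
(one mate primary on phage, one on host, both within 2 mismatches — the
edit cap excludes reads that overhang the junction itself) are clustered
along the host coordinate with a single-linkage window of
insert_mean + 2·insert_sd; the attB estimate corrects each pair by half
the expected host-side gap. Integration fractions convert the spanning
count n into a junction depth via

    junction_depth = n · 2R / W,   W = 2 · E[(F − 2R)+],

where F ~ Normal(insert_mean, insert_sd) and R is the read length: a
fully-host/fully-phage pair requires a fragment longer than 2R, and with
two junctions per integrated prophage this W makes the estimator
unbiased for the lysogen-molecule depth (verified on simulation).
integrated_cell_fraction = junction_depth / host depth;
integrated_phage_fraction = junction_depth / phage depth; both clipped to
[0, 1] with a warning, since low-depth sampling noise can push the raw
ratio above 1. Junction depth uses both mates of each spanning pair; the
window is recorded in output metadata. Lineage attribution of spanning
pairs requires the host-side mate to cover a lineage-diagnostic SNV with
the alternative base; all other pairs are "unassigned".

Spacer/protospacer quantification classifies each read once against the
repeat–spacer–repeat construct of its best-matching cluster (fewest
spacer mismatches, deterministic tie-break): full spacer plus ≥ 10
matched repeat bases on both sides is a spacer read (host array support);
full spacer with less repeat on either side is a protospacer read (free
phage support). Reads near an array edge that cover the spacer but
truncate a flank are counted as protospacer reads by this rule; the
resulting count-ratio bias is (R−s+1)/(R−s−2f+1) and shrinks with read
length — at 250 bp reads it is ~10%. The spacer–protospacer relation is
ordinary least squares and Pearson r on log10(count + 1).

## Propagation statistics

Generations between CFU counts: log2(CFU(t2)/CFU(t1)), negative when the
population shrank. Freeze-drying survival is reported as
100 · CFU_after / CFU_before; note that the printed source formula for
this quantity has before/after inverted, which would exceed 100% for any
cell loss and contradicts the reported ~71.5% value, so the
after/before orientation consistent with that value is used.

## Problem sizes used in validation

The test-suite and acceptance runs use 12–30 kb host genomes, depth
40–150, and 1–11 samples — chosen so the full pipeline (including 30
independent lysogeny simulations and an 11-sample strain-deconvolution
series) completes in a couple of minutes on one CPU while leaving every
estimator in the statistical regime its tolerances assume (≥ 50
diagnostic SNVs per lineage at depth 100; Poisson spanning-pair counts of
~3–17 per sample averaged over 10 seeds).

## Known limitations

- The aligner is ungapped; indels and rearrangements beyond the planted
  insertion junctions are out of scope.
- Array leader orientation is not inferred from sequence; ages require
  externally known leader distances.
- Phase/lineage reconciliation is not forced: phases (read-linkage view)
  and isolate-defined lineages (genome view) are reported independently,
  since their correspondence is an empirical question, not an identity.
- The detection-limit and linkage thresholds are tuned to the AAF noise
  scale of depth ≳ 50 data; much shallower series would need a larger
  linkage threshold or deeper sequencing.
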