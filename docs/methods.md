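# Methods

`rrnphase` analyses full-length 16S rRNA gene amplicon data at the level
of *intragenomic gene-copy variation*. A bacterial genome typically
carries several copies of the 16S gene (rrn operons) that differ at a
handful of positions. In deep amplicon data from a pure isolate these
copy variants appear as positions where a reproducible fraction of
reads — k/C for k variant-carrying copies out of C — disagrees with the
reference. The package turns that stoichiometric signal into called
SNPs, uses it to compare strains, and, separately, benchmarks how much
taxonomic resolution is lost when only a sub-region of the gene is
sequenced.

## Pairwise glocal alignment

Reads are aligned to reference genes with an affine-gap (Gotoh)
dynamic program under a *glocal* contract: the read must align in
full, while reference overhangs at either end are free. This matches
the geometry of a full-length amplicon against a gene that may extend
beyond the amplified span.

Scoring defaults follow established practice for this data type:
match +1, substitution −9, and a minimum reported alignment score of
750 for mixed-community data or 1200 for isolate data (reads that
score lower are discarded and counted). Gap penalties are not pinned
down by that convention and default to open −12 / extend −2
(gap of length L costs `open + (L−1)·extend`); all five numbers are
exposed in `ScoringScheme`. Determinism is pinned explicitly: at equal
score the aligner prefers diagonal > deletion > insertion, ends at the
leftmost reference column, and best-hit ties between references break
by input order. A diagonal band (half-width 40 by default in the
pipeline) is used for near-full-length reads; the band is an
optimisation only — tests verify banded and full dynamic programs
return identical scores and operation lists on simulated reads, and
the full program is checked op-for-op against an independent
pure-Python oracle and score-checked against scikit-bio's `pair_align`.

Two auxiliary schemes serve other tasks. `IDENTITY_SCORING` backs the
OTU identity computation, where identity is defined as matches /
alignment columns with terminal gaps excluded (identity definitions
differ between tools, so the definition is pinned in code).
`PROFILE_SCORING` (match +1, mismatch −1, open −4, extend −2) backs
the projection of near-identical sequences onto reference coordinates
(predicted profiles, entropy columns, coordinate maps); its mild
mismatch penalty guarantees that runs of substitutions are represented
as substitutions rather than being fragmented into gap pairs when a
substituted base coincidentally equals a neighbouring reference base.

## Tallies and substitution profiles

Per reference position the pipeline counts spanning reads (depth),
bases, deletions, and left-anchored insertions; base counts plus
deletions equal depth everywhere. The substitution profile keeps only
substitution signal: `variant_fraction = (depth − reference-base count
− deletions) / depth`. Indel fractions are retained for diagnostics —
deletion errors in this chemistry concentrate in homopolymer runs, and
`deletion_rate_by_runlength` groups per-position deletion fractions by
the length of the maximal single-base run containing each position.

## IQR SNP calling and sample QC

Copy-variant SNPs are separated from background error by a robust
outlier rule applied to the distribution of variant fractions over all
covered positions: a position is called when its fraction exceeds
Q3 + 9·IQR (quartiles by linear interpolation, the type-7 convention;
the multiplier and method are configurable). Two QC gates bracket the
rule: samples with fewer than 200 aligned reads are rejected
(`fail_low_depth`; below that depth the signal-to-noise of a 1/C
fraction is inadequate), and samples with SNPs at more than 3% of
covered positions are rejected as impure (`fail_impure`), since a pure
isolate cannot be polymorphic at that many sites. "Positions" for the
3% rule means covered (aligned) positions, stated in the QC report
metadata. When the IQR is exactly zero (e.g. error-free reads) the
cutoff falls back to Q3 plus one read's worth of frequency
(1/n_reads), so a perfect profile yields zero calls rather than
flagging every position. QC failure withholds the call set; the
candidate count is retained for reporting.

## Predicted profiles and strain comparison

`predicted_profile` aligns every copy of a genome's gene-copy set to
the designated reference copy and reports, per reference position, the
fraction of copies carrying a substituted base — the ground-truth
analogue of an observed profile (7 copies with a variant in 3 predict
42.9%; the smallest nonzero signal for C=7 is 1/7 ≈ 14.3%). Copy-level
deletions are excluded, mirroring substitution-only profiling.

Measurement error is estimated from technical replicates: for each
locus called in any replicate, the sample SD (ddof = 1; for two
replicates `|x1−x2|/√2`) of its variant fractions across replicates,
averaged over loci, gives the per-sample error ζ_w in percent. The
formula is the standard within-subject repeatability statistic. Cohort
mean + 3 SD of ζ_w defines the difference threshold: two isolates in
the same 99% OTU are *different* when any locus (union of both SNP
sets, absent loci read as 0) differs by more than the threshold. The
relation is symmetric but not transitive, so unique-profile counting
uses a greedy scan in sorted-isolate-id order: an isolate joins the
first representative it does not differ from, else founds a new
profile. Cross-isolate coordinates are reconciled by aligning each
isolate's internal reference to the OTU centroid and mapping SNP
positions through the alignment.

## Region-resolution benchmarking

In-silico amplicons are cut by locating primer sites with a
fixed-length Hamming scan under IUPAC expansion, allowing up to 3
mismatches per primer; the subsequence strictly between the sites,
primers removed, is the amplicon. Indels inside primer sites are not
modelled — fixed-length sites keep the downstream length filter exact
— which is a deliberate deviation from trimming tools that allow
them. Site ties resolve to the leftmost forward and rightmost reverse
site (maximal amplicon); both template orientations are tried.

Curation applies three filters: sources that fail extraction for any
region are removed everywhere; records containing N are removed; and
records whose length deviates from the per-region mean by more than
2 sample SDs are removed (statistics computed after the first two
filters).

Classification is a word-based naive-Bayes classifier over overlapping
8-mers with the corpus-wide word prior (n + 0.5)/(N + 1) and per-label
conditional (m + prior)/(M + 1). A query gets the label with the
highest joint log-probability over all its words (ties to the
lexicographically first label); confidence is the percentage of 100
bootstrap trials — each resampling ⌊w/8⌋ of the query's w words with
replacement — that agree. Exact score ties within a trial are broken
uniformly at random (seeded), so a query supported equally by several
labels — identical training sequences under different labels — comes
out with ~1/t confidence for t tied labels and is left unclassified at
any practical cutoff, rather than confidently assigned to an arbitrary
one; only the reported label's tie-break is lexicographic, for
determinism. Each representative sequence acts as its own
species label (the species proxy used for filtered reference
databases), and a region's resolution score is the fraction of curated
amplicons that fail self-classification. "Failure" has two readings —
misclassified-or-below-cutoff versus below-cutoff only — and both are
reported.

OTUs are built greedily: sequences scanned in decreasing abundance
join the first centroid at or above the identity threshold, else found
a new centroid; no chimera filtering.

## The synthetic-data generator

The generator emulates the data the pipeline is designed for, without
any downloads:

* **Gene-copy sets** — C copies of a base gene (default study condition
  C = 7, gene length 1500 bp, GC 0.54) with each planted locus
  substituted in exactly the stated number of non-reference copies,
  plus optional single-base copy-level deletions. The truth table
  records every placement, and `predicted_profile` on a generated set
  reproduces it exactly.
* **CCS-like reads** — full-length copies of the gene (no
  fragmentation, matching amplicon geometry), with independent
  substitutions (default 0.5% per base, the error level of multi-pass
  circular consensus), insertions (0.1%), and deletions whose
  probability is `deletion_rate_base · homopolymer_factor^(run−1)`
  capped at 0.5 (defaults 0.2% and 2.0), reproducing the concentration
  of deletion errors in homopolymer runs and its growth with run
  length. Per-copy dosage within a genome is uniform (1/C); unequal
  operon expression is out of scope. Every read carries provenance
  (source genome, copy, explicit event list) and replaying the events
  reconstructs the read byte-for-byte. Quality strings are constant
  placeholders; the pipeline is quality-agnostic.
* **Communities** — reads pooled over genomes at chosen abundances,
  supporting two-strain mixtures of one species, where observed locus
  fractions converge on the abundance-weighted combination
  w1·f1 + w2·f2.
* **Pooling arithmetic** — genome DNA mass m = n · 1.096×10⁻²¹ g/bp
  and per-member masses that equalise delivered 16S copies
  (mass_i = target_copies / copy_number_i · m_i).
* **Benchmark databases** — n species derived from one base gene with
  private substitutions confined to chosen windows and shared
  primer-binding motifs planted at fixed offsets, so that the
  resolution of a region can be manipulated by construction.

What the generator does **not** emulate: chimeras, PCR bias,
context-dependent substitution spectra, quality-value information,
unequal operon dosage, and fragmentary reads. Passing tests therefore
demonstrate correctness of the method's logic under its stated error
model, not performance on any particular instrument's artefacts.

## Experiment scales and numerical choices

The packaged experiments (`rrnphase.experiments`) run at the study
conditions: seven copies, loci at every stoichiometry 1/7…6/7, 500
reads per sample, 100 independent runs for the recovery experiment;
1000 reads for the 70/30 two-strain mixture; 400 reads for the
homopolymer trend and replicate-error experiments (6 isolates × 2
replicates); 40 species for the region benchmark; 10 strain pairs for
discrimination. These sizes make every experiment reproducible in
minutes on one core while keeping binomial noise well inside the
asserted tolerances.

The recovery and mixture experiments use a substitution-only error
model (0.5%), which is how their conditions are defined; the
homopolymer, replicate-error, and strain experiments use the full
indel-aware model. A known interaction motivates this split: when a
planted variant base extends a homopolymer run, deletion errors in
that run cause the aligner to represent the read's difference as a
deletion at the variant position rather than a substitution, and since
deletions are excluded from the variant fraction the locus is
under-called (by up to ~60% at run length 7 with factor 2). This is a
genuine property of substitution-only profiling on indel-prone
chemistry, visible in the diagnostics (`deletion_fraction` spikes at
the locus), and a limitation users should know about.

Two statistical calibrations are worth stating. First, a fraction
estimated from 500 reads carries binomial SD up to
√(0.5·0.5/500) ≈ 0.022, so single-run locus estimates scatter beyond
±0.03 routinely; the ±0.03 guarantee applies to the estimator's bias
(mean over the 100 runs, SE ≈ 0.002). Second, with a 6.58-point
difference threshold the run-to-run difference of a 3/7 locus at 500
reads sits only ~2.1 SD below threshold, so identical strains are
occasionally split at that depth; the identical-strain stability check
is therefore run at 2000 reads, where the threshold is >4 SD away and
splits are vanishingly rare. Separation of genuinely different strains
(≥2/7 apart, i.e. ≥28.6 points) is insensitive to this.

## Known limitations

* Primer sites are matched without indels; a primer site containing an
  indel in a real template would be missed where trimming tools that
  allow indels would find it.
* Entropy and predicted profiles come from pairwise projection onto a
  single reference rather than one multiple alignment; columns that
  are heavily gapped in a true MSA can differ.
* Exact gap penalties of the alignment convention the scoring mimics
  are not published; per-position fractions on real data may shift
  slightly under different gap choices.
* The greedy OTU and unique-profile counts depend on scan order; both
  orders are fixed (abundance, then id) for reproducibility rather
  than optimised.
* The 3%-impurity rule uses covered length; on partially covered
  references it is more permissive than a reference-length reading.
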