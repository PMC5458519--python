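# Methods

## Scope and data model

The package analyses splice-junction count data from a two-genotype
(wild-type vs splicing-modulator-resistant mutant), two-treatment
(vehicle control vs compound) design with biological replicates
(hexaplicate by default). Inputs are per-sample junction tables in the
9-column aligner dialect (chrom, intron start, intron end, strand code,
motif, annotated, unique reads, multimapped reads, max overhang), a
4-column TSV of reads crossing the exon–intron boundary at 3′ splice
sites, a BED12 or minimal-GTF transcript annotation, a genome FASTA, and
per-clone variant tables. All coordinates are held 1-based inclusive
internally — the junction-table convention, in which the two coordinates
are the first and last intronic base — and BED's 0-based half-open
coordinates are converted only at the I/O boundary. Only unique-read
counts are used; multimapper counts are parsed and discarded, the
conservative choice when the counting protocol does not state otherwise.

Junctions with unknown strand (code 0) are retained in per-junction PSI
output but excluded from every strand-dependent analysis (splice-site
grouping, trifurcation, GC profiles), because the identity of a 3′ splice
site depends on the strand.

## PSI and the 3′-splice-site trifurcation

Junction PSI is the junction's unique-read count divided by the summed
counts of all junctions sharing a splice site, computed separately for the
donor-sharing and acceptor-sharing groups; a group with zero total reads
yields an undefined (NaN) PSI, never a silent 0/0. Downstream IR/ES
analyses use the acceptor-side value, since the trifurcation is anchored
at the 3′ splice site.

At each 3′ splice site the informative reads are partitioned into ES
(junctions classified as single-cassette-exon skips against the
annotation), inclusion (junctions matching an annotated intron) and IR
(boundary-crossing reads); the three fractions of the class total sum to
one whenever the total is positive. Replicate averaging is the arithmetic
mean of per-sample PSIs over samples where PSI is defined (not pooled
counts), with the number of contributing samples reported. No minimum
read-count filter is applied by default; a threshold exists in the run
configuration and defaults to zero.

A boundary-count record that is absent for a site in one sample is treated
as zero boundary-crossing reads. One subtlety of the event matrix: an
upstream intron that competes with a skip junction shares only its *donor*
with it, so its exon-inclusion evidence cannot appear on the acceptor
side. Canonical junctions therefore contribute a second, donor-side event
series (category `inclusion_5p`), used for the ES-triplet inclusion filter
and excluded from category summaries to avoid double counting.

## Moderated t and significance

Writing s²_g for the pooled two-group residual variance of event g on d
residual degrees of freedom, the hierarchical model is

    s²_g | σ²_g ~ σ²_g · χ²_d / d,    1/σ²_g ~ χ²_d0 / (d0 · s0²),

so marginally s²_g / s0² ~ F(d, d0). The hyper-parameters are fit by
moment matching on log s² using the digamma/trigamma moments of the
log-chi-square; the trigamma inverse is solved by Newton iteration. When
the observed spread of log variances does not exceed what sampling noise
alone predicts, the fit returns d0 = ∞ with s0² equal to the mean sample
variance — the common-variance limit, in which the statistic's null is
taken as normal. Events with fewer than two defined values in either
group are reported untestable rather than imputed. The implementation is
validated against an independent reference implementation of the same
empirical-Bayes fit on frozen fixtures (hyper-parameters, posterior
variances, t and p values to ~1e-8), and the degenerate d0 = 0 prior
reproduces the textbook pooled-variance two-sample t exactly.

Benjamini–Hochberg correction is applied per contrast over all events
with a defined p-value; q ≤ 0.05 is the significance rule everywhere.
Ties in p are handled stably (the adjusted value is a function of the
p-value alone, so input order is irrelevant).

Event categories are a total classification: `canonical` (annotated
intron, reported as `inclusion`), `ES` (merges the outer boundaries of two
consecutive annotated introns), `alt5`/`alt3` (exactly one annotated
splice site; the novel side names the category), `IR` (boundary event at
an annotated acceptor) and `other`. Category summaries report counts,
fractions and log2 fold changes of PSI with a pseudocount,
log2((PSI_treat + ε)/(PSI_ctrl + ε)), ε = 0.01 by default and
configurable — a documented convention, since a fold change on fractions
requires one; quartiles and 1.5×IQR whisker bounds are reported per
category.

## GC metagene profiles

Foreground sets: for IR, each significant retained-intron site contributes
one (intron, downstream exon) pair when the intron is ≥ 100 nt and an exon
of length ≥ 50 nt borders its 3′ end; when several exons qualify, one is
chosen uniformly at random under the run seed. The "length 50" exon rule
is read as *at least* 50, harmonising the IR-side filter with the ES-side
filter which is explicitly "at least". For ES, a junction qualifies when
it skips exactly one annotated exon ≥ 50 nt, both flanking introns are
≥ 100 nt, and both carry exon-inclusion evidence in the untreated samples
at q < 0.05 (taken from the same contrast's inclusion events, either
side); multi-exon skips are excluded as ambiguous.

Each intron is divided into 100 bins and each exon into 50 bins of
near-equal length using floor boundaries (bin k spans [⌊kL/n⌋, ⌊(k+1)L/n⌋),
sizes differing by at most one base) — a deterministic, order-preserving
remainder rule. Bins are ordered 5′→3′ in transcript orientation; the
downstream-intron half of an ES triplet reads exon-then-intron. GC is the
fraction of G/C among non-N bases; N bases are excluded from numerator and
denominator, and an all-N bin is NaN and drops out of that bin's mean
(avoiding a bias of GC toward zero). Per-bin means are accompanied by a
95% percentile-bootstrap CI (not a normal approximation) over 100
resamples of whole pairs — resampling pairs, not bins, preserves
within-pair correlation. The background is drawn once per run from all
annotated pairs passing exactly the same filters as the foreground
selector — 10,000 pairs, without replacement when the universe allows,
otherwise with replacement and a logged warning — and the single
background is reused across panels for comparability.

GC is strand-symmetric, but bin order is not: a reverse-complemented
genome with flipped annotation must give identical profiles, which is
verified with a planted 5′→3′ GC gradient.

## Switch analysis

For each significant ES site of condition A (mutant + compound), the
replicate-averaged trifurcation PSIs of conditions A and B (wild-type +
compound) are tabulated; a site switches iff ES PSI is strictly lower and
IR PSI strictly higher in B. Strict inequalities are the conservative
reading — exact ties do not count. Sites with undefined trifurcation PSI
in either condition are excluded from numerator and denominator alike
(they carry no evidence), with the exclusion count logged. The waterfall
view sorts sites by descending ES PSI in condition A with ties broken by
site key, and both conditions are plotted in that single order; the switch
fraction is invariant to the ordering.

## Resistant-clone variant triage

Variants pass the filter iff the gene is in the curated list, the allele
frequency is strictly greater than 0.2, and the effect class is one of
{missense, nonsense, frameshift, inframe_indel, splice_site} ("non-silent";
synonymous and unclassifiable effects are dropped). Genes are then counted
by *distinct* affected clones — a clone with several variants in one gene
counts once — and reported at a recurrence threshold of ≥ 3 clones, with a
per-treatment-arm breakdown. A clone harbouring two sub-populations is
represented as one clone carrying both variant records. The filter is
idempotent, and raising either threshold can only shrink the output.

## Synthetic data generator

Each locus is a three-exon gene (exon–intron–cassette exon–intron–exon);
the cassette exon's downstream 3′ splice site is shared by the inclusion
junction, the skip junction and the exon–intron boundary, so the read mass
at that site trifurcates exactly as the pipeline expects. Loci alternate
strands and are laid head-to-tail on one chromosome with 100-nt spacers.
Defaults mirror the emulated study design: 2,000 loci and a 2 × 2 × 6
hexaplicate layout (24 samples) — large enough for stable statistics while
keeping a full run in the tens of seconds on one CPU.

Planted labels and their default fractions: `no_effect` 0.55,
`ir_responsive` 0.20 (compound shifts ΔIR = 0.4 of inclusion mass into IR
in wild-type; attenuated to 25% of that in the mutant), `es_responsive`
0.09 (ΔES = 0.4 into ES in the mutant, half that in wild-type, with a
small compensating IR dip so these loci sit clearly on the non-switch side
of the strict switch boundary), and `switch` 0.16 (IR shift in wild-type,
ES shift in the mutant). The switch/(switch + ES) ratio of 0.64 plants the
headline switch fraction among mutant-responsive ES loci. Effect
magnitudes are multiplied by clip(GC_intron / 0.55, 0, 1), encoding the
premise that high-GC introns are the weaker substrates and respond more
strongly; per-label GC targets (retained introns 0.55 for IR/switch loci,
0.35 for ES loci, 0.40 for neutral loci, exons 0.60) give the metagene
profiles a known planted shape. Sequences are sampled base-by-base at each
feature's GC target. Five percent of loci get deliberately short introns
so the metagene length filters are exercised.

Counts: per locus and sample, the informative total is negative binomial
(mean 200, dispersion 0.05) and splits among (ES, inclusion, IR) by a
Dirichlet-multinomial around the condition's trifurcation probabilities
(concentration 150). The Dirichlet layer makes replicate variances
heterogeneous across loci — the regime the moderated test exists for — and
a pure multinomial would understate it. Baseline trifurcations are
inclusion-dominant (ES and IR each uniform on [0.02, 0.08]).

Clone variants: twelve clones in two compound arms with planted recurrent
drivers (five + two SF3B1 HEAT-repeat mutations, one + four PHF5A Y36C,
plus one mixed clone carrying both populations), over a Poisson background
(rate 3/clone) of passengers with AF ~ U(0.05, 1), drawn from listed genes
as synonymous and from unlisted genes as missense — each a path the filter
must reject.

A single master seed derives named per-stage child seeds
(genome/counts/variants/analysis) through `numpy` seed sequences, so
stages are independently reproducible; datasets are byte-identical across
runs under the same seed.

### What the generator does not emulate

Counts are simulated directly — there is no read-level error, mapping
ambiguity, overhang filtering, positional coverage bias or GC-dependent
amplification bias; junction discovery is perfect and each locus has
exactly one transcript, so alt-5′/alt-3′ events arise only as annotation
mismatches, not from genuine alternative site usage. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under a known generative model, not robustness to alignment
artefacts or annotation incompleteness in real RNA-seq.

## Pipeline, determinism, degenerate inputs

Stages run in order PSI → differential → GC profiles → switch, with the
variant path independent; each stage reads files and writes TSVs, so a run
resumed at any stage reproduces the full run bit-for-bit (per-stage
generators use fixed spawn keys off the run seed). The manifest carries
the config hash, seed and output list; contrasts are declared explicitly
in the config rather than inferred, and per-stage logs count records in
and out of every filter, since event counts are filter-sensitive.

Degenerate inputs are defined rather than accidental: zero-total sites are
undefined and excluded downstream with logged counts; q_max = 0 produces
empty-but-valid outputs at every stage; an empty gene list, an empty
background universe, and all-zero variances raise errors naming the cause.

## Known limitations

- Boundary-crossing read counts are taken as given; the minimum overhang
  for a read to "cross" the boundary is a property of the upstream
  counting step, not of this package.
- The per-junction PSI denominator groups junctions per site (donor and
  acceptor separately); pooling both sides into one denominator is a
  defensible alternative reading that is not implemented.
- The log2 fold change of the category summaries is defined on PSI with a
  pseudocount; defining it on junction counts would give different values.
- The infinite-prior case takes the normal limit for p-values rather than
  capping the total degrees of freedom at the summed residual df, so
  p-values in that regime are marginally more liberal than the capped
  convention (identical to ~3 significant figures at typical event counts).
- The curated spliceosome gene list shipped with the simulator is a
  placeholder; any user list is accepted.
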