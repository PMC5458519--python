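# splicemod

Differential splicing analysis for splicing-modulator experiments in
`WT` vs resistant-mutant cell lines: junction-level PSI quantification, the
ES/inclusion/IR trifurcation at shared 3′ splice sites, empirical-Bayes
moderated-t differential PSI, GC-content metagene profiles with bootstrap
confidence intervals, ES↔IR switch analysis across genotypes, and
resistant-clone variant triage — together with a synthetic-data generator
that plants known effects so every stage is testable end to end.

## Who this is for

Small molecules of the pladienolide / herboxidiene / spliceostatin families
bind the SF3b subcomplex of U2 snRNP near the branch-point adenosine and
perturb 3′-splice-site recognition, inducing intron retention (IR) and
exon skipping (ES) genome-wide. Resistance mutations in SF3B1 and PHF5A
(e.g. PHF5A Y36C) blunt and *qualitatively reshape* this response: loci
that retain an intron in wild-type cells under compound can instead skip
the neighbouring cassette exon in the mutant, and the direction of the
change tracks the GC content of the retained intron relative to its
downstream exon. This package implements the quantitative analyses needed
to characterise that phenotype from splice-junction count data.

## The statistics at its core

**PSI.** For a junction *j* with unique-read count *n<sub>j</sub>*, PSI at a
shared splice site *S* is *n<sub>j</sub>* / Σ<sub>k∈S</sub> *n<sub>k</sub>*,
computed separately for the donor- and acceptor-sharing groups. At a shared
3′ splice site the informative reads trifurcate into ES (skip junction),
exon inclusion (annotated-intron junction) and IR (reads crossing the
exon–intron boundary); their fractions of the class total are the
per-class PSIs and sum to one.

**Moderated t.** Per-event pooled variances *s²<sub>g</sub>* on *d*
residual df are shrunk toward a prior by empirical Bayes under the scaled-F
model *s²<sub>g</sub>/s₀² ~ F(d, d₀)*; (d₀, s₀²) are fit by moment matching
on log *s²* via digamma/trigamma identities, the posterior variance is
*s̃²<sub>g</sub> = (d₀s₀² + d·s²<sub>g</sub>)/(d₀ + d)* and the moderated
statistic *t̃ = ΔPSI / √(s̃²(1/n₁+1/n₂))* has *d + d₀* degrees of freedom.
P-values are Benjamini–Hochberg corrected; q ≤ 0.05 is called significant.

**GC metagene.** Each retained intron is rescaled to 100 bins and its
downstream exon to 50 bins (cassette exons of ES triplets carry both
flanking introns); per-bin GC fractions are averaged over events with a
95% percentile CI from 100 bootstrap resamples of whole intron/exon pairs,
against a background of 10,000 random annotated pairs passing the same
length filters (intron ≥ 100 nt, exon ≥ 50 nt).

**Switch.** For every significant ES site in the mutant-plus-compound
condition, the site "switches" when the wild-type-plus-compound condition
shows strictly lower ES PSI and strictly higher IR PSI.

**Clone triage.** Whole-exome variants from resistant clones are filtered
to non-silent mutations in a curated spliceosome gene list with allele
frequency > 0.2, and genes hit in ≥ 3 distinct clones are reported.

## Worked example

```sh
splicemod simulate demo --n-loci 300 --seed 7
splicemod run-all demo demo_out --seed 7
```

The simulator emits a self-contained dataset (genome FASTA, BED12
annotation, per-sample junction tables, boundary counts, clone variants,
and the planted truth); `run-all` executes PSI → differential → GC
profiles → switch → variant triage and logs, per stage:

```
INFO splicemod: stage diff Y36C_compound_vs_control: 2100 events, 288 significant (d0=5.87, s0^2=0.000594)
INFO splicemod: stage gc: wrote 7 profiles
INFO splicemod: stage switch: 53/76 sites switch (69.7%)
INFO splicemod: stage variants: 13/41 variants kept, 2 recurrent genes
```

`demo_out/switch_summary.tsv` then reads

```
n_switch	n_total	fraction
53	76	0.697368
```

meaning 53 of the 76 sites with a significant compound-induced ES response
in the mutant line show the ES→IR switch in wild-type cells (the generator
plants switches at ~64% of responsive ES loci; at 76 sites the binomial
sampling error is ±5–6 points). `demo_out/recurrence_summary.txt` reports
the recurrently mutated genes of the simulated two-arm clone screen:

```
SF3B1: 8 clones (E7107: 5, herboxidiene: 3)
PHF5A: 5 clones (E7107: 1, herboxidiene: 4)
```

and `gcprofile_*.tsv` hold the binned GC profiles (segment, bin, mean,
CI bounds, number of pairs) for the IR/ES foregrounds and the shared
background. All outputs are plain TSV with a JSON run manifest carrying
the config hash and seed; reruns under the same config and seed are
byte-identical, including partial reruns resumed at any stage.

Every CLI command is a thin wrapper over library functions
(`splicemod.psi`, `splicemod.differential`, `splicemod.gc_metagene`,
`splicemod.switch`, `splicemod.resistance`, `splicemod.simulate`,
`splicemod.pipeline`), which can be used directly on any data in the
documented formats.

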