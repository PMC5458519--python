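"""Synthetic genomes, annotations, splice-junction counts and clone variants
with exported ground truth.

The generator emulates a splicing-modulator RNA-seq experiment: a 2 genotype
(WT / resistant-mutant) × 2 treatment (control / compound) design in
hexaplicate.  Each simulated locus is a three-exon gene whose middle
(cassette) exon shares its downstream 3' splice site between an exon-
inclusion junction, an exon-skipping junction and the exon–intron boundary
(intron retention), so the read mass at that site trifurcates into the
ES/inclusion/IR classes the pipeline quantifies.

Loci carry planted labels: *no_effect* (no treatment response), *ir_responsive*
(compound shifts read mass into intron retention in WT cells, attenuated in
the mutant), *es_responsive* (compound shifts mass into exon skipping,
strongest in the mutant) and *switch* (IR in WT + compound, ES in mutant +
compound — the ES↔IR switch the analysis is designed to detect).  Effect
magnitudes are coupled to the GC content of the retained intron: high-GC
introns are the weaker substrates and respond more strongly.  Feature
sequences are sampled base-by-base at per-feature GC targets, so GC
metagene profiles have a known planted shape.

Counts are negative-binomial totals split among the three classes by a
Dirichlet-multinomial around the condition's trifurcation probabilities;
the Dirichlet layer gives biological replicates the variance heterogeneity
an empirical-Bayes moderated test is meant to handle.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .formats_io import (
    AnnotationModel,
    JunctionRecord,
    Transcript,
    VariantRecord,
    format_site_key,
    write_boundary_counts,
    write_bed12,
    write_junction_table,
    write_variants_tsv,
)
from .psi import acceptor_site

log = logging.getLogger("splicemod")

LABELS = ("no_effect", "ir_responsive", "es_responsive", "switch")
GENOTYPES = ("WT", "Y36C")
TREATMENTS = ("control", "compound")


@dataclass
class SimConfig:
    """Study-design and noise parameters of the simulated experiment.

    Defaults are the simulated counterpart of the emulated study: a
    2 × 2 × 6 hexaplicate design, ~2,000 cassette-exon loci, and a
    switch-vs-ES label split that plants a ~64% ES→IR switch fraction among
    mutant-compound-responsive ES loci.
    """

    n_loci: int = 2000
    n_replicates: int = 6
    #: fraction of loci per planted label (must sum to 1)
    label_fractions: dict = field(
        default_factory=lambda: {
            "no_effect": 0.55,
            "ir_responsive": 0.20,
            "es_responsive": 0.09,
            "switch": 0.16,
        }
    )
    #: exon/intron length ranges (uniform integers, inclusive)
    exon_len: tuple[int, int] = (80, 200)
    intron_len: tuple[int, int] = (150, 400)
    #: fraction of loci deliberately failing the metagene length filters
    #: (short introns), so filter paths are exercised
    frac_filter_fail: float = 0.05
    short_intron_len: tuple[int, int] = (60, 90)
    spacer_len: int = 100
    chrom: str = "chrS"
    #: per-label GC targets for (upstream intron, exons, retained intron)
    gc_targets: dict = field(
        default_factory=lambda: {
            "no_effect": (0.40, 0.60, 0.40),
            "ir_responsive": (0.45, 0.60, 0.55),
            "es_responsive": (0.35, 0.60, 0.35),
            "switch": (0.50, 0.60, 0.55),
        }
    )
    #: treatment effect sizes: probability mass moved out of inclusion
    delta_ir: float = 0.4
    delta_es: float = 0.4
    #: mutant attenuation of the compound's IR response
    y36c_ir_attenuation: float = 0.25
    #: WT cells respond to ES-responsive loci at this fraction of delta_es
    wt_es_fraction: float = 0.5
    #: GC→effect coupling: multiplier = clip(gc_intron / gc_ref, 0, 1);
    #: gc_ref <= 0 disables the coupling (multiplier 1)
    gc_ref: float = 0.55
    #: sequencing depth (mean informative reads per site per sample)
    depth: float = 200.0
    #: negative-binomial dispersion (variance = mean + dispersion * mean^2)
    nb_dispersion: float = 0.05
    #: Dirichlet concentration around the condition trifurcation probabilities
    dirichlet_conc: float = 150.0
    #: clone-variant simulation
    n_clones_per_arm: int = 6
    arms: tuple[str, str] = ("E7107", "herboxidiene")
    background_rate: float = 3.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.label_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"label fractions sum to {total}, not 1")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if any(f < 0 for f in self.label_fractions.values()):
            raise ValueError("negative label fraction")

    def samples(self) -> list[tuple[str, str, str]]:
        """(sample_name, genotype, treatment) for every sample in the design."""
        out = []
        for g in GENOTYPES:
            for t in TREATMENTS:
                for r in range(1, self.n_replicates + 1):
                    out.append((f"{g}_{t}_r{r}", g, t))
        return out

    def child_seeds(self) -> dict[str, np.random.SeedSequence]:
        """Named per-stage child seeds derived from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        return dict(zip(("genome", "counts", "variants", "analysis"), children))


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """Sample a sequence base-by-base with P(G or C) = gc."""
    is_gc = rng.random(length) < gc
    pick = rng.integers(0, 2, size=length)
    bases = np.where(is_gc, np.where(pick == 0, "G", "C"), np.where(pick == 0, "A", "T"))
    return "".join(bases)


def make_genome_and_annotation(
    config: SimConfig, seed: np.random.SeedSequence | int | None = None
) -> tuple[dict[str, str], AnnotationModel, pd.DataFrame]:
    """Build the synthetic genome, its annotation and the truth table.

    Every locus is one three-exon transcript (exon–intron–cassette exon–
    intron–exon) laid head-to-tail on a single chromosome with spacers;
    strands alternate so both orientations are exercised.  Returns
    ``(genome, annotation, truth)`` where genome maps chrom → sequence.
    """
    if seed is None:
        seed = config.child_seeds()["genome"]
    rng = np.random.default_rng(seed)

    n = config.n_loci
    labels = rng.permutation(
        np.repeat(
            LABELS,
            _label_counts(config.label_fractions, n),
        )
    )
    filter_fail = rng.random(n) < config.frac_filter_fail

    chunks: list[str] = []
    pos = 0
    truth_rows = []
    annotation = AnnotationModel()
    chrom = config.chrom
    for i in range(n):
        label = labels[i]
        strand = "+" if i % 2 == 0 else "-"
        gc_i1, gc_ex, gc_i2 = config.gc_targets[label]
        e_lo, e_hi = config.exon_len
        i_lo, i_hi = (config.short_intron_len if filter_fail[i] else config.intron_len)
        exon_lens = rng.integers(e_lo, e_hi + 1, size=3)
        intron_lens = rng.integers(i_lo, i_hi + 1, size=2)
        # genomic layout left-to-right; on '-' the transcript 5' end is the
        # right-most exon, so swap the intron GC roles to keep "retained
        # intron" = the intron upstream of the shared 3'ss in transcript order
        if strand == "+":
            feat_gc = [gc_ex, gc_i1, gc_ex, gc_i2, gc_ex]
        else:
            feat_gc = [gc_ex, gc_i2, gc_ex, gc_i1, gc_ex]
        feat_len = [
            exon_lens[0],
            intron_lens[0],
            exon_lens[1],
            intron_lens[1],
            exon_lens[2],
        ]
        chunks.append(_random_sequence(config.spacer_len, 0.5, rng))
        pos += config.spacer_len
        coords = []
        for L, gc in zip(feat_len, feat_gc):
            chunks.append(_random_sequence(int(L), gc, rng))
            coords.append((pos + 1, pos + int(L)))
            pos += int(L)
        exons = [coords[0], coords[2], coords[4]]
        tx = Transcript(f"locus{i:05d}", f"gene{i:05d}", chrom, strand, exons)
        annotation.add(tx)

        introns_tx = tx.introns_5p_to_3p()
        up_intron, ret_intron = introns_tx[0], introns_tx[1]
        ret_key = (chrom, ret_intron[0], ret_intron[1], strand)
        site = acceptor_site(ret_key)
        up_key = (chrom, up_intron[0], up_intron[1], strand)
        skip_key = (
            chrom,
            min(up_intron[0], ret_intron[0]),
            max(up_intron[1], ret_intron[1]),
            strand,
        )

        base = _baseline_trifurcation(rng)
        cond = _condition_probabilities(config, label, gc_i2, base)
        row = {
            "locus_id": tx.transcript_id,
            "chrom": chrom,
            "strand": strand,
            "label": label,
            "filter_ok": not filter_fail[i],
            "gc_intron_up": gc_i1,
            "gc_exon": gc_ex,
            "gc_intron_ret": gc_i2,
            "site": format_site_key(site),
            "junction_up": f"{chrom}:{up_key[1]}-{up_key[2]}:{strand}",
            "junction_inc": f"{chrom}:{ret_key[1]}-{ret_key[2]}:{strand}",
            "junction_skip": f"{chrom}:{skip_key[1]}-{skip_key[2]}:{strand}",
        }
        for (g, t), (p_es, p_inc, p_ir) in cond.items():
            row[f"p_es_{g}_{t}"] = p_es
            row[f"p_inc_{g}_{t}"] = p_inc
            row[f"p_ir_{g}_{t}"] = p_ir
        truth_rows.append(row)

    genome = {chrom: "".join(chunks)}
    truth = pd.DataFrame(truth_rows)
    return genome, annotation, truth


def _label_counts(fractions: dict, n: int) -> list[int]:
    counts = [int(round(fractions[lab] * n)) for lab in LABELS]
    counts[0] += n - sum(counts)  # absorb rounding in the no-effect class
    return counts


def _baseline_trifurcation(rng: np.random.Generator) -> tuple[float, float, float]:
    """Control-condition (ES, inclusion, IR) probabilities: inclusion-dominant."""
    es = rng.uniform(0.02, 0.08)
    ir = rng.uniform(0.02, 0.08)
    return (es, 1.0 - es - ir, ir)


def _condition_probabilities(
    config: SimConfig, label: str, gc_ret_intron: float, base: tuple[float, float, float]
) -> dict[tuple[str, str], tuple[float, float, float]]:
    """Per-(genotype, treatment) trifurcation probabilities for one locus."""
    mult = 1.0
    if config.gc_ref > 0:
        mult = float(np.clip(gc_ret_intron / config.gc_ref, 0.0, 1.0))
    d_ir = config.delta_ir * mult
    d_es = config.delta_es * mult

    def shift(es=0.0, ir=0.0):
        e, i, r = base[0] + es, base[1] - es - ir, base[2] + ir
        if i < 0:
            raise ValueError("effect sizes exhaust the inclusion probability")
        return (e, i, r)

    out = {}
    for g in GENOTYPES:
        out[(g, "control")] = base
    if label == "no_effect":
        out[("WT", "compound")] = base
        out[("Y36C", "compound")] = base
    elif label == "ir_responsive":
        out[("WT", "compound")] = shift(ir=d_ir)
        out[("Y36C", "compound")] = shift(ir=d_ir * config.y36c_ir_attenuation)
    elif label == "es_responsive":
        # the WT response is ES-directed too: a slight IR decrease keeps
        # these loci from drifting across the strict ES/IR switch boundary
        out[("WT", "compound")] = shift(
            es=d_es * config.wt_es_fraction, ir=-min(0.02, base[2] / 2)
        )
        out[("Y36C", "compound")] = shift(es=d_es)
    elif label == "switch":
        out[("WT", "compound")] = shift(ir=d_ir)
        out[("Y36C", "compound")] = shift(es=d_es)
    else:  # pragma: no cover
        raise ValueError(f"unknown label {label!r}")
    return out


def simulate_counts(
    config: SimConfig,
    truth: pd.DataFrame,
    seed: np.random.SeedSequence | int | None = None,
) -> tuple[dict[str, list[JunctionRecord]], dict[tuple[str, tuple[str, int, str]], int]]:
    """Per-sample junction tables and boundary counts from the truth table.

    For each locus and sample the informative read total is negative
    binomial around the configured depth; the total splits among
    (ES, inclusion, IR) by a Dirichlet-multinomial around the condition's
    trifurcation probabilities.  Inclusion reads support both annotated
    intron junctions, ES reads the skip junction, and IR reads the
    exon–intron boundary at the shared 3' splice site.
    """
    if seed is None:
        seed = config.child_seeds()["counts"]
    rng = np.random.default_rng(seed)
    n = len(truth)
    size = 1.0 / config.nb_dispersion  # NB shape: var = mu + mu^2/size
    p_nb = size / (size + config.depth)

    junctions: dict[str, list[JunctionRecord]] = {}
    boundaries: dict[tuple[str, tuple[str, int, str]], int] = {}

    jkeys = {
        col: [_parse_junction(s) for s in truth[f"junction_{col}"]]
        for col in ("up", "inc", "skip")
    }
    sites = [_parse_site(s) for s in truth["site"]]

    for sample, genotype, treatment in config.samples():
        probs = truth[
            [
                f"p_es_{genotype}_{treatment}",
                f"p_inc_{genotype}_{treatment}",
                f"p_ir_{genotype}_{treatment}",
            ]
        ].to_numpy()
        totals = rng.negative_binomial(size, p_nb, size=n)
        alpha = config.dirichlet_conc * probs
        g = rng.gamma(alpha)
        p = g / g.sum(axis=1, keepdims=True)
        counts = rng.multinomial(totals, p)  # n x 3: ES, inclusion, IR
        recs = []
        for i in range(n):
            es, inc, ir = (int(x) for x in counts[i])
            c, a, b, s = jkeys["up"][i]
            recs.append(JunctionRecord(c, a, b, s, inc))
            c, a, b, s = jkeys["inc"][i]
            recs.append(JunctionRecord(c, a, b, s, inc))
            c, a, b, s = jkeys["skip"][i]
            recs.append(JunctionRecord(c, a, b, s, es))
            boundaries[(sample, sites[i])] = ir
        junctions[sample] = recs
    return junctions, boundaries


def _parse_junction(text: str) -> tuple[str, int, int, str]:
    chrom, span, strand = text.rsplit(":", 2)
    a, b = span.split("-")
    return (chrom, int(a), int(b), strand)


def _parse_site(text: str) -> tuple[str, int, str]:
    chrom, pos, strand = text.rsplit(":", 2)
    return (chrom, int(pos), strand)


# ---------------------------------------------------------------------------
# Clone variants
# ---------------------------------------------------------------------------

#: curated spliceosome gene list shipped as the simulation's default
DEFAULT_GENE_LIST = [
    "SF3B1", "SF3B2", "SF3B3", "SF3B4", "SF3B5", "SF3B6", "PHF5A",
    "U2AF1", "U2AF2", "SF3A1", "SF3A2", "SF3A3", "SRSF2", "SNRPB",
    "SNRNP200", "PRPF8", "RBM39", "HTATSF1", "DDX46", "SF1",
]

#: background (non-driver) genes outside the curated list
BACKGROUND_GENES = [
    "TP53", "TTN", "MUC16", "KRAS", "OBSCN", "RYR2", "ABCA13", "CSMD1",
]


def simulate_clone_variants(
    config: SimConfig,
    seed: np.random.SeedSequence | int | None = None,
    drivers: list[tuple[str, str, str, str]] | None = None,
) -> tuple[list[VariantRecord], dict[str, str]]:
    """Per-clone variant tables with planted recurrent drivers.

    ``drivers`` lists (clone_id, gene, protein_change, effect) records;
    the default plants SF3B1 mutations in five clones of the first arm plus
    two of the second, and a recurrent PHF5A Y36C in the remaining clones —
    the recurrence structure of a two-arm resistant-clone screen.  Passenger
    background variants are Poisson per clone with AF ~ Uniform(0.05, 1),
    drawn from both listed genes (as synonymous) and unlisted genes.
    Returns (variants, clone→arm map).
    """
    if seed is None:
        seed = config.child_seeds()["variants"]
    rng = np.random.default_rng(seed)
    clones = {
        f"{arm}_c{i}": arm
        for arm in config.arms
        for i in range(1, config.n_clones_per_arm + 1)
    }
    if drivers is None:
        drivers = default_driver_plan(config)
    variants = [
        VariantRecord(clone, gene, change, effect, float(rng.uniform(0.35, 0.95)))
        for clone, gene, change, effect in drivers
    ]
    for clone in clones:
        n_bg = rng.poisson(config.background_rate)
        for _ in range(n_bg):
            af = float(rng.uniform(0.05, 1.0))
            if rng.random() < 0.3:
                gene = DEFAULT_GENE_LIST[rng.integers(len(DEFAULT_GENE_LIST))]
                effect = "synonymous"  # listed gene but silent: must be filtered out
            else:
                gene = BACKGROUND_GENES[rng.integers(len(BACKGROUND_GENES))]
                effect = "missense"
            variants.append(
                VariantRecord(clone, gene, f"P{int(rng.integers(1, 999))}L", effect, af)
            )
    log.info("simulated %d variants over %d clones", len(variants), len(clones))
    return variants, clones


def reference_clone_screen() -> tuple[list[VariantRecord], dict[str, str]]:
    """The two-arm resistant-clone screen layout used as a worked fixture.

    Twelve clones, six per compound arm: SF3B1 HEAT-repeat mutations in five
    pladienolide-arm clones plus two herboxidiene-arm clones, and PHF5A Y36C
    in the remaining pladienolide-arm clone plus four herboxidiene-arm
    clones.  At a three-clone recurrence threshold the report is exactly
    {SF3B1: 7 clones, PHF5A: 5 clones}.
    """
    variants = []
    arms = {}
    sf3b1 = ["R1074H", "V1078A", "V1078I", "R1074H", "V1078A"]
    for i in range(1, 7):
        arms[f"E7107_c{i}"] = "E7107"
        arms[f"herboxidiene_c{i}"] = "herboxidiene"
    for i in range(1, 6):
        variants.append(
            VariantRecord(f"E7107_c{i}", "SF3B1", sf3b1[i - 1], "missense", 0.45)
        )
    variants.append(VariantRecord("E7107_c6", "PHF5A", "Y36C", "missense", 0.48))
    variants.append(VariantRecord("herboxidiene_c1", "SF3B1", "R1074H", "missense", 0.52))
    variants.append(VariantRecord("herboxidiene_c2", "SF3B1", "K1071E", "missense", 0.41))
    for i in range(3, 7):
        variants.append(
            VariantRecord(f"herboxidiene_c{i}", "PHF5A", "Y36C", "missense", 0.5)
        )
    return variants, arms


def default_driver_plan(config: SimConfig) -> list[tuple[str, str, str, str]]:
    """Driver layout: 5 + 2 clones with SF3B1 HEAT-repeat mutations, the
    remaining 1 + 4 clones with PHF5A Y36C, and one mixed clone carrying
    both populations."""
    arm1, arm2 = config.arms
    plan: list[tuple[str, str, str, str]] = []
    sf3b1 = ["R1074H", "V1078A", "V1078I", "R1074H", "V1078A"]
    for i in range(1, 6):
        plan.append((f"{arm1}_c{i}", "SF3B1", sf3b1[(i - 1) % len(sf3b1)], "missense"))
    plan.append((f"{arm1}_c6", "PHF5A", "Y36C", "missense"))
    plan.append((f"{arm2}_c1", "SF3B1", "R1074H", "missense"))
    plan.append((f"{arm2}_c2", "SF3B1", "K1071E", "missense"))
    for i in range(3, 7):
        plan.append((f"{arm2}_c{i}", "PHF5A", "Y36C", "missense"))
    # the mixed clone: two populations in one isolate
    plan.append((f"{arm2}_c3", "SF3B1", "K1071E", "missense"))
    return plan


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_dataset(config: SimConfig, outdir: str | Path) -> Path:
    """Emit a self-contained dataset directory.

    Contents: ``genome.fa``, ``annotation.bed``, ``junctions/<sample>.sj.tab``,
    ``boundary_counts.tsv``, ``variants.tsv``, ``gene_list.txt``,
    ``clone_arms.tsv``, ``design.tsv``, ``truth.tsv`` and a ``config.yaml``
    echo.  Fully deterministic under ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.child_seeds()

    genome, annotation, truth = make_genome_and_annotation(config, seeds["genome"])
    write_fasta(genome, outdir / "genome.fa")
    write_bed12(annotation, outdir / "annotation.bed")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    junctions, boundaries = simulate_counts(config, truth, seeds["counts"])
    jdir = outdir / "junctions"
    jdir.mkdir(exist_ok=True)
    for sample, recs in junctions.items():
        write_junction_table(recs, jdir / f"{sample}.sj.tab")
    write_boundary_counts(boundaries, outdir / "boundary_counts.tsv")

    variants, clone_arms = simulate_clone_variants(config, seeds["variants"])
    write_variants_tsv(variants, outdir / "variants.tsv")
    with open(outdir / "gene_list.txt", "w") as fh:
        fh.write("\n".join(DEFAULT_GENE_LIST) + "\n")
    with open(outdir / "clone_arms.tsv", "w") as fh:
        for clone, arm in sorted(clone_arms.items()):
            fh.write(f"{clone}\t{arm}\n")

    with open(outdir / "design.tsv", "w") as fh:
        fh.write("sample\tgenotype\ttreatment\treplicate\n")
        for sample, g, t in config.samples():
            fh.write(f"{sample}\t{g}\t{t}\t{sample.rsplit('r', 1)[1]}\n")

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
    return outdir
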