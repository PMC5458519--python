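"""End-to-end orchestration: PSI → differential → GC profiles → switch →
variant triage, with a manifest and per-stage resumability.

Every stage reads its inputs from files (the data directory plus earlier
stage outputs in the run directory) and writes TSV outputs, so a run can be
resumed from any stage and reproduces the full run bit-for-bit.  All
randomness (pair selection, background sampling, bootstraps) derives from
the run seed through fixed per-stage child seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, gc_metagene, psi, resistance, switch
from .formats_io import (
    format_site_key,
    parse_site_key,
    read_annotation,
    read_boundary_counts,
    read_gene_list,
    read_junction_table,
    read_variants,
)

log = logging.getLogger("splicemod")

STAGES = ("psi", "diff", "gc", "switch", "variants")


@dataclass
class RunConfig:
    """Paths, contrasts and thresholds of one analysis run.

    ``comparisons`` maps a contrast name to (control samples, treatment
    samples); contrasts are declared explicitly rather than inferred from
    the design table.  Thresholds default to the analysis constants used
    throughout: q ≤ 0.05 significance, allele frequency > 0.2, recurrence
    in ≥ 3 clones, 100 bootstraps, 10,000 background pairs.
    """

    data_dir: str
    out_dir: str
    comparisons: dict[str, tuple[list[str], list[str]]] = field(default_factory=dict)
    #: contrast used for IR-side analyses (wild-type response)
    ir_comparison: str = "WT_compound_vs_control"
    #: contrast used for ES-side and switch analyses (mutant response)
    es_comparison: str = "Y36C_compound_vs_control"
    #: switch condition B: the genotype/treatment whose trifurcation is
    #: compared against the ES-defining condition A
    switch_condition_a: tuple[str, str] = ("Y36C", "compound")
    switch_condition_b: tuple[str, str] = ("WT", "compound")
    q_max: float = 0.05
    epsilon: float = 0.01
    min_samples: int = 2
    af_min: float = 0.2
    min_clones: int = 3
    n_boot: int = 100
    n_background: int = 10_000
    min_reads: int = 0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.q_max <= 1 and 0 <= self.af_min <= 1):
            raise ValueError("thresholds out of range")
        if self.n_boot < 1 or self.n_background < 1 or self.min_clones < 1:
            raise ValueError("thresholds out of range")

    # -- construction -------------------------------------------------------

    @classmethod
    def default_for(
        cls, data_dir: str | Path, out_dir: str | Path, seed: int = 0, **kw
    ) -> "RunConfig":
        """Config for a simulated dataset directory: one compound-vs-control
        contrast per genotype, samples taken from ``design.tsv``."""
        design = pd.read_csv(Path(data_dir) / "design.tsv", sep="\t")
        comparisons = {}
        for g in sorted(design["genotype"].unique()):
            ctrl = design.query("genotype == @g and treatment == 'control'")["sample"]
            trt = design.query("genotype == @g and treatment == 'compound'")["sample"]
            comparisons[f"{g}_compound_vs_control"] = (sorted(ctrl), sorted(trt))
        return cls(str(data_dir), str(out_dir), comparisons, seed=seed, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["comparisons"] = {
            k: (list(v[0]), list(v[1])) for k, v in raw.get("comparisons", {}).items()
        }
        for key in ("switch_condition_a", "switch_condition_b"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def design(self) -> pd.DataFrame:
        df = pd.read_csv(Path(self.data_dir) / "design.tsv", sep="\t", dtype=str)
        missing = {
            s for grp in self.comparisons.values() for side in grp for s in side
        } - set(df["sample"])
        if missing:
            raise ValueError(f"comparison samples absent from design table: {sorted(missing)}")
        return df

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Stage-scoped generator: fixed spawn key per stage name, so partial
        reruns see identical streams."""
        key = STAGES.index(stage)
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Stage 1: PSI quantification
# ---------------------------------------------------------------------------


def stage_psi(config: RunConfig) -> pd.DataFrame:
    """Per-sample trifurcation and junction PSI tables.

    At every 3' splice site with junction evidence the unique reads split
    into ES (skip-junction), inclusion (annotated-intron junction) and IR
    (boundary-crossing) classes; their fractions are the per-class PSIs.
    Junction-level PSI at donor and acceptor groups is written alongside.
    """
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = read_annotation(data / "annotation.bed")
    index = differential.AnnotationIndex.build(annotation)
    boundaries = read_boundary_counts(data / "boundary_counts.tsv")
    design = config.design()

    tri_rows = []
    psi_rows = []
    for sample in design["sample"]:
        records = read_junction_table(data / "junctions" / f"{sample}.sj.tab")
        counts = {}
        for r in records:
            key = psi.junction_key(r)
            counts[key] = counts.get(key, 0) + r.unique_reads
        groups = psi.index_shared_sites(counts.keys())
        jpsi = psi.compute_junction_psi(counts, groups)
        for key, (pd_, pa) in sorted(jpsi.items()):
            psi_rows.append(
                {
                    "sample": sample,
                    "junction": f"{key[0]}:{key[1]}-{key[2]}:{key[3]}",
                    "category": differential.classify_junction(key, index),
                    "reads": counts[key],
                    "psi_donor": pd_,
                    "psi_acceptor": pa,
                }
            )
        # trifurcation at acceptor sites
        site_classes: dict[tuple, dict[str, int]] = {}
        for key, n in counts.items():
            if key[3] == ".":
                continue
            site = psi.acceptor_site(key)
            cls = differential.classify_junction(key, index)
            bucket = site_classes.setdefault(site, {"es": 0, "inc": 0})
            if cls == "ES":
                bucket["es"] += n
            elif cls == "canonical":
                bucket["inc"] += n
        for site in sorted(site_classes):
            es = site_classes[site]["es"]
            inc = site_classes[site]["inc"]
            ir = boundaries.get((sample, site), 0)
            tri = psi.trifurcate_3ss(site, es, inc, ir)
            if tri.total_reads < config.min_reads:
                continue
            tri_rows.append(
                {
                    "sample": sample,
                    "site": format_site_key(site),
                    "es_reads": es,
                    "inc_reads": inc,
                    "ir_reads": ir,
                    "total_reads": tri.total_reads,
                    "psi_es": tri.psi_es,
                    "psi_inc": tri.psi_inc,
                    "psi_ir": tri.psi_ir,
                }
            )
    tri = pd.DataFrame(tri_rows)
    tri.to_csv(out / "trifurcation.tsv", sep="\t", index=False)
    pd.DataFrame(psi_rows).to_csv(out / "junction_psi.tsv", sep="\t", index=False)
    log.info("stage psi: %d trifurcation records, %d junction records", len(tri), len(psi_rows))
    return tri


# ---------------------------------------------------------------------------
# Stage 2: differential PSI
# ---------------------------------------------------------------------------


def _event_matrix(tri: pd.DataFrame, jpsi: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Events × samples PSI matrix plus per-event categories.

    Junction events (key ``J@chrom:a-b:strand``) use the acceptor-side PSI;
    boundary events (``IR@site``) use the trifurcation IR fraction.
    Canonical junctions are categorised 'inclusion' and additionally
    contribute a donor-side event (``D@...``, category 'inclusion_5p') —
    an upstream intron competing with a skip junction only shares its
    donor with it, so its inclusion evidence lives on the donor side.
    """
    jm = jpsi.pivot_table(
        index="junction", columns="sample", values="psi_acceptor", aggfunc="first"
    )
    jcat = (
        jpsi.drop_duplicates("junction").set_index("junction")["category"]
    ).replace({"canonical": "inclusion"})
    canonical = jcat.index[jcat == "inclusion"]
    dm = (
        jpsi[jpsi["junction"].isin(canonical)]
        .pivot_table(index="junction", columns="sample", values="psi_donor", aggfunc="first")
    )
    dcat = pd.Series("inclusion_5p", index="D@" + dm.index)
    dm.index = "D@" + dm.index
    jm.index = "J@" + jm.index
    jcat.index = "J@" + jcat.index

    im = tri.pivot_table(index="site", columns="sample", values="psi_ir", aggfunc="first")
    im.index = "IR@" + im.index
    icat = pd.Series("IR", index=im.index)

    mat = pd.concat([jm, dm, im])
    cat = pd.concat([jcat, dcat, icat])
    return mat, cat.loc[mat.index]


def stage_diff(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Moderated-t differential PSI for every declared contrast.

    delta_psi is treatment − control; one variance prior is fit per
    contrast across all testable events.  Writes ``diff_<name>.tsv`` and a
    Fig-style per-category summary ``summary_<name>.tsv``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tri = pd.read_csv(out / "trifurcation.tsv", sep="\t")
    jpsi = pd.read_csv(out / "junction_psi.tsv", sep="\t")
    mat, cat = _event_matrix(tri, jpsi)

    results = {}
    for name, (ctrl, trt) in config.comparisons.items():
        labels = {s: "control" for s in ctrl} | {s: "treatment" for s in trt}
        res = differential.moderated_t_test(
            mat[[*ctrl, *trt]],
            labels,
            group_order=("control", "treatment"),
            min_samples=config.min_samples,
        )
        res.insert(0, "category", cat)
        res.insert(0, "event_key", res.index)
        res["log2fc"] = np.log2(
            (res["mean_2"] + config.epsilon) / (res["mean_1"] + config.epsilon)
        )
        res.to_csv(out / f"diff_{name}.tsv", sep="\t", index=False)
        # donor-side helper events would double-count inclusion in summaries
        summary = differential.summarize_events(
            res[res["category"] != "inclusion_5p"], config.q_max, config.epsilon
        )
        summary.to_csv(out / f"summary_{name}.tsv", sep="\t", index=False)
        prior = res.attrs["prior"]
        log.info(
            "stage diff %s: %d events, %d significant (d0=%.3g, s0^2=%.3g)",
            name,
            len(res),
            int((res["q"] <= config.q_max).sum()),
            prior.d0,
            prior.s0_sq,
        )
        results[name] = res
    return results


def _load_diff(config: RunConfig, name: str) -> pd.DataFrame:
    path = Path(config.out_dir) / f"diff_{name}.tsv"
    if not path.exists():
        raise FileNotFoundError(f"stage diff output missing: {path}")
    return pd.read_csv(path, sep="\t")


def significant_events(
    diff: pd.DataFrame, category: str, q_max: float, direction: int = +1
) -> pd.DataFrame:
    """Significant events of one category with the given response direction
    (+1: increased under treatment, −1: decreased)."""
    mask = (
        (diff["category"] == category)
        & (diff["q"] <= q_max)
        & diff["q"].notna()
        & (np.sign(diff["delta_psi"]) == direction)
    )
    return diff[mask]


def _junction_from_key(event_key: str) -> tuple[str, int, int, str]:
    chrom, span, strand = event_key[2:].rsplit(":", 2)
    a, b = span.split("-")
    return (chrom, int(a), int(b), strand)


# ---------------------------------------------------------------------------
# Stage 3: GC metagene profiles
# ---------------------------------------------------------------------------


def stage_gc(config: RunConfig) -> dict[str, gc_metagene.GCProfile]:
    """GC profiles for significant IR pairs and ES triplets plus one shared
    random background, each with bootstrap CIs."""
    import pyfaidx

    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = read_annotation(data / "annotation.bed")
    genome = pyfaidx.Fasta(str(data / "genome.fa"))
    rng = config.stage_rng("gc")

    profiles: dict[str, gc_metagene.GCProfile] = {}
    # one shared background per run, reused across panels
    profiles["background"] = gc_metagene.sample_background(
        annotation, genome, n=config.n_background, seed=rng, n_boot=config.n_boot
    )

    for name in config.comparisons:
        diff = _load_diff(config, name)
        ir_sites = [
            parse_site_key(k[3:])
            for k in significant_events(diff, "IR", config.q_max)["event_key"]
        ]
        if ir_sites:
            pairs = gc_metagene.select_ir_pairs(ir_sites, annotation, genome, seed=rng)
            if pairs:
                profiles[f"ir_{name}"] = gc_metagene.profile_with_bootstrap(
                    pairs, n_boot=config.n_boot, seed=rng
                )
        es_keys = [
            _junction_from_key(k)
            for k in significant_events(diff, "ES", config.q_max)["event_key"]
        ]
        # untreated exon-inclusion evidence: canonical-intron events whose
        # inclusion PSI is significantly higher in the untreated samples,
        # on either the acceptor (J@) or the donor (D@) side
        inclusion_q: dict[tuple, float] = {}
        for category in ("inclusion", "inclusion_5p"):
            sub = significant_events(diff, category, config.q_max, direction=-1)
            for k, qv in zip(sub["event_key"], sub["q"]):
                jk = _junction_from_key(k)
                inclusion_q[jk] = min(qv, inclusion_q.get(jk, 1.0))
        triplets = gc_metagene.select_es_triplets(
            es_keys, inclusion_q, annotation, genome, q_max=config.q_max
        )
        if triplets:
            ups, downs = zip(*triplets)
            profiles[f"es_upstream_{name}"] = gc_metagene.profile_with_bootstrap(
                list(ups), n_boot=config.n_boot, seed=rng
            )
            profiles[f"es_downstream_{name}"] = gc_metagene.profile_with_bootstrap(
                list(downs), n_boot=config.n_boot, seed=rng
            )

    for pname, prof in profiles.items():
        prof.to_frame().to_csv(out / f"gcprofile_{pname}.tsv", sep="\t", index=False)
    log.info("stage gc: wrote %d profiles", len(profiles))
    return profiles


# ---------------------------------------------------------------------------
# Stage 4: switch analysis
# ---------------------------------------------------------------------------


def group_mean_trifurcation(
    tri: pd.DataFrame, samples: list[str]
) -> dict[tuple, psi.TrifurcationPSI]:
    """Replicate-averaged trifurcation PSIs over a sample group.

    Means are taken over samples where PSI is defined; the returned records
    carry the number of contributing samples in ``total_reads``.
    """
    sub = tri[tri["sample"].isin(samples)]
    out = {}
    for site_txt, grp in sub.groupby("site"):
        site = parse_site_key(site_txt)
        es, n = psi.average_replicates(list(grp["psi_es"]))
        inc, _ = psi.average_replicates(list(grp["psi_inc"]))
        ir, _ = psi.average_replicates(list(grp["psi_ir"]))
        if n == 0:
            out[site] = psi.TrifurcationPSI(site, math.nan, math.nan, math.nan, 0)
        else:
            out[site] = psi.TrifurcationPSI(site, es, inc, ir, n)
    return out


def stage_switch(config: RunConfig) -> pd.DataFrame:
    """ES↔IR switch table between the two compound-treated genotypes.

    Condition A is the contrast that defined the significant ES set (the
    mutant line under compound); condition B is the wild-type line under
    compound.  Writes the waterfall-ordered table plus a one-line summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tri = pd.read_csv(out / "trifurcation.tsv", sep="\t")
    diff = _load_diff(config, config.es_comparison)
    design = config.design()

    sig_es = significant_events(diff, "ES", config.q_max)
    es_sites = sorted(
        {psi.acceptor_site(_junction_from_key(k)) for k in sig_es["event_key"]}
    )

    def condition_samples(genotype: str, treatment: str) -> list[str]:
        sel = design.query("genotype == @genotype and treatment == @treatment")
        return sorted(sel["sample"])

    tri_a = group_mean_trifurcation(tri, condition_samples(*config.switch_condition_a))
    tri_b = group_mean_trifurcation(tri, condition_samples(*config.switch_condition_b))
    table = switch.build_switch_table(es_sites, tri_a, tri_b)
    ordered = switch.waterfall_order(table, "A")
    n_switch, n_total, fraction = switch.count_switches(table)
    ordered.to_csv(out / "switch_waterfall.tsv", sep="\t", index=False)
    with open(out / "switch_summary.tsv", "w") as fh:
        fh.write("n_switch\tn_total\tfraction\n")
        fh.write(f"{n_switch}\t{n_total}\t{fraction:.6g}\n")
    log.info("stage switch: %d/%d sites switch (%.1f%%)", n_switch, n_total, 100 * fraction if n_total else float("nan"))
    return ordered


# ---------------------------------------------------------------------------
# Stage 5: variant triage
# ---------------------------------------------------------------------------


def stage_variants(config: RunConfig) -> resistance.RecurrenceReport:
    """Filter clone variants and report recurrently mutated genes."""
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    variants = read_variants(data / "variants.tsv")
    gene_list = read_gene_list(data / "gene_list.txt")
    arms_path = data / "clone_arms.tsv"
    clone_arms = None
    if arms_path.exists():
        clone_arms = dict(
            line.split("\t") for line in arms_path.read_text().strip().splitlines()
        )
    kept = resistance.filter_variants(variants, gene_list, config.af_min)
    report = resistance.recurrent_genes(kept, config.min_clones, clone_arms)
    with open(out / "recurrence_report.tsv", "w") as fh:
        fh.write("gene\tn_clones\tclones\n")
        for gene in report.genes():
            clones = sorted({c for c, _ in report.hits[gene]})
            fh.write(f"{gene}\t{report.n_clones[gene]}\t{','.join(clones)}\n")
    with open(out / "recurrence_summary.txt", "w") as fh:
        fh.write("\n".join(report.summary_lines()) + "\n")
    log.info("stage variants: %d/%d variants kept, %d recurrent genes", len(kept), len(variants), len(report.n_clones))
    return report


# ---------------------------------------------------------------------------
# End to end
# ---------------------------------------------------------------------------

_STAGE_FUNCS = {
    "psi": stage_psi,
    "diff": stage_diff,
    "gc": stage_gc,
    "switch": stage_switch,
    "variants": stage_variants,
}


def run_end_to_end(config: RunConfig, start_stage: str = "psi") -> Path:
    """Run all stages from ``start_stage`` on and write the run manifest.

    Stage order: psi → diff → gc → switch; the variants path is independent
    and runs last.  Any stage failure aborts with the stage name and cause.
    """
    if start_stage not in STAGES:
        raise ValueError(f"unknown stage {start_stage!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    todo = STAGES[STAGES.index(start_stage) :]
    for stage in todo:
        try:
            _STAGE_FUNCS[stage](config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages_run": list(todo),
        "outputs": sorted(
            p.name for p in out.iterdir() if p.suffix in (".tsv", ".txt", ".yaml")
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
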