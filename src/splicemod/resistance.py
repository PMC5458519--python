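"""Resistant-clone variant triage: non-silent, high-AF, recurrent genes.

Whole-exome variant calls from compound-resistant clones are filtered to
non-silent mutations in a curated spliceosome gene list with allele
frequency strictly above 0.2, then genes recurrently hit in at least three
distinct clones are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .formats_io import VariantRecord

#: effect classes counted as non-silent
NON_SILENT = frozenset({"missense", "nonsense", "frameshift", "inframe_indel", "splice_site"})


def filter_variants(
    variants: Iterable[VariantRecord],
    gene_list: set[str],
    af_min: float = 0.2,
    keep_effects: frozenset[str] = NON_SILENT,
) -> list[VariantRecord]:
    """Keep variants in listed genes with AF strictly above ``af_min`` and a
    non-silent effect class.  Idempotent; raising ``af_min`` only removes."""
    if not gene_list:
        raise ValueError("empty curated gene list")
    return [
        v
        for v in variants
        if v.gene in gene_list
        and v.allele_frequency > af_min
        and v.effect_class in keep_effects
    ]


@dataclass
class RecurrenceReport:
    """Genes hit in at least ``min_clones`` distinct clones.

    ``hits`` maps gene → set of (clone_id, protein_change); ``n_clones``
    counts distinct clones per gene; ``by_arm`` breaks clone counts down by
    treatment arm when a clone → arm mapping is supplied.
    """

    min_clones: int
    hits: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    n_clones: dict[str, int] = field(default_factory=dict)
    by_arm: dict[str, dict[str, int]] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return sorted(self.n_clones)

    def summary_lines(self) -> list[str]:
        lines = []
        for gene in sorted(self.n_clones, key=lambda g: (-self.n_clones[g], g)):
            arms = self.by_arm.get(gene, {})
            arm_txt = (
                " (" + ", ".join(f"{a}: {n}" for a, n in sorted(arms.items())) + ")"
                if arms
                else ""
            )
            lines.append(f"{gene}: {self.n_clones[gene]} clones{arm_txt}")
        return lines


def recurrent_genes(
    filtered_variants: Iterable[VariantRecord],
    min_clones: int = 3,
    clone_arms: Mapping[str, str] | None = None,
) -> RecurrenceReport:
    """Count genes by distinct affected clones and keep those at or above the
    recurrence threshold.  A clone with several variants in one gene counts
    once toward that gene."""
    per_gene: dict[str, set[tuple[str, str]]] = {}
    for v in filtered_variants:
        per_gene.setdefault(v.gene, set()).add((v.clone_id, v.protein_change))
    report = RecurrenceReport(min_clones=min_clones)
    for gene, pairs in per_gene.items():
        clones = {c for c, _ in pairs}
        if len(clones) < min_clones:
            continue
        report.hits[gene] = pairs
        report.n_clones[gene] = len(clones)
        if clone_arms:
            arms: dict[str, int] = {}
            for c in clones:
                arm = clone_arms.get(c, "unknown")
                arms[arm] = arms.get(arm, 0) + 1
            report.by_arm[gene] = arms
    return report
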