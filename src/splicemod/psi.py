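"""Junction PSI and the 3'-splice-site ES/inclusion/IR trifurcation.

PSI (percent spliced in) of a junction is its unique-read count divided by
the summed counts of all junctions that share the same splice site; it is
computed separately for the donor-sharing and the acceptor-sharing group.
At a shared 3' splice site the reads further trifurcate into exon skipping
(ES), exon inclusion and intron retention (IR) classes; their fractions of
the class total are the per-class PSIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .formats_io import JunctionRecord, SiteKey

# a splice-site group key: (chrom, position, strand, side)
GroupKey = tuple[str, int, str, str]
# a junction identity key (count-free)
JunctionKey = tuple[str, int, int, str]


def junction_key(j: JunctionRecord) -> JunctionKey:
    return (j.chrom, j.intron_first, j.intron_last, j.strand)


def donor_site(j: JunctionRecord | JunctionKey) -> SiteKey:
    """The 5' end of the intron on the transcript strand."""
    chrom, first, last, strand = j if isinstance(j, tuple) else junction_key(j)
    return (chrom, first if strand == "+" else last, strand)


def acceptor_site(j: JunctionRecord | JunctionKey) -> SiteKey:
    """The 3' end of the intron (3' splice site); on '-' this is the lower coordinate."""
    chrom, first, last, strand = j if isinstance(j, tuple) else junction_key(j)
    return (chrom, last if strand == "+" else first, strand)


def index_shared_sites(
    junctions: Iterable[JunctionRecord | JunctionKey],
) -> dict[GroupKey, list[JunctionKey]]:
    """Group junctions by shared splice site.

    Every stranded junction lands in exactly one donor group and one acceptor
    group, keyed by (chrom, position, strand, side).  Junctions with unknown
    strand are skipped (their site identity is ambiguous).
    """
    groups: dict[GroupKey, list[JunctionKey]] = {}
    for j in junctions:
        key = j if isinstance(j, tuple) else junction_key(j)
        if key[3] == ".":
            continue
        for side, site in (("donor", donor_site(key)), ("acceptor", acceptor_site(key))):
            groups.setdefault((*site, side), []).append(key)
    for members in groups.values():
        members.sort()
    return groups


def compute_junction_psi(
    counts: Mapping[JunctionKey, int],
    groups: Mapping[GroupKey, Sequence[JunctionKey]] | None = None,
) -> dict[JunctionKey, tuple[float, float]]:
    """Per-junction PSI at its donor and acceptor group, for one sample.

    PSI = junction count / summed counts over all junctions sharing the site.
    A group with zero total reads yields NaN (undefined), never 0/0.
    Unknown-strand junctions get PSI 1.0 only implicitly via singleton
    membership being impossible — they are excluded from grouping and return
    (nan, nan).
    """
    if groups is None:
        groups = index_shared_sites(counts.keys())
    group_sums = {
        gkey: sum(counts.get(m, 0) for m in members) for gkey, members in groups.items()
    }
    out: dict[JunctionKey, tuple[float, float]] = {}
    for key, n in counts.items():
        if key[3] == ".":
            out[key] = (math.nan, math.nan)
            continue
        psis = []
        for side, site in (("donor", donor_site(key)), ("acceptor", acceptor_site(key))):
            total = group_sums.get((*site, side), 0)
            psis.append(n / total if total > 0 else math.nan)
        out[key] = (psis[0], psis[1])
    return out


@dataclass(frozen=True)
class TrifurcationPSI:
    """ES/inclusion/IR fractional usage of one shared 3' splice site.

    When ``total_reads == 0`` all three fractions are NaN (undefined) and
    :attr:`defined` is False; downstream stages must not treat them as zero.
    """

    site_key: SiteKey
    psi_es: float
    psi_inc: float
    psi_ir: float
    total_reads: int

    @property
    def defined(self) -> bool:
        return self.total_reads > 0


def trifurcate_3ss(
    site_key: SiteKey, es_reads: int, inclusion_reads: int, ir_reads: int
) -> TrifurcationPSI:
    """Partition the reads informative at one 3' splice site into fractions.

    ES reads cover the junction that excludes the cassette exon, inclusion
    reads share the 3' splice site but use a 5' splice site bordering the
    cassette exon, IR reads cross the exon–intron boundary at the site.
    """
    for name, n in (("es", es_reads), ("inclusion", inclusion_reads), ("ir", ir_reads)):
        if n < 0:
            raise ValueError(f"negative {name} read count: {n}")
    total = es_reads + inclusion_reads + ir_reads
    if total == 0:
        return TrifurcationPSI(site_key, math.nan, math.nan, math.nan, 0)
    return TrifurcationPSI(
        site_key, es_reads / total, inclusion_reads / total, ir_reads / total, total
    )


def average_replicates(values: Sequence[float]) -> tuple[float, int]:
    """Mean PSI over replicate samples where PSI is defined.

    Returns ``(mean, n_defined)``; the mean is NaN when no sample has a
    defined value.  Averaging is over per-sample PSIs, not pooled counts.
    """
    defined = [v for v in values if not math.isnan(v)]
    if not defined:
        return (math.nan, 0)
    return (sum(defined) / len(defined), len(defined))
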