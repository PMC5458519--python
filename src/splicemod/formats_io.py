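"""Readers and writers for the tabular formats the pipeline touches.

All genomic coordinates are 1-based and inclusive internally, matching the
splice-junction table dialect (STAR ``SJ.out.tab``): for a junction the
coordinates are the first and last *intronic* bases.  BED input/output is
converted at the I/O boundary only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger("splicemod")

# ---------------------------------------------------------------------------
# Junction tables (STAR SJ.out.tab dialect)
# ---------------------------------------------------------------------------

#: column-4 strand codes of the junction-table dialect
STRAND_CODES = {0: ".", 1: "+", 2: "-"}
STRAND_TO_CODE = {v: k for k, v in STRAND_CODES.items()}


class FormatError(ValueError):
    """A malformed record in an input file."""


@dataclass(frozen=True, order=True)
class JunctionRecord:
    """One splice junction with its unique-read support in one sample.

    ``intron_first``/``intron_last`` are the 1-based positions of the first
    and last intronic base.  ``strand`` is ``'+'``, ``'-'`` or ``'.'``
    (unknown).
    """

    chrom: str
    intron_first: int
    intron_last: int
    strand: str
    unique_reads: int

    def __post_init__(self):
        if self.intron_first > self.intron_last:
            raise FormatError(
                f"intron_first {self.intron_first} > intron_last {self.intron_last}"
            )
        if self.unique_reads < 0:
            raise FormatError(f"negative unique_reads: {self.unique_reads}")
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def strand_known(self) -> bool:
        return self.strand != "."


def read_junction_table(path: str | Path) -> list[JunctionRecord]:
    """Read one sample's junction table (9-column whitespace-separated).

    Columns: chrom, intron start, intron end, strand code (0 unknown / 1 + /
    2 −), motif, annotated, unique reads, multimapped reads, max overhang.
    Only the unique-read count (column 7) is kept; multimapper counts are
    deliberately ignored.  Rows with strand code 0 are retained (flagged via
    ``strand == '.'``) but are excluded downstream from strand-dependent
    analyses.
    """
    path = Path(path)
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 7:
                raise FormatError(f"{path}:{lineno}: expected >=7 columns, got {len(fields)}")
            try:
                chrom = fields[0]
                first, last = int(fields[1]), int(fields[2])
                strand = STRAND_CODES[int(fields[3])]
                unique = int(fields[6])
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if unique < 0:
                raise FormatError(f"{path}:{lineno}: negative unique-read count {unique}")
            records.append(JunctionRecord(chrom, first, last, strand, unique))
    if not records:
        log.warning("junction table %s is empty", path)
    return records


def write_junction_table(records: Iterable[JunctionRecord], path: str | Path) -> None:
    """Write records in the 9-column dialect (motif/annotated/multimap/overhang zeroed)."""
    with open(path, "w") as fh:
        for r in sorted(records):
            fh.write(
                f"{r.chrom}\t{r.intron_first}\t{r.intron_last}\t"
                f"{STRAND_TO_CODE[r.strand]}\t0\t0\t{r.unique_reads}\t0\t0\n"
            )


# ---------------------------------------------------------------------------
# Boundary counts (exon–intron boundary reads at 3' splice sites)
# ---------------------------------------------------------------------------

SiteKey = tuple[str, int, str]  # (chrom, 3'ss position, strand)


def parse_site_key(text: str) -> SiteKey:
    """Parse ``chrom:pos:strand`` into a site key."""
    try:
        chrom, pos, strand = text.rsplit(":", 2)
        pos = int(pos)
    except ValueError as exc:
        raise FormatError(f"bad site key {text!r}") from exc
    if strand not in ("+", "-", "."):
        raise FormatError(f"bad strand in site key {text!r}")
    return (chrom, pos, strand)


def format_site_key(key: SiteKey) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}"


def read_boundary_counts(path: str | Path) -> dict[tuple[str, SiteKey], int]:
    """Read the 4-column boundary-count TSV: sample, chrom:pos:strand, reads, note.

    Returns a mapping ``(sample, site_key) -> reads`` where reads counts the
    reads crossing the exon–intron boundary at that 3' splice site.
    """
    path = Path(path)
    out: dict[tuple[str, SiteKey], int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            sample = fields[0]
            key = parse_site_key(fields[1])
            try:
                reads = int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad read count {fields[2]!r}") from exc
            if reads < 0:
                raise FormatError(f"{path}:{lineno}: negative read count")
            if (sample, key) in out:
                raise FormatError(f"{path}:{lineno}: duplicate record for {sample}, {fields[1]}")
            out[(sample, key)] = reads
    return out


def write_boundary_counts(counts: dict[tuple[str, SiteKey], int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# sample\tsite(chrom:pos:strand)\treads\tnote\n")
        for (sample, key), reads in sorted(counts.items()):
            fh.write(f"{sample}\t{format_site_key(key)}\t{reads}\t.\n")


# ---------------------------------------------------------------------------
# Transcript annotation (BED12 / minimal GTF)
# ---------------------------------------------------------------------------


@dataclass
class Transcript:
    """One transcript: ordered exons on a strand, introns derived.

    ``exons`` are (start, end) 1-based inclusive intervals in ascending
    genomic order; use :meth:`exons_5p_to_3p` for transcript order.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def validate(self) -> None:
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise FormatError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        if any(s > e for s, e in ex):
            raise FormatError(f"transcript {self.transcript_id}: inverted exon interval")
        self.exons = ex

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, ascending genomic order; length >= 1."""
        ex = sorted(self.exons)
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(ex, ex[1:])]

    def exons_5p_to_3p(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return ex if self.strand == "+" else ex[::-1]

    def introns_5p_to_3p(self) -> list[tuple[int, int]]:
        iv = self.introns()
        return iv if self.strand == "+" else iv[::-1]


@dataclass
class AnnotationModel:
    """Gene models: transcripts with exons, introns derived as exon gaps."""

    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def add(self, tx: Transcript) -> None:
        tx.validate()
        self.transcripts[tx.transcript_id] = tx

    def __iter__(self):
        return iter(self.transcripts.values())

    def __len__(self):
        return len(self.transcripts)


def read_annotation(path: str | Path, fmt: str | None = None) -> AnnotationModel:
    """Read a BED12 file or a minimal GTF (exon features with transcript_id).

    ``fmt`` is ``'bed12'`` or ``'gtf'``; inferred from the suffix when None.
    BED coordinates (0-based half-open) are shifted to the internal 1-based
    inclusive convention.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "bed12"
    if fmt == "bed12":
        return _read_bed12(path)
    if fmt == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def _read_bed12(path: Path) -> AnnotationModel:
    model = AnnotationModel()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(f)}")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{lineno}: blockCount mismatch")
            exons = [
                (chrom_start + st + 1, chrom_start + st + sz)  # 0-based -> 1-based inclusive
                for st, sz in zip(starts, sizes)
            ]
            gene = name.rsplit(".", 1)[0] if "." in name else name
            model.add(Transcript(name, gene, chrom, strand, exons))
    return model


def _read_gtf(path: Path) -> AnnotationModel:
    txs: dict[str, Transcript] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: GTF needs 9 columns")
            if f[2] != "exon":
                continue
            chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            attr = _parse_gtf_attrs(attrs)
            if "transcript_id" not in attr:
                raise FormatError(f"{path}:{lineno}: exon lacks transcript_id")
            tid = attr["transcript_id"]
            gene = attr.get("gene_id", tid)
            tx = txs.setdefault(tid, Transcript(tid, gene, chrom, strand, []))
            tx.exons.append((start, end))
    model = AnnotationModel()
    for tx in txs.values():
        model.add(tx)
    return model


def _parse_gtf_attrs(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def write_bed12(model: AnnotationModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tx in sorted(model, key=lambda t: (t.chrom, min(s for s, _ in t.exons), t.transcript_id)):
            exons = sorted(tx.exons)
            chrom_start = exons[0][0] - 1  # back to 0-based
            chrom_end = exons[-1][1]
            sizes = ",".join(str(e - s + 1) for s, e in exons) + ","
            starts = ",".join(str(s - 1 - chrom_start) for s, _ in exons) + ","
            fh.write(
                f"{tx.chrom}\t{chrom_start}\t{chrom_end}\t{tx.transcript_id}\t0\t{tx.strand}\t"
                f"{chrom_start}\t{chrom_end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# Variant tables (minimal VCF subset / 5-column TSV)
# ---------------------------------------------------------------------------

EFFECT_CLASSES = {
    "synonymous",
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "splice_site",
    "other",
}

#: synonym map from common annotation vocabularies to the internal classes
EFFECT_SYNONYMS = {
    "synonymous_variant": "synonymous",
    "silent": "synonymous",
    "missense_variant": "missense",
    "nonsynonymous": "missense",
    "stop_gained": "nonsense",
    "stop_gain": "nonsense",
    "nonsense_variant": "nonsense",
    "frameshift_variant": "frameshift",
    "frame_shift": "frameshift",
    "inframe_insertion": "inframe_indel",
    "inframe_deletion": "inframe_indel",
    "in_frame_indel": "inframe_indel",
    "splice_acceptor_variant": "splice_site",
    "splice_donor_variant": "splice_site",
    "splice_region_variant": "splice_site",
}


def normalize_effect(text: str) -> str:
    """Map an effect string to one of the internal classes ('other' if unknown)."""
    t = text.strip().lower()
    if t in EFFECT_CLASSES:
        return t
    return EFFECT_SYNONYMS.get(t, "other")


@dataclass(frozen=True, order=True)
class VariantRecord:
    clone_id: str
    gene: str
    protein_change: str
    effect_class: str
    allele_frequency: float

    def __post_init__(self):
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise FormatError(
                f"allele frequency {self.allele_frequency} outside [0,1] "
                f"({self.clone_id} {self.gene} {self.protein_change})"
            )
        if self.effect_class not in EFFECT_CLASSES:
            raise FormatError(f"unknown effect class {self.effect_class!r}")


def read_variants(path: str | Path, fmt: str | None = None) -> list[VariantRecord]:
    """Read a variant table: 5-column TSV or a minimal VCF subset.

    TSV columns: clone_id, gene, protein_change, effect, allele_frequency.
    VCF records need ``AF=``, ``GENE=``, ``EFFECT=`` and optionally ``AAChange=``
    in INFO; the clone id is the (single) sample column name or a ``CLONE=``
    INFO key.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "tsv":
        return _read_variants_tsv(path)
    if fmt == "vcf":
        return _read_variants_vcf(path)
    raise ValueError(f"unknown variant format {fmt!r}")


def _read_variants_tsv(path: Path) -> list[VariantRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            try:
                af = float(f[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad allele frequency {f[4]!r}") from exc
            out.append(VariantRecord(f[0], f[1], f[2], normalize_effect(f[3]), af))
    return out


def _read_variants_vcf(path: Path) -> list[VariantRecord]:
    out = []
    sample_name = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##") or not line.strip():
                continue
            if line.startswith("#CHROM"):
                cols = line.rstrip("\n").split("\t")
                if len(cols) > 9:
                    sample_name = cols[9]
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise FormatError(f"{path}:{lineno}: VCF record needs >=8 columns")
            info = dict(
                kv.partition("=")[::2] for kv in f[7].split(";") if "=" in kv
            )
            where = f"{path}:{lineno} ({f[0]}:{f[1]})"
            if "AF" not in info:
                raise FormatError(f"{where}: record lacks AF")
            if "GENE" not in info:
                raise FormatError(f"{where}: record lacks GENE")
            clone = info.get("CLONE", sample_name)
            if clone is None:
                raise FormatError(f"{where}: no CLONE key and no sample column")
            out.append(
                VariantRecord(
                    clone,
                    info["GENE"],
                    info.get("AACHANGE", info.get("AAChange", ".")),
                    normalize_effect(info.get("EFFECT", "other")),
                    float(info["AF"]),
                )
            )
    return out


def write_variants_tsv(variants: Iterable[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# clone_id\tgene\tprotein_change\teffect\tallele_frequency\n")
        for v in sorted(variants):
            fh.write(
                f"{v.clone_id}\t{v.gene}\t{v.protein_change}\t{v.effect_class}\t"
                f"{v.allele_frequency:g}\n"
            )


def read_gene_list(path: str | Path) -> set[str]:
    """Curated gene list: one symbol per line, '#' comments allowed."""
    with open(path) as fh:
        genes = {ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")}
    return genes
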