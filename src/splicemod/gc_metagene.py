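"""Binned GC-content metagene profiles with bootstrap confidence intervals.

Retained introns and their downstream exons (and, for exon-skipping events,
the cassette exon with both flanking introns) are each rescaled to a fixed
number of bins — 100 per intron, 50 per exon — and the per-bin GC fraction
is averaged over events.  The 95% CI per bin comes from 100 bootstrap
resamples of whole intron/exon pairs.  A background profile is drawn from
random annotated intron/exon pairs passing the same length filters
(10,000 by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import AnnotationModel, SiteKey
from .psi import JunctionKey, acceptor_site

log = logging.getLogger("splicemod")

N_INTRON_BINS = 100
N_EXON_BINS = 50
MIN_INTRON_LEN = 100
MIN_EXON_LEN = 50

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def fetch_sequence(genome, chrom: str, start: int, end: int, strand: str) -> str:
    """Extract [start, end] (1-based inclusive), reverse-complemented on '-'.

    ``genome`` is any mapping of chrom → sliceable sequence (a
    ``pyfaidx.Fasta`` or a plain dict of strings).
    """
    seq = genome[chrom][start - 1 : end]
    seq = str(getattr(seq, "seq", seq)).upper()
    if strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def bin_gc(sequence: str, n_bins: int) -> np.ndarray:
    """GC fraction per bin, bins contiguous and ordered 5'→3'.

    Bin k covers [floor(k·L/n), floor((k+1)·L/n)) so bin sizes differ by at
    most one base.  N bases are excluded from both numerator and denominator;
    an all-N bin is NaN.
    """
    L = len(sequence)
    if L < n_bins:
        raise ValueError(f"sequence length {L} < n_bins {n_bins}")
    seq = sequence.upper()
    is_gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    gc_mask = (is_gc == ord("G")) | (is_gc == ord("C"))
    n_mask = is_gc == ord("N")
    bounds = (np.arange(n_bins + 1) * L) // n_bins
    out = np.empty(n_bins)
    for k in range(n_bins):
        lo, hi = bounds[k], bounds[k + 1]
        valid = hi - lo - int(n_mask[lo:hi].sum())
        out[k] = gc_mask[lo:hi].sum() / valid if valid > 0 else np.nan
    return out


@dataclass(frozen=True)
class IntronExonPair:
    """One intron/exon pair (or half of an ES triplet) with its sequences.

    Sequences are stored 5'→3' in transcript orientation.  ``role`` is one
    of IR_pair, ES_triplet_upstream, ES_triplet_downstream, background.
    """

    chrom: str
    strand: str
    intron_interval: tuple[int, int]
    exon_interval: tuple[int, int]
    intron_seq: str
    exon_seq: str
    role: str

    def bins(self, n_intron: int = N_INTRON_BINS, n_exon: int = N_EXON_BINS) -> np.ndarray:
        """Concatenated per-bin GC in transcript 5'→3' segment order.

        The downstream-intron half of an ES triplet reads exon first; every
        other role reads intron first (the exon borders the intron's 3' end).
        """
        gi = bin_gc(self.intron_seq, n_intron)
        ge = bin_gc(self.exon_seq, n_exon)
        if self.role == "ES_triplet_downstream":
            return np.concatenate([ge, gi])
        return np.concatenate([gi, ge])

    def segment_layout(self, n_intron: int = N_INTRON_BINS, n_exon: int = N_EXON_BINS):
        if self.role == "ES_triplet_downstream":
            return [("exon", n_exon), ("intron", n_intron)]
        return [("intron", n_intron), ("exon", n_exon)]


@dataclass
class GCProfile:
    """Per-bin mean GC with bootstrap 95% CI over a set of intron/exon pairs."""

    segments: list[tuple[str, int]]
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_pairs: int
    n_bootstrap: int

    def to_frame(self) -> pd.DataFrame:
        seg_names = np.concatenate(
            [np.repeat(name, n) for name, n in self.segments]
        )
        bin_idx = np.concatenate([np.arange(n) for _, n in self.segments])
        return pd.DataFrame(
            {
                "segment": seg_names,
                "bin": bin_idx,
                "mean_gc": self.mean,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "n_pairs": self.n_pairs,
            }
        )


def profile_with_bootstrap(
    pairs: Sequence[IntronExonPair],
    n_boot: int = 100,
    seed: int | np.random.Generator | None = None,
    n_intron: int = N_INTRON_BINS,
    n_exon: int = N_EXON_BINS,
) -> GCProfile:
    """Mean per-bin GC over pairs with percentile-bootstrap 95% CI.

    Bootstraps resample whole pairs (profiles) with replacement, up to the
    number of pairs; the CI is the 2.5/97.5 percentile of bootstrap means.
    """
    if not pairs:
        raise ValueError("need at least one intron/exon pair")
    layouts = {tuple(p.segment_layout(n_intron, n_exon)) for p in pairs}
    if len(layouts) > 1:
        raise ValueError("pairs with mixed segment layouts cannot share a profile")
    mat = np.vstack([p.bins(n_intron, n_exon) for p in pairs])
    return bootstrap_profile(mat, list(layouts.pop()), n_boot=n_boot, seed=seed)


def bootstrap_profile(
    matrix: np.ndarray,
    segments: list[tuple[str, int]],
    n_boot: int = 100,
    seed: int | np.random.Generator | None = None,
) -> GCProfile:
    """Percentile-bootstrap profile from a (pairs × bins) value matrix.

    Rows (whole pairs) are resampled with replacement; NaN entries are
    excluded bin-wise from every mean.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_pairs = matrix.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins -> NaN
        mean = np.nanmean(matrix, axis=0)
        boots = np.empty((n_boot, matrix.shape[1]))
        for b in range(n_boot):
            idx = rng.integers(0, n_pairs, size=n_pairs)
            boots[b] = np.nanmean(matrix[idx], axis=0)
        ci_lo, ci_hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return GCProfile(
        segments=segments,
        mean=mean,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        n_pairs=n_pairs,
        n_bootstrap=n_boot,
    )


# ---------------------------------------------------------------------------
# Foreground selection
# ---------------------------------------------------------------------------


def _qualifying_pairs_at_acceptor(
    site: SiteKey,
    annotation: AnnotationModel,
    min_intron: int,
    min_exon: int,
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All distinct (intron, downstream exon) interval pairs whose intron ends
    at the given 3' splice site and which pass the length filters."""
    found = set()
    chrom, pos, strand = site
    for tx in annotation:
        if tx.chrom != chrom or tx.strand != strand:
            continue
        introns = tx.introns_5p_to_3p()
        exons = tx.exons_5p_to_3p()
        for k, intron in enumerate(introns):
            key = (tx.chrom, intron[0], intron[1], tx.strand)
            if acceptor_site(key) != site:
                continue
            if intron[1] - intron[0] + 1 < min_intron:
                continue
            exon = exons[k + 1]  # exon at the intron's 3' end
            if exon[1] - exon[0] + 1 < min_exon:
                continue
            found.add((intron, exon))
    return sorted(found)


def select_ir_pairs(
    significant_ir_sites: Iterable[SiteKey],
    annotation: AnnotationModel,
    genome,
    seed: int | np.random.Generator | None = None,
    min_intron: int = MIN_INTRON_LEN,
    min_exon: int = MIN_EXON_LEN,
) -> list[IntronExonPair]:
    """One (intron, downstream exon) pair per significant IR 3' splice site.

    Sites whose intron is shorter than ``min_intron`` or which border no exon
    of length ≥ ``min_exon`` at the intron's 3' end are dropped (logged).
    When multiple exons qualify, one is selected at random, reproducibly
    under the supplied seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[IntronExonPair] = []
    n_dropped = 0
    for site in sorted(set(significant_ir_sites)):
        cands = _qualifying_pairs_at_acceptor(site, annotation, min_intron, min_exon)
        if not cands:
            n_dropped += 1
            log.debug("IR site %s: no qualifying intron/exon pair", site)
            continue
        intron, exon = cands[rng.integers(len(cands))]
        chrom, _, strand = site
        out.append(
            IntronExonPair(
                chrom,
                strand,
                intron,
                exon,
                fetch_sequence(genome, chrom, intron[0], intron[1], strand),
                fetch_sequence(genome, chrom, exon[0], exon[1], strand),
                "IR_pair",
            )
        )
    if n_dropped:
        log.info("select_ir_pairs: dropped %d sites without qualifying pairs", n_dropped)
    return out


def select_es_triplets(
    significant_es_junctions: Iterable[JunctionKey],
    inclusion_q: Mapping[JunctionKey, float],
    annotation: AnnotationModel,
    genome,
    q_max: float = 0.05,
    min_intron: int = MIN_INTRON_LEN,
    min_exon: int = MIN_EXON_LEN,
) -> list[tuple[IntronExonPair, IntronExonPair]]:
    """Cassette-exon triplets (upstream intron, exon) + (exon, downstream intron).

    An ES junction qualifies when it merges the outer ends of two consecutive
    annotated introns (single skipped exon — multi-exon skips are excluded),
    both introns are ≥ ``min_intron`` long and carry untreated exon-inclusion
    evidence at q < ``q_max`` (``inclusion_q`` keyed by intron junction), and
    the cassette exon is ≥ ``min_exon`` long.
    """
    wanted = set(significant_es_junctions)
    out = []
    seen = set()
    for tx in sorted(annotation, key=lambda t: t.transcript_id):
        introns = tx.introns_5p_to_3p()
        exons = tx.exons_5p_to_3p()
        for k in range(len(introns) - 1):
            up, dn = introns[k], introns[k + 1]
            lo = min(up[0], dn[0])
            hi = max(up[1], dn[1])
            skip_key = (tx.chrom, lo, hi, tx.strand)
            if skip_key not in wanted or skip_key in seen:
                continue
            cassette = exons[k + 1]
            if cassette[1] - cassette[0] + 1 < min_exon:
                log.debug("ES %s: cassette exon too short", skip_key)
                continue
            if (up[1] - up[0] + 1 < min_intron) or (dn[1] - dn[0] + 1 < min_intron):
                log.debug("ES %s: flanking intron too short", skip_key)
                continue
            up_key = (tx.chrom, up[0], up[1], tx.strand)
            dn_key = (tx.chrom, dn[0], dn[1], tx.strand)
            if not (
                inclusion_q.get(up_key, 1.0) < q_max
                and inclusion_q.get(dn_key, 1.0) < q_max
            ):
                log.debug("ES %s: missing untreated inclusion evidence", skip_key)
                continue
            seen.add(skip_key)
            exon_seq = fetch_sequence(genome, tx.chrom, cassette[0], cassette[1], tx.strand)
            pair_up = IntronExonPair(
                tx.chrom,
                tx.strand,
                up,
                cassette,
                fetch_sequence(genome, tx.chrom, up[0], up[1], tx.strand),
                exon_seq,
                "ES_triplet_upstream",
            )
            pair_dn = IntronExonPair(
                tx.chrom,
                tx.strand,
                dn,
                cassette,
                fetch_sequence(genome, tx.chrom, dn[0], dn[1], tx.strand),
                exon_seq,
                "ES_triplet_downstream",
            )
            out.append((pair_up, pair_dn))
    return out


# ---------------------------------------------------------------------------
# Background
# ---------------------------------------------------------------------------


def background_universe(
    annotation: AnnotationModel,
    min_intron: int = MIN_INTRON_LEN,
    min_exon: int = MIN_EXON_LEN,
) -> list[tuple[str, str, tuple[int, int], tuple[int, int]]]:
    """All distinct annotated (intron, downstream exon) pairs passing the
    same length filters as the IR foreground selector."""
    universe = set()
    for tx in annotation:
        introns = tx.introns_5p_to_3p()
        exons = tx.exons_5p_to_3p()
        for k, intron in enumerate(introns):
            exon = exons[k + 1]
            if intron[1] - intron[0] + 1 < min_intron:
                continue
            if exon[1] - exon[0] + 1 < min_exon:
                continue
            universe.add((tx.chrom, tx.strand, intron, exon))
    return sorted(universe)


def sample_background(
    annotation: AnnotationModel,
    genome,
    n: int = 10_000,
    seed: int | np.random.Generator | None = None,
    min_intron: int = MIN_INTRON_LEN,
    min_exon: int = MIN_EXON_LEN,
    n_boot: int = 100,
) -> GCProfile:
    """GC profile of ``n`` random annotated intron/exon pairs.

    Sampling is uniform without replacement when the qualifying universe has
    at least ``n`` pairs, otherwise with replacement (logged).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = background_universe(annotation, min_intron, min_exon)
    if not universe:
        raise ValueError("no annotated intron/exon pair passes the background filters")
    if len(universe) >= n:
        idx = rng.choice(len(universe), size=n, replace=False)
    else:
        log.warning(
            "background universe (%d pairs) smaller than n=%d; sampling with replacement",
            len(universe),
            n,
        )
        idx = rng.choice(len(universe), size=n, replace=True)
    pairs = []
    for i in idx:
        chrom, strand, intron, exon = universe[i]
        pairs.append(
            IntronExonPair(
                chrom,
                strand,
                intron,
                exon,
                fetch_sequence(genome, chrom, intron[0], intron[1], strand),
                fetch_sequence(genome, chrom, exon[0], exon[1], strand),
                "background",
            )
        )
    return profile_with_bootstrap(pairs, n_boot=n_boot, seed=rng)
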