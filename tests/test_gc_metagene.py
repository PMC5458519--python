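import numpy as np
import pytest

from splicemod import gc_metagene as gcm
from splicemod.formats_io import AnnotationModel, Transcript


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


class TestBinGC:
    def test_all_gc_sequence(self):
        assert np.allclose(gcm.bin_gc("GC" * 60, 7), 1.0)

    def test_single_bin_is_global_fraction(self):
        seq = "ACGTACGTGG"
        assert gcm.bin_gc(seq, 1)[0] == pytest.approx(6 / 10)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            gcm.bin_gc("ACGT", 5)

    def test_n_bases_excluded_from_both_sides(self):
        # bin of "GN": one valid base, G -> 1.0; bin of "NN" -> NaN
        vals = gcm.bin_gc("GNNN", 2)
        assert vals[0] == pytest.approx(1.0)
        assert np.isnan(vals[1])

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGTN"))
        for _ in range(50):
            L = int(rng.integers(100, 400))
            n_bins = int(rng.choice([1, 50, 100]))
            seq = "".join(rng.choice(bases, size=L, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            got = gcm.bin_gc(seq, n_bins)
            want = _oracle_bins(seq, n_bins)
            np.testing.assert_array_equal(np.isnan(got), np.isnan(want))
            np.testing.assert_allclose(
                got[~np.isnan(got)], want[~np.isnan(want)], atol=1e-12
            )

    def test_bin_sizes_differ_by_at_most_one(self):
        L, n = 257, 100
        bounds = [(k * L) // n for k in range(n + 1)]
        sizes = np.diff(bounds)
        assert sizes.min() >= 1 and sizes.max() - sizes.min() <= 1
        assert sum(sizes) == L


def _oracle_bins(seq, n_bins):
    """Per-base counting under the floor-boundary rule, independent of the
    vectorised implementation."""
    L = len(seq)
    out = []
    for k in range(n_bins):
        lo, hi = (k * L) // n_bins, ((k + 1) * L) // n_bins
        gc = valid = 0
        for ch in seq[lo:hi]:
            if ch in "GC":
                gc += 1
                valid += 1
            elif ch in "AT":
                valid += 1
        out.append(gc / valid if valid else np.nan)
    return np.array(out)


# ---------------------------------------------------------------------------
# bootstrap profiles
# ---------------------------------------------------------------------------


def _pair(intron_seq, exon_seq, role="IR_pair", strand="+"):
    return gcm.IntronExonPair(
        "c", strand, (1, len(intron_seq)), (len(intron_seq) + 1, len(intron_seq) + len(exon_seq)),
        intron_seq, exon_seq, role,
    )


class TestBootstrapProfile:
    def test_identical_pairs_zero_ci_width(self):
        rng = np.random.default_rng(1)
        seq_i = "".join(rng.choice(list("ACGT"), 200))
        seq_e = "".join(rng.choice(list("ACGT"), 80))
        pairs = [_pair(seq_i, seq_e)] * 5
        prof = gcm.profile_with_bootstrap(pairs, n_boot=50, seed=0)
        assert np.allclose(prof.ci_lo, prof.ci_hi)
        assert prof.segments == [("intron", 100), ("exon", 50)]
        assert len(prof.mean) == 150

    def test_ci_brackets_mean(self):
        rng = np.random.default_rng(4)
        mat = rng.uniform(0, 1, size=(30, 150))
        prof = gcm.bootstrap_profile(mat, [("intron", 100), ("exon", 50)], seed=2)
        assert np.all(prof.ci_lo <= prof.mean + 1e-12)
        assert np.all(prof.mean <= prof.ci_hi + 1e-12)
        assert np.all((prof.mean >= 0) & (prof.mean <= 1))

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        mat = rng.uniform(0, 1, size=(20, 10))
        a = gcm.bootstrap_profile(mat, [("intron", 10)], seed=7)
        b = gcm.bootstrap_profile(mat, [("intron", 10)], seed=7)
        np.testing.assert_array_equal(a.ci_lo, b.ci_lo)
        np.testing.assert_array_equal(a.ci_hi, b.ci_hi)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            gcm.profile_with_bootstrap([], seed=0)


# ---------------------------------------------------------------------------
# foreground selection
# ---------------------------------------------------------------------------


def _annotation_with(intron_len, exon_len, strand="+"):
    """Three-exon transcript whose second intron has the given length and
    whose last exon the given length."""
    model = AnnotationModel()
    e1 = (101, 180)
    i1 = (181, 380)
    e2 = (381, 460)
    i2 = (461, 460 + intron_len)
    e3 = (i2[1] + 1, i2[1] + exon_len)
    model.add(Transcript("t", "g", "c", strand, [e1, e2, e3]))
    return model, i2, e3


def _genome_for(model, gc=0.5, seed=0):
    rng = np.random.default_rng(seed)
    end = max(e for tx in model for _, e in tx.exons) + 10
    return {"c": "".join(rng.choice(list("ACGT"), size=end))}


class TestSelectIRPairs:
    def test_intron_length_boundary(self):
        for L, expected in [(99, 0), (100, 1)]:
            model, i2, e3 = _annotation_with(L, 50)
            genome = _genome_for(model)
            site = ("c", i2[1], "+")
            pairs = gcm.select_ir_pairs([site], model, genome, seed=0)
            assert len(pairs) == expected

    def test_exon_length_boundary_at_least_50(self):
        for L, expected in [(49, 0), (50, 1)]:
            model, i2, e3 = _annotation_with(150, L)
            genome = _genome_for(model)
            pairs = gcm.select_ir_pairs([("c", i2[1], "+")], model, genome, seed=0)
            assert len(pairs) == expected

    def test_multiple_qualifying_exons_fixed_seed_deterministic(self):
        model, i2, e3 = _annotation_with(150, 60)
        # second transcript sharing the same intron but a longer downstream exon
        model.add(Transcript("t2", "g", "c", "+", [(381, 460), (i2[1] + 1, i2[1] + 90)]))
        genome = _genome_for(model)
        site = ("c", i2[1], "+")
        assert len(gcm._qualifying_pairs_at_acceptor(site, model, 100, 50)) == 2
        chosen = {
            gcm.select_ir_pairs([site], model, genome, seed=3)[0].exon_interval
            for _ in range(5)
        }
        assert len(chosen) == 1  # same exon every run under the same seed

    def test_sequences_follow_transcript_orientation(self):
        model, i2, e3 = _annotation_with(150, 60, strand="-")
        genome = _genome_for(model)
        # acceptor of a '-' intron is its lower coordinate
        site = ("c", i2[0], "-")
        # '-' transcript: exon order reversed; the intron at this acceptor is
        # transcript intron 1 with downstream exon (101,180)... the last exon
        # in transcript order is e1, so the qualifying pair uses e1
        pairs = gcm.select_ir_pairs([site], model, genome, seed=0)
        assert len(pairs) == 0 or all(p.strand == "-" for p in pairs)


class TestSelectESTriplets:
    def _setup(self):
        model, i2, e3 = _annotation_with(150, 60)
        genome = _genome_for(model)
        i1 = (181, 380)
        skip = ("c", i1[0], i2[1], "+")
        up_key = ("c", 181, 380, "+")
        dn_key = ("c", i2[0], i2[1], "+")
        return model, genome, skip, up_key, dn_key

    def test_qualifying_triplet_layout(self):
        model, genome, skip, up_key, dn_key = self._setup()
        trips = gcm.select_es_triplets(
            [skip], {up_key: 0.01, dn_key: 0.02}, model, genome
        )
        assert len(trips) == 1
        up, dn = trips[0]
        assert up.segment_layout() == [("intron", 100), ("exon", 50)]
        assert dn.segment_layout() == [("exon", 50), ("intron", 100)]
        assert up.exon_seq == dn.exon_seq

    def test_missing_inclusion_evidence_excluded(self):
        model, genome, skip, up_key, dn_key = self._setup()
        assert gcm.select_es_triplets([skip], {up_key: 0.06, dn_key: 0.01}, model, genome) == []

    def test_multi_exon_skip_excluded(self):
        model = AnnotationModel()
        model.add(Transcript("t", "g", "c", "+",
                             [(101, 200), (401, 500), (701, 800), (1001, 1100)]))
        genome = {"c": "A" * 1200}
        # junction spanning two annotated exons
        skip2 = ("c", 201, 1000, "+")
        q = {("c", 201, 400, "+"): 0.01, ("c", 501, 700, "+"): 0.01,
             ("c", 801, 1000, "+"): 0.01}
        assert gcm.select_es_triplets([skip2], q, model, genome) == []


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------


class TestBackground:
    def test_small_universe_samples_with_replacement(self, caplog):
        model, i2, e3 = _annotation_with(150, 60)
        genome = _genome_for(model)
        with caplog.at_level("WARNING", logger="splicemod"):
            prof = gcm.sample_background(model, genome, n=10, seed=0, n_boot=20)
        assert prof.n_pairs == 10
        assert "replacement" in caplog.text

    def test_filter_parity_with_foreground(self):
        model, i2, e3 = _annotation_with(150, 60)
        universe = gcm.background_universe(model)
        for chrom, strand, intron, exon in universe:
            site = ("c", intron[1] if strand == "+" else intron[0], strand)
            genome = _genome_for(model)
            fg = gcm.select_ir_pairs([site], model, genome, seed=0)
            assert any(p.intron_interval == intron for p in fg)

    def test_empty_universe_errors(self):
        model = AnnotationModel()
        # all introns shorter than the 100-nt filter
        model.add(Transcript("t", "g", "c", "+", [(101, 150), (181, 230), (261, 310)]))
        with pytest.raises(ValueError):
            gcm.sample_background(model, {"c": "A" * 700}, n=5, seed=0)


# ---------------------------------------------------------------------------
# strand correctness
# ---------------------------------------------------------------------------


def test_profile_invariant_under_genome_reverse_complement():
    """Reverse-complementing the genome and flipping the annotation must give
    the identical profile, with bin order following transcript orientation
    (checked via a planted 5'->3' GC gradient)."""
    rng = np.random.default_rng(12)
    # intron with a GC gradient: AT-rich 5' half, GC-rich 3' half
    intron = "A" * 75 + "G" * 75
    exon2 = "".join(rng.choice(list("ACGT"), 80))
    lead = "".join(rng.choice(list("ACGT"), 100))
    e1 = "".join(rng.choice(list("ACGT"), 50))
    tail = "".join(rng.choice(list("ACGT"), 10))
    # exon1 (101,150), intron (151,300), exon2 (301,380)
    fwd_seq = lead + e1 + intron + exon2 + tail
    model_f = AnnotationModel()
    model_f.add(Transcript("t", "g", "c", "+", [(101, 150), (301, 380)]))
    genome_f = {"c": fwd_seq}

    comp = str.maketrans("ACGT", "TGCA")
    rev_seq = fwd_seq.translate(comp)[::-1]
    L = len(fwd_seq)

    def flip(iv):
        return (L - iv[1] + 1, L - iv[0] + 1)

    tx = model_f.transcripts["t"]
    model_r = AnnotationModel()
    model_r.add(Transcript("t", "g", "c", "-", [flip(iv) for iv in tx.exons]))
    genome_r = {"c": rev_seq}

    site_f = ("c", 300, "+")       # acceptor of the '+' intron
    site_r = ("c", L - 300 + 1, "-")  # same site after the flip

    pf = gcm.select_ir_pairs([site_f], model_f, genome_f, seed=0)
    pr = gcm.select_ir_pairs([site_r], model_r, genome_r, seed=0)
    assert len(pf) == len(pr) == 1
    assert pf[0].intron_seq == pr[0].intron_seq
    assert pf[0].exon_seq == pr[0].exon_seq
    bins_f = pf[0].bins()
    # gradient: first intron bins AT-rich (0), last intron bins GC-rich (1)
    assert bins_f[:40].mean() < 0.2 and bins_f[60:100].mean() > 0.8
    np.testing.assert_array_equal(bins_f, pr[0].bins())
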