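"""Structural-anatomy contracts: TSDs, terminal repeats, nested
decomposition, PBS/PPT, LTR motifs and partition, solo LTRs, dotplots,
pairwise identity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retronest import anatomy
from retronest import synthetic_data as sd
from retronest.core_io import GenomicInterval, SequenceRecord


def _allele_with_tsd(seed, tsd, host_len=400, el_len=120):
    rng = np.random.default_rng(seed)
    host = SequenceRecord("h", sd.random_seq(host_len, rng))
    pos = host_len // 2
    host = SequenceRecord("h", host.seq[:pos - len(tsd)] + tsd + host.seq[pos:])
    element = SequenceRecord("e", sd.random_seq(el_len, rng))
    truth = sd.insert_with_tsd(host, element, pos=pos, tsd_len=len(tsd))
    return truth


class TestDetectTsd:
    def test_planted_tsd_recovered_exactly(self):
        truth = _allele_with_tsd(1, "CATTGC")
        report = anatomy.detect_tsd(truth.sequence, truth.feature("element").interval)
        assert report.length == 6 and report.sequence == "CATTGC"
        assert report.left_interval.end == truth.feature("element").interval.start
        assert report.right_interval.start == truth.feature("element").interval.end

    def test_zero_length_tsd(self):
        # boundaries engineered so no flanking duplication exists at all
        allele = SequenceRecord("a", "C" * 50 + "A" * 60 + "G" * 50)
        report = anatomy.detect_tsd(allele, GenomicInterval("a", 50, 110))
        assert report.length == 0 and report.sequence == ""

    def test_insufficient_flank_errors(self):
        allele = SequenceRecord("a", "ACGT" * 30)
        with pytest.raises(ValueError, match="flank"):
            anatomy.detect_tsd(allele, GenomicInterval("a", 5, 100))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(0, 12))
    def test_maximality_against_brute_force(self, seed, k):
        rng = np.random.default_rng(seed)
        tsd = sd.random_seq(k, rng)
        truth = _allele_with_tsd(seed + 1, tsd)
        iv = truth.feature("element").interval
        report = anatomy.detect_tsd(truth.sequence, iv)
        # brute-force oracle: largest k with equal flanking k-mers
        s = truth.sequence.seq
        expected = max(
            (kk for kk in range(0, 26)
             if s[iv.start - kk:iv.start] == s[iv.end:iv.end + kk]),
            default=0,
        )
        assert report.length == expected >= k  # >= planted (chance extension ok)


class TestTerminalRepeats:
    def test_identical_ltrs_full_length_identity_one(self, replica):
        rep = anatomy.detect_terminal_repeats(replica.beta4)
        assert rep.length == 522 and rep.identity == 1.0
        assert rep.five_prime.start == 0 and rep.three_prime.end == 9344

    def test_diverged_ltrs(self):
        spec = sd.ElementSpec(
            ltr_length=300, internal_length=1400, polyA_offset=150,
            tata_offset=250, tss_offset=258, term_offset=280,
            orf_plan=(), ltr_divergence=0.02)
        rec, _ = sd.build_element(spec, seed=5)
        rep = anatomy.detect_terminal_repeats(rec)
        assert rep.length == 300
        assert 0.94 <= rep.identity < 1.0

    def test_random_sequence_has_no_repeat(self):
        for seed in (1, 2, 3):
            rec = SequenceRecord("r", sd.random_seq(1000, np.random.default_rng(seed)))
            assert anatomy.detect_terminal_repeats(rec) is None

    def test_short_element_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            anatomy.detect_terminal_repeats(SequenceRecord("s", "ACGT" * 10))


class TestDecomposeNested:
    def test_synthetic_nest_exact_recovery(self):
        # host ~2 kb, inner 1 kb with 120-bp LTRs, 4-8 bp TSD
        spec = sd.ElementSpec(
            ltr_length=120, internal_length=760, polyA_offset=30,
            tata_offset=80, tss_offset=88, term_offset=100, orf_plan=())
        host, inner, truth = sd.build_nested_allele(7, host_len=2000, spec=spec)
        results = anatomy.decompose_nested(truth.sequence, annotate_inner=False)
        assert len(results) == 1
        n = results[0]
        assert n.inner_element.seq == inner.seq
        assert n.host_reconstructed.seq == host.seq
        assert n.insertion_pos_in_host == truth.insertion_pos_in_host
        assert n.tsd.sequence == truth.tsd

    def test_no_inner_repeat_structure_is_absent(self):
        rec = SequenceRecord("r", sd.random_seq(3000, np.random.default_rng(8)))
        assert anatomy.decompose_nested(rec) == []

    def test_length_conservation_invariant(self, replica):
        n = anatomy.decompose_nested(replica.composite, annotate_inner=False)[0]
        assert (len(replica.composite)
                == len(n.host_reconstructed) + len(n.inner_element) + n.tsd.length)

    def test_excision_identity_over_seeded_replicates(self):
        spec = sd.ElementSpec(
            ltr_length=150, internal_length=900, polyA_offset=40,
            tata_offset=100, tss_offset=108, term_offset=120, orf_plan=())
        exact = 0
        n_reps = 20
        for seed in range(n_reps):
            host, inner, truth = sd.build_nested_allele(
                1000 + seed, host_len=2500, spec=spec)
            res = anatomy.decompose_nested(truth.sequence, annotate_inner=False)
            if (len(res) == 1 and res[0].host_reconstructed.seq == host.seq
                    and res[0].inner_element.seq == inner.seq
                    and res[0].insertion_pos_in_host == truth.insertion_pos_in_host
                    and res[0].tsd.sequence == truth.tsd):
                exact += 1
        assert exact == n_reps


class TestPbsPpt:
    def test_planted_pbs_zero_mismatches(self, replica):
        rep = anatomy.detect_terminal_repeats(replica.beta4)
        hit = anatomy.find_pbs(replica.beta4, rep, replica.trnas)
        assert hit.matched_trna_id == "tRNA-Lys" and hit.mismatches == 0
        assert hit.interval.start == 522 + sd.BETA4_SPEC.pbs_gap

    def test_no_pbs_returns_absent(self):
        rng = np.random.default_rng(9)
        # element with terminal repeats but a scrambled PBS region
        ltr = sd.random_seq(100, rng)
        rec = SequenceRecord("e", ltr + sd.random_seq(400, rng) + ltr)
        rep = anatomy.detect_terminal_repeats(rec)
        assert rep is not None
        assert anatomy.find_pbs(rec, rep, sd.SYNTHETIC_TRNA_PANEL, max_mismatch=0) is None

    def test_empty_trna_set_errors(self, replica):
        rep = anatomy.detect_terminal_repeats(replica.beta4)
        with pytest.raises(ValueError, match="empty tRNA"):
            anatomy.find_pbs(replica.beta4, rep, [])

    def test_planted_ppt_length_and_fraction(self, replica):
        rep = anatomy.detect_terminal_repeats(replica.beta4)
        hit = anatomy.find_ppt(replica.beta4, rep)
        assert hit.interval.length == 12 and hit.purine_fraction == 1.0
        assert hit.interval.end == rep.three_prime.start  # gap 0

    def test_pyrimidine_region_absent_and_strict_threshold(self):
        rng = np.random.default_rng(10)
        ltr = sd.random_seq(80, rng)
        body = "CT" * 200
        rec = SequenceRecord("e", ltr + body + ltr)
        rep = anatomy.detect_terminal_repeats(rec)
        assert anatomy.find_ppt(rec, rep) is None
        # 11 purines with one pyrimidine in the middle fails min_purine=1.0
        body2 = "C" * 380 + "AAAAAGCAAAAA"[:12]
        rec2 = SequenceRecord("e2", ltr + body2 + ltr)
        rep2 = anatomy.detect_terminal_repeats(rec2)
        assert anatomy.find_ppt(rec2, rep2, min_purine=1.0, min_len=12) is None


class TestLtrMotifsAndPartition:
    def test_replica_ltr_motifs_at_reference_offsets(self, replica):
        ltr = replica.beta4.slice(0, 522, "LTR5")
        scan = anatomy.scan_ltr_motifs(ltr)
        assert scan.polyA_site == 328 and scan.tata_site == 396

    def test_no_motifs_in_homopolymer(self):
        scan = anatomy.scan_ltr_motifs(SequenceRecord("c", "C" * 200))
        assert scan.polyA_site is None and scan.tata_site is None
        assert scan.polyA_sites == () and scan.tata_sites == ()

    def test_planted_pair_at_100_and_300(self):
        s = list("C" * 400)
        s[99:105] = "AATAAA"
        s[299:305] = "TATATA"  # TATAWA with W = T
        scan = anatomy.scan_ltr_motifs(SequenceRecord("l", "".join(s)))
        assert (scan.polyA_site, scan.tata_site) == (100, 300)

    def test_partition_matches_reference_u3_r_u5(self):
        part = anatomy.partition_ltr(522, tss_pos=404, term_pos=425)
        assert part.u3.one_based() == (1, 403)
        assert part.r.one_based() == (404, 425)
        assert part.u5.one_based() == (426, 522)

    def test_all_r_partition(self):
        part = anatomy.partition_ltr(100, tss_pos=1, term_pos=100)
        assert part.u3 is None and part.u5 is None
        assert part.r.one_based() == (1, 100)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_partition_tiling_property(self, data):
        length = data.draw(st.integers(10, 2000))
        tss = data.draw(st.integers(1, length))
        term = data.draw(st.integers(tss, length))
        part = anatomy.partition_ltr(length, tss, term)
        total = sum(iv.length for iv in (part.u3, part.r, part.u5) if iv is not None)
        assert total == length

    def test_partition_ordering_errors(self):
        with pytest.raises(ValueError):
            anatomy.partition_ltr(100, tss_pos=50, term_pos=40)


class TestSoloLtr:
    def test_product_length_equals_ltr_length(self, replica):
        ann = anatomy.annotate_element(replica.beta4, trnas=replica.trnas)
        product = anatomy.predict_solo_ltr(replica.beta4, ann)
        assert len(product) == 522
        assert product.seq == replica.beta4.seq[:522]

    def test_idempotence_product_reclassifies_solo(self, replica):
        ann = anatomy.annotate_element(replica.beta4, trnas=replica.trnas)
        product = anatomy.predict_solo_ltr(replica.beta4, ann)
        again = anatomy.annotate_element(product)
        assert again.classification == "solo_ltr"
        with pytest.raises(ValueError, match="already a solo"):
            anatomy.predict_solo_ltr(product, again)

    def test_diverged_ltrs_refused(self):
        spec = sd.ElementSpec(
            ltr_length=300, internal_length=2500, polyA_offset=150,
            tata_offset=250, tss_offset=258, term_offset=280,
            orf_plan=(("gag", 120), ("pro", 110), ("pol", 130), ("env", 140)),
            ltr_divergence=0.10)
        rec, _ = sd.build_element(spec, seed=12)
        ann = anatomy.annotate_element(rec, min_orf_aa=100)
        assert ann.classification == "full_length_provirus"
        with pytest.raises(ValueError, match="manual review"):
            anatomy.predict_solo_ltr(rec, ann, min_identity=0.95)


class TestDotplotAndIdentity:
    def test_self_comparison_has_full_diagonal(self):
        rec = SequenceRecord("s", sd.random_seq(200, np.random.default_rng(13)))
        points = anatomy.dotplot(rec, rec)
        diag = {(x, y) for x, y, o in points if o == "+" and x == y}
        assert diag == {(i, i) for i in range(200 - 12 + 1)}

    def test_terminal_repeats_appear_off_diagonal(self, replica):
        points = anatomy.dotplot(replica.beta4, replica.beta4)
        corner = [(x, y) for x, y, o in points
                  if o == "+" and y - x == 9344 - 522 and x < 522]
        assert len(corner) == 522 - 12 + 1

    def test_reverse_complement_antidiagonal_only(self):
        rec = SequenceRecord("s", sd.random_seq(150, np.random.default_rng(14)))
        rc = rec.reverse_complement()
        points = anatomy.dotplot(rec, rc)
        assert points and all(o == "-" for _, _, o in points)
        # a word at x in rec equals the revcomp of the rc word starting at
        # the mirrored position: y = len - word - x
        assert all(y == len(rec) - 12 - x for x, y, _ in points)

    def test_dotplot_symmetry_transpose(self):
        rng = np.random.default_rng(15)
        a = SequenceRecord("a", sd.random_seq(300, rng))
        b = SequenceRecord("b", sd.random_seq(300, rng) + a.seq[50:120])
        ab = {(x, y, o) for x, y, o in anatomy.dotplot(a, b)}
        ba = {(y, x, o) for x, y, o in anatomy.dotplot(b, a)}
        assert ab == ba

    def test_pairwise_identity_hand_checkable(self):
        a = SequenceRecord("a", "ACGT")
        b = SequenceRecord("b", "ACGA")
        assert anatomy.pairwise_identity(a, b, mode="global") == 75.0
        assert anatomy.pairwise_identity(a, a) == 100.0

    def test_identity_matches_planted_substitution_count(self):
        rng = np.random.default_rng(16)
        a = SequenceRecord("a", sd.random_seq(4000, rng))
        b = sd.mutate_seq(a, 0.05, seed=17)
        diffs = sum(1 for x, y in zip(a.seq, b.seq) if x != y)
        expected = 100.0 * (len(a) - diffs) / len(a)
        assert anatomy.pairwise_identity(a, b, mode="ungapped") == pytest.approx(expected)
        # no indels planted, so the global alignment gives the same value
        assert anatomy.pairwise_identity(a, b, mode="global") == pytest.approx(expected)
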