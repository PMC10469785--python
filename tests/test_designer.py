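import numpy as np
import pytest

import oracles
from blockprime.core_seq import DesignRules, NucSequence, PrimerOligo, gc_fraction, revcomp
from blockprime.designer import (
    RULE_HOST_UNIQUE,
    RULE_LENGTH,
    RULE_NO_FOOTPRINT_OVERLAP,
    RULE_OFFTARGET,
    CandidateWindow,
    design,
    emit_blocking_primers,
    enumerate_candidates,
    host_uniqueness,
    rank_candidates,
    specificity_screen,
    validate_blocking_primer,
    write_candidate_tsv,
)
from blockprime.insilico_pcr import extract_amplicon
from conftest import random_dna


def window(seq, start=0, strand="+", host_id="h", min_mm=None, gc=None, status="enumerated"):
    end = start + len(seq)
    return CandidateWindow(
        host_id=host_id,
        start=start,
        end=end,
        strand=strand,
        seq=NucSequence(f"{host_id}:{start}-{end}({strand})", seq),
        gc_fraction=gc if gc is not None else gc_fraction(seq),
        min_offtarget_mismatches=min_mm,
        status=status,
    )


class TestEnumerate:
    def test_window_count_on_short_interior(self, host, oligos):
        # interior of 25 nt admits sum_{L=20..25}(25-L+1) = 21 windows
        # per orientation
        amp = extract_amplicon(host, oligos["1389F"], oligos["1015R"])
        rules = DesignRules(min_len=20, max_len=25)
        sub = host  # restrict via a fake amplicon interior of 25 nt
        from blockprime.insilico_pcr import AmpliconMap, BindingSite

        fwd_fp = BindingSite(host.id, amp.interior_start - 15, amp.interior_start, "+", 0, "f")
        rev_fp = BindingSite(host.id, amp.interior_start + 25, amp.interior_start + 45, "-", 0, "r")
        small = AmpliconMap(host.id, fwd_fp.start, rev_fp.end, fwd_fp, rev_fp)
        cands = enumerate_candidates(small, sub, rules)
        plus = [c for c in cands if c.strand == "+"]
        assert len(plus) == 21
        assert len(cands) == 42  # both orientations

    def test_interior_shorter_than_min_len_yields_empty(self, host, oligos):
        from blockprime.insilico_pcr import AmpliconMap, BindingSite

        fwd_fp = BindingSite(host.id, 100, 115, "+", 0, "f")
        rev_fp = BindingSite(host.id, 134, 154, "-", 0, "r")  # interior 19 nt
        amp = AmpliconMap(host.id, 100, 154, fwd_fp, rev_fp)
        assert enumerate_candidates(amp, host, DesignRules(min_len=20)) == []

    def test_windows_respect_interior_bounds_and_footprints(self, host, offtargets, oligos):
        amp = extract_amplicon(host, oligos["1389F"], oligos["1015R"])
        cands = enumerate_candidates(amp, host, DesignRules())
        assert cands
        for c in cands:
            assert amp.interior_start <= c.start < c.end <= amp.interior_end
            assert 20 <= c.length <= 30
        # the boundary window ending exactly at interior_end exists
        assert any(c.end == amp.interior_end for c in cands)

    def test_minus_strand_oligo_is_revcomp_of_plus(self, host, oligos):
        amp = extract_amplicon(host, oligos["1389F"], oligos["1015R"])
        cands = enumerate_candidates(amp, host, DesignRules())
        by_key = {(c.start, c.end, c.strand): c for c in cands}
        plus = by_key[(amp.interior_start, amp.interior_start + 20, "+")]
        minus = by_key[(amp.interior_start, amp.interior_start + 20, "-")]
        assert minus.seq.seq == str(revcomp(plus.seq.seq))

    def test_raising_min_len_never_grows_enumeration(self, host, oligos):
        amp = extract_amplicon(host, oligos["1389F"], oligos["1015R"])
        sizes = [
            len(enumerate_candidates(amp, host, DesignRules(min_len=m)))
            for m in (20, 22, 25, 30)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestHostUniqueness:
    def test_single_locus(self):
        rng = np.random.default_rng(3)
        h = NucSequence("h", random_dna(rng, 300))
        c = window(h.seq[50:72], start=50)
        assert host_uniqueness(c, h) == 1

    def test_tandem_duplication_counts_twice(self):
        rng = np.random.default_rng(4)
        unit = random_dna(rng, 60)
        h = NucSequence("h", unit + unit)
        c = window(unit[10:34], start=10)
        assert host_uniqueness(c, h) == 2

    def test_palindrome_counts_intervals_not_strand_hits(self):
        rng = np.random.default_rng(5)
        half = random_dna(rng, 12)
        pal = half + str(revcomp(half))  # reverse-complement palindrome
        h = NucSequence("h", random_dna(rng, 40) + pal + random_dna(rng, 40))
        c = window(pal, start=40)
        # both strands hit the same plus-strand interval -> one locus
        assert host_uniqueness(c, h) == 1


class TestSpecificityScreen:
    def test_identical_offtarget_scores_zero(self):
        c = window("ACGTACGTACGTACGTACGT")
        res = specificity_screen(c, [NucSequence("ot", c.seq.seq)])
        assert res.min_mismatches == 0

    def test_constructed_three_mismatch_offtarget(self):
        rng = np.random.default_rng(6)
        cand_seq = random_dna(rng, 24)
        mutated = list(cand_seq)
        for p in (3, 11, 19):
            mutated[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[p]]
        ot = NucSequence("ot", random_dna(rng, 150) + "".join(mutated) + random_dna(rng, 150))
        c = window(cand_seq)
        res = specificity_screen(c, [ot])
        assert res.min_mismatches == oracles.screen_min(cand_seq, ot.seq) == 3

    def test_short_offtarget_penalizes_uncovered_positions(self):
        c = window("A" * 30)
        ot = NucSequence("ot", "A" * 10)  # 20 uncovered candidate positions
        res = specificity_screen(c, [ot])
        assert res.min_mismatches == 20

    def test_empty_library_is_explicitly_unscreened(self):
        res = specificity_screen(window("ACGTACGTACGTACGTACGT"), [])
        assert res.unscreened and res.min_mismatches is None

    def test_reverse_strand_match_detected(self):
        rng = np.random.default_rng(7)
        cand_seq = random_dna(rng, 22)
        ot = NucSequence("ot", random_dna(rng, 90) + str(revcomp(cand_seq)) + random_dna(rng, 90))
        res = specificity_screen(window(cand_seq), [ot])
        assert res.min_mismatches == 0
        assert res.hits[0].strand == "-"

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        cand_seq = random_dna(rng, int(rng.integers(15, 61)))
        subjects = [
            NucSequence(f"s{i}", random_dna(rng, int(rng.integers(5, 500))))
            for i in range(3)
        ]
        res = specificity_screen(window(cand_seq), subjects)
        for hit, subj in zip(res.hits, subjects):
            assert hit.mismatches == oracles.screen_min(cand_seq, subj.seq)
        assert res.min_mismatches == min(h.mismatches for h in res.hits)


class TestRanking:
    def test_primary_key_is_offtarget_distance(self):
        a, b = window("A" * 20, min_mm=5), window("C" * 20, min_mm=3)
        assert rank_candidates([b, a])[0] is a

    def test_tie_preserves_input_order(self):
        a = window("ACGT" * 5, start=10, min_mm=4)
        b = window("ACGT" * 5, start=10, strand="-", min_mm=4)
        assert rank_candidates([a, b]) == [a, b]
        assert rank_candidates([b, a]) == [b, a]

    def test_full_hand_computed_order(self):
        # keys: mm desc, |gc-0.5| asc, length asc, start asc
        c1 = window("A" * 20, start=5, min_mm=4, gc=0.50)
        c2 = window("A" * 20, start=2, min_mm=4, gc=0.30)
        c3 = window("A" * 24, start=0, min_mm=4, gc=0.50)
        c4 = window("A" * 20, start=9, min_mm=6, gc=0.10)
        assert rank_candidates([c1, c2, c3, c4]) == [c4, c1, c3, c2]


class TestEmit:
    def ranked(self, n_accepted):
        out = []
        for i in range(n_accepted):
            c = window("ACGTACGTACGTACGTACGT", start=i, min_mm=5, status="accepted")
            out.append(c)
        return out

    def test_top_k_converted_with_c3_spacer(self):
        blockers = emit_blocking_primers(self.ranked(5), k=2)
        assert len(blockers) == 2
        for b in blockers:
            assert b.role == "blocking" and b.terminator == "C3_spacer"
            assert b.display().endswith("[SpcC3]")

    def test_fewer_than_k_returns_all_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            blockers = emit_blocking_primers(self.ranked(1), k=2)
        assert len(blockers) == 1
        assert "1 accepted" in caplog.text

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            emit_blocking_primers([], k=0)


class TestValidate:
    def test_printed_blocking_primers_pass_length_rule(self, oligos):
        for name, n in (("BP-F_Hi_V9", 23), ("BP-R_Hi_V9", 22)):
            oligo = oligos[name]
            assert len(oligo.gene_specific) == n
            report = validate_blocking_primer(oligo, None, None, [])
            check = report.check(RULE_LENGTH)
            assert check.passed is True
            assert not report.failed

    def test_footprint_overlap_fails(self, host, oligos):
        amp = extract_amplicon(host, oligos["1389F"], oligos["1015R"])
        # window overlapping the forward footprint by exactly 1 nt
        s = amp.interior_start - 1
        seq = host.seq[s : s + 22]
        oligo = PrimerOligo("bad", NucSequence("bad", seq), role="blocking", terminator="C3_spacer")
        report = validate_blocking_primer(oligo, amp, host, [])
        assert report.check(RULE_NO_FOOTPRINT_OVERLAP).passed is False
        assert report.failed

    def test_unmapped_oligo_reports_no_host_locus(self, host, oligos):
        amp = extract_amplicon(host, oligos["1389F"], oligos["1015R"])
        report = validate_blocking_primer(oligos["BP-F_Hi_V9"], amp, host, [])
        assert report.check("host_locus").passed is False
        assert "no host locus" in report.check("host_locus").detail

    def test_accepted_designs_revalidate_clean(self, host, offtargets, design_result):
        # closure property: everything the designer accepts passes the
        # validator on the same inputs
        amp = design_result.amplicon
        for cand in design_result.accepted[:25]:
            oligo = PrimerOligo(
                cand.id, cand.seq, role="blocking", terminator="C3_spacer"
            )
            report = validate_blocking_primer(oligo, amp, host, offtargets)
            assert not report.failed, report.to_text()

    def test_non_unique_oligo_fails_host_unique(self, oligos):
        rng = np.random.default_rng(8)
        fwd, rev = oligos["1389F"], oligos["1015R"]
        unit = random_dna(rng, 40)
        interior = unit + unit  # duplicated blocker locus inside the interior
        seq = (
            random_dna(rng, 20)
            + fwd.gene_specific.seq
            + interior
            + str(revcomp(rev.gene_specific.seq.replace("Y", "T")))
            + random_dna(rng, 20)
        )
        h = NucSequence("h", seq)
        amp = extract_amplicon(h, fwd, rev)
        oligo = PrimerOligo("dup", NucSequence("dup", unit[:22]), role="blocking", terminator="C3_spacer")
        report = validate_blocking_primer(oligo, amp, h, [])
        assert report.check(RULE_HOST_UNIQUE).passed is False


class TestDesignPipeline:
    def test_raising_threshold_shrinks_accepted_set(self, host, offtargets, oligos):
        fwd, rev = oligos["1389F"], oligos["1015R"]
        accepted = [
            {c.id for c in design(host, fwd, rev, offtargets, DesignRules(min_offtarget_mismatches=t)).accepted}
            for t in (3, 4, 5)
        ]
        assert accepted[2] <= accepted[1] <= accepted[0]

    def test_unscreened_candidates_never_accepted(self, host, oligos):
        res = design(host, oligos["1389F"], oligos["1015R"], offtargets=[])
        assert res.accepted == []
        assert all("specificity_unscreened" in c.reject_reasons for c in res.candidates)

    def test_rejections_carry_reasons(self, design_result):
        for c in design_result.candidates:
            if c.status == "rejected":
                assert c.reject_reasons
            else:
                assert c.reject_reasons == []
                assert c.host_copy_count == 1
                assert c.min_offtarget_mismatches >= 3

    def test_candidate_tsv_is_deterministic(self, design_result, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_candidate_tsv(design_result.candidates, p1)
        write_candidate_tsv(design_result.candidates, p2)
        assert p1.read_bytes() == p2.read_bytes()
        header = p1.read_text().splitlines()
        assert header[0].startswith("#")  # ranking flagged as tool convention
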