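"""ORF finding, redundancy clustering, consensus merge and the SSR scan."""

import re

import numpy as np
import pytest
from Bio.Seq import Seq

from coexflow.seqprep import (
    DEFAULT_MIN_REPEATS,
    TranscriptRecord,
    alignment_identity_coverage,
    canonical_rotation,
    cluster_redundant,
    consensus_merge,
    find_orfs,
    scan_ssr,
)


def rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def orf_free(rng, n):
    """Random sequence without ATG on either strand (so no incidental ORFs)."""
    while True:
        s = rand_seq(rng, n)
        if "ATG" not in s and "CAT" not in s:
            return s


class TestFindOrfs:
    def test_single_planted_orf_found_with_exact_span(self):
        rng = np.random.default_rng(0)
        body = "".join(
            c for c in ["GGC", "CTC", "TCC", "GGA"] * 24
        )  # 288 nt, no ATG/stop in frame
        seq = "CC" + "ATG" + body + "TAA" + "GG"
        rec = TranscriptRecord("x", seq)
        orfs = find_orfs(rec, min_orf_nt=294)
        plus = [o for o in orfs if o.strand == "+"]
        assert len(plus) == 1
        o = plus[0]
        assert (o.start, o.end) == (2, 2 + 294)
        assert o.length == 294
        assert rec.longest_orf is not None

    def test_sequence_without_atg_has_no_orfs(self):
        rec = TranscriptRecord("x", "CCTTCCTTGGAA" * 30)
        assert find_orfs(rec, min_orf_nt=30) == []
        assert rec.longest_orf is None

    def test_reverse_complement_mirrors_coordinates(self):
        rng = np.random.default_rng(3)
        seq = rand_seq(rng, 60) + "ATG" + rand_seq(rng, 10) * 0 + (
            "GCT" * 120
        ) + "TGA" + rand_seq(rng, 60)
        fwd = TranscriptRecord("f", seq)
        rev = TranscriptRecord("r", str(Seq(seq).reverse_complement()))
        n = len(seq)
        fwd_orfs = {(o.start, o.end, o.strand) for o in find_orfs(fwd, 300)}
        rev_orfs = {(o.start, o.end, o.strand) for o in find_orfs(rev, 300)}
        flipped = {
            (n - e, n - s, "+" if st == "-" else "-") for s, e, st in rev_orfs
        }
        assert fwd_orfs == flipped

    def test_orf_properties_hold(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            rec = TranscriptRecord("x", rand_seq(rng, 600))
            for o in find_orfs(rec, min_orf_nt=60):
                assert o.length % 3 == 0
                if o.strand == "+":
                    sub = rec.sequence[o.start : o.end]
                else:
                    sub = str(Seq(rec.sequence[o.start : o.end]).reverse_complement())
                assert sub.startswith("ATG")
                assert sub[-3:] in {"TAA", "TAG", "TGA"}

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            TranscriptRecord("x", "ACGTX")


class TestClusterRedundant:
    def test_identical_pair_keeps_longer_orf_member(self):
        rng = np.random.default_rng(1)
        core = orf_free(rng, 200)
        orf = "ATG" + "GCT" * 110 + "TAA"
        with_orf = TranscriptRecord("withorf", core + orf)
        plain = TranscriptRecord("plain", core + orf_free(rng, len(orf)))
        # make the two near-identical: copy with the ORF scrambled out
        twin = TranscriptRecord("twin", with_orf.sequence)
        res = cluster_redundant([with_orf, twin])
        assert len(res.representatives) == 1
        # identical ORF lengths: deterministic id tie-break
        assert res.representatives[0].id == "twin"
        res2 = cluster_redundant([with_orf, plain])  # dissimilar halves
        assert {r.id for r in res2.representatives} == {"withorf", "plain"}

    def test_longest_cds_member_represents_its_cluster(self):
        rng = np.random.default_rng(2)
        prefix = orf_free(rng, 60)
        long_orf = "ATG" + "GCT" * 150 + "TAA"
        short_orf = "ATG" + "GCT" * 100 + "TAA"
        a = TranscriptRecord("a_short", prefix + short_orf + orf_free(rng, 156))
        b = TranscriptRecord("b_long", prefix + long_orf + orf_free(rng, 6))
        # same length, nearly identical? They differ beyond thresholds; build
        # a true duplicate instead: same sequence, different annotation
        dup = TranscriptRecord("dup", b.sequence[:-9] + orf_free(rng, 9))
        res = cluster_redundant([b, dup])
        assert len(res.representatives) == 1
        assert res.representatives[0].orf_length >= dup.orf_length

    def test_half_identity_pair_stays_separate(self):
        rng = np.random.default_rng(4)
        s1 = rand_seq(rng, 400)
        s2 = s1[:200] + rand_seq(rng, 200)
        res = cluster_redundant(
            [TranscriptRecord("a", s1), TranscriptRecord("b", s2)]
        )
        assert len(res.representatives) == 2

    def test_no_representative_pair_exceeds_both_thresholds(self):
        rng = np.random.default_rng(5)
        records = []
        for i in range(12):
            records.append(TranscriptRecord(f"r{i:02d}", rand_seq(rng, 300)))
        # add mutated copies of the first three
        for i in range(3):
            seq = list(records[i].sequence)
            for pos in rng.choice(len(seq), 6, replace=False):
                seq[pos] = "ACGT".replace(seq[pos], "")[0]
            records.append(TranscriptRecord(f"m{i:02d}", "".join(seq)))
        res = cluster_redundant(records)
        reps = res.representatives
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                ident, cov = alignment_identity_coverage(
                    reps[i].sequence, reps[j].sequence
                )
                assert not (ident >= 0.95 and cov >= 0.90)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(6)
        records = [TranscriptRecord(f"r{i}", rand_seq(rng, 250)) for i in range(8)]
        once = cluster_redundant(records)
        twice = cluster_redundant(once.representatives)
        assert {r.id for r in twice.representatives} == {
            r.id for r in once.representatives
        }

    def test_empty_input_gives_empty_output(self):
        res = cluster_redundant([])
        assert res.representatives == [] and res.membership == {}


class TestConsensusMerge:
    def test_shared_contig_retained_once(self):
        rng = np.random.default_rng(7)
        shared = rand_seq(rng, 300)
        a = [TranscriptRecord("a1", shared), TranscriptRecord("a2", rand_seq(rng, 300))]
        b = [TranscriptRecord("b1", shared)]
        kept = consensus_merge(a, b)
        assert [r.id for r in kept] == ["a1"]

    def test_half_overlap_dropped(self):
        rng = np.random.default_rng(8)
        s = rand_seq(rng, 400)
        a = [TranscriptRecord("a1", s)]
        b = [TranscriptRecord("b1", s[:200] + rand_seq(rng, 200))]
        assert consensus_merge(a, b) == []

    def test_self_merge_is_identity_up_to_exact_duplicates(self):
        rng = np.random.default_rng(9)
        seqs = [rand_seq(rng, 200) for _ in range(5)]
        seqs.append(seqs[0])  # exact duplicate under another id
        recs = [TranscriptRecord(f"c{i}", s) for i, s in enumerate(seqs)]
        kept = consensus_merge(recs, recs)
        assert len(kept) == 5
        assert len({r.sequence for r in kept}) == 5


def regex_ssr_oracle(seq, min_contig_nt=1000, min_repeats=None):
    """Independent enumeration: backreference regex per motif length with the
    same aperiodicity/threshold/gate rules."""
    min_repeats = min_repeats or DEFAULT_MIN_REPEATS
    if len(seq) <= min_contig_nt:
        return set()
    hits = set()
    for k, m in min_repeats.items():
        for match in re.finditer(rf"([ACGT]{{{k}}})\1{{{m - 1},}}", seq):
            motif = match.group(1)
            if any(
                k % d == 0 and motif == motif[:d] * (k // d) for d in range(1, k)
            ):
                continue
            count = (match.end() - match.start()) // k
            hits.add(
                (canonical_rotation(motif), count, match.start(), match.start() + count * k)
            )
    return hits


class TestScanSsr:
    def test_planted_di_repeat_in_long_contig(self):
        rng = np.random.default_rng(10)
        seq = rand_seq(rng, 600).replace("AG", "TT") + "AG" * 8 + rand_seq(
            rng, 600
        ).replace("AG", "TT").replace("GA", "CC")
        rec = TranscriptRecord("x", seq)
        hits = [h for h in scan_ssr(rec) if h.motif == "AG"]
        assert any(h.repeat_count >= 8 for h in hits)

    def test_contig_at_or_below_one_kb_is_gated(self):
        seq = "C" * 400 + "AG" * 8 + "T" * 300  # 716 nt < 1000
        rec = TranscriptRecord("x", seq[:1000])
        assert scan_ssr(rec) == []

    def test_homopolymer_below_minimum_not_reported(self):
        rng = np.random.default_rng(11)
        flank = rand_seq(rng, 600).replace("A", "G")
        rec = TranscriptRecord("x", flank + "A" * 9 + flank)
        assert all(h.motif != "A" for h in scan_ssr(rec))

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(12)
        for trial in range(200):
            seq = rand_seq(rng, 1100)
            if trial % 3 == 0:  # plant a motif so hits actually occur
                motif = ["A", "AG", "ATC", "AATG"][trial % 4]
                reps = {1: 12, 2: 8, 3: 6, 4: 6}[len(motif)]
                pos = int(rng.integers(50, 900))
                seq = seq[:pos] + motif * reps + seq[pos + len(motif) * reps :]
            rec = TranscriptRecord("x", seq)
            got = {(h.motif, h.repeat_count, h.start, h.end) for h in scan_ssr(rec)}
            assert got == regex_ssr_oracle(seq)

    def test_hit_geometry_invariant(self):
        rng = np.random.default_rng(13)
        seq = rand_seq(rng, 1050) + "ATC" * 7 + rand_seq(rng, 50)
        for h in scan_ssr(TranscriptRecord("x", seq)):
            assert h.end - h.start == len(h.motif) * h.repeat_count
            assert h.repeat_count >= DEFAULT_MIN_REPEATS[len(h.motif)]
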