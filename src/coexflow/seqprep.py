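"""Post-assembly transcript curation.

Four operations used to polish a de novo transcriptome before analysis:

* ``consensus_merge`` — keep transcripts supported by two independent
  assemblies (exact-identity overlap over >= 95% of the shorter sequence);
* ``cluster_redundant`` — greedy longest-first redundancy clustering at
  >= 95% identity over >= 90% of the shorter sequence, retaining the member
  with the longest ORF as the cluster representative;
* ``find_orfs`` — six-frame ATG...stop open-reading-frame scan (a simplified
  longest-CDS selector, without a coding-potential model);
* ``scan_ssr`` — MISA-style perfect microsatellite scan of contigs larger
  than 1 kb, motif lengths 1-6 with per-length minimum repeat counts.

Alignment uses Biopython's pairwise aligner with match/mismatch/gap scores
of +1/-1/-2; for redundancy clustering end gaps are free so a short
redundant sequence may align within a longer representative.  All
coordinates are 0-based half-open on the forward strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")
_STOPS = {"TAA", "TAG", "TGA"}

DEFAULT_MIN_REPEATS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class ORF:
    """Open reading frame in forward-strand half-open coordinates."""

    start: int
    end: int
    strand: str  # '+' or '-'
    frame: int  # 0..2 within its reading orientation

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptRecord:
    id: str
    sequence: str
    longest_orf: Optional[ORF] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"{self.id}: invalid characters {sorted(bad)} (expected ACGTN)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def orf_length(self) -> int:
        return self.longest_orf.length if self.longest_orf else 0


@dataclass(frozen=True)
class SSRHit:
    transcript_id: str
    motif: str  # canonical rotation
    repeat_count: int
    start: int
    end: int

    def __post_init__(self) -> None:
        assert self.end - self.start == len(self.motif) * self.repeat_count


def _scan_frames(seq: str, min_orf_nt: int) -> List[Tuple[int, int, int]]:
    """ATG...in-frame-stop ORFs on one strand; (start, end, frame), end after stop."""
    out = []
    n = len(seq)
    for frame in range(3):
        pos = frame
        starts: List[int] = []
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if codon == "ATG":
                starts.append(pos)
            elif codon in _STOPS:
                # every open ATG in this frame closes at this stop
                for s in starts:
                    if pos + 3 - s >= min_orf_nt:
                        out.append((s, pos + 3, frame))
                starts = []
            pos += 3
    return out


def find_orfs(
    record: TranscriptRecord, min_orf_nt: int = 300
) -> List[ORF]:
    """Scan all six frames for ATG...stop ORFs of at least ``min_orf_nt``.

    Coordinates are reported on the forward strand (minus-strand ORFs are
    mirrored).  The longest ORF is stored on the record; ties prefer the
    forward strand, then the smaller start coordinate.
    """
    seq = record.sequence
    if not seq:
        raise ValueError(f"{record.id}: empty sequence")
    n = len(seq)
    orfs: List[ORF] = []
    for s, e, frame in _scan_frames(seq, min_orf_nt):
        orfs.append(ORF(s, e, "+", frame))
    rc = str(Seq(seq).reverse_complement())
    for s, e, frame in _scan_frames(rc, min_orf_nt):
        orfs.append(ORF(n - e, n - s, "-", frame))
    orfs.sort(key=lambda o: (-o.length, 0 if o.strand == "+" else 1, o.start))
    record.longest_orf = orfs[0] if orfs else None
    return orfs


def _make_aligner(end_gaps_free: bool, local: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    if local:
        aligner.mode = "local"
    else:
        aligner.mode = "global"
        if end_gaps_free:
            if hasattr(aligner, "end_insertion_score"):
                aligner.end_insertion_score = 0.0
                aligner.end_deletion_score = 0.0
            else:  # older Biopython naming
                aligner.target_end_gap_score = 0.0
                aligner.query_end_gap_score = 0.0
    return aligner


def alignment_identity_coverage(
    a: str, b: str, aligner: Optional[Align.PairwiseAligner] = None
) -> Tuple[float, float]:
    """Identity over aligned columns and coverage of the shorter sequence."""
    aligner = aligner or _make_aligner(end_gaps_free=True)
    aln = aligner.align(a, b)[0]
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        aligned_cols += te - ts
        seg_a, seg_b = a[ts:te], b[qs:qe]
        matches += sum(1 for x, y in zip(seg_a, seg_b) if x == y)
    if aligned_cols == 0:
        return 0.0, 0.0
    shorter = min(len(a), len(b))
    return matches / aligned_cols, aligned_cols / shorter


@dataclass
class RedundancyClusters:
    representatives: List[TranscriptRecord]
    membership: Dict[str, str]  # member id -> representative id


_SCREEN_K = 12


def _kmers(seq: str, k: int = _SCREEN_K) -> set:
    return {seq[i : i + k] for i in range(0, max(len(seq) - k + 1, 0))}


def _kmer_screen(short_kmers: set, long_kmers: set) -> bool:
    """Cheap word filter before alignment (the CD-HIT idea): a pair at
    >= 95% identity over >= 90% of the shorter sequence must share a large
    fraction of the shorter sequence's 12-mers; random pairs share none.
    The 0.05 bound is far below the worst case for a true match, so the
    screen never discards a pair the alignment would accept."""
    if not short_kmers:
        return True
    shared = len(short_kmers & long_kmers)
    return shared / len(short_kmers) >= 0.05


def cluster_redundant(
    records: Sequence[TranscriptRecord],
    identity_min: float = 0.95,
    coverage_min: float = 0.90,
    min_orf_nt: int = 300,
) -> RedundancyClusters:
    """Greedy longest-first redundancy clustering.

    A record joins the first (longest-representative) cluster whose
    representative it matches at identity >= ``identity_min`` over
    >= ``coverage_min`` of the shorter sequence.  Within a cluster the
    member with the longest ORF becomes the representative (ties by longer
    sequence, then id).  ORFs are computed on demand.
    """
    if not records:
        return RedundancyClusters([], {})
    for rec in records:
        if rec.longest_orf is None:
            find_orfs(rec, min_orf_nt=min_orf_nt)
    aligner = _make_aligner(end_gaps_free=True)
    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    clusters: List[List[TranscriptRecord]] = []
    cluster_kmers: List[set] = []
    for rec in ordered:
        rec_kmers = _kmers(rec.sequence)
        placed = False
        for cluster, rep_kmers in zip(clusters, cluster_kmers):
            rep = cluster[0]  # longest member, by insertion order
            if not _kmer_screen(rec_kmers, rep_kmers):
                continue
            ident, cov = alignment_identity_coverage(rep.sequence, rec.sequence, aligner)
            if ident >= identity_min and cov >= coverage_min:
                cluster.append(rec)
                placed = True
                break
        if not placed:
            clusters.append([rec])
            cluster_kmers.append(rec_kmers)
    representatives: List[TranscriptRecord] = []
    membership: Dict[str, str] = {}
    for cluster in clusters:
        best = sorted(cluster, key=lambda r: (-r.orf_length, -r.length, r.id))[0]
        representatives.append(best)
        for member in cluster:
            membership[member.id] = best.id
    representatives.sort(key=lambda r: r.id)
    return RedundancyClusters(representatives, membership)


def _longest_common_substring(a: str, b: str) -> int:
    m = SequenceMatcher(None, a, b, autojunk=False)
    return m.find_longest_match(0, len(a), 0, len(b)).size


def consensus_merge(
    assembly_a: Sequence[TranscriptRecord],
    assembly_b: Sequence[TranscriptRecord],
    identity: float = 1.00,
    overlap_min: float = 0.95,
) -> List[TranscriptRecord]:
    """Keep assembly-A transcripts corroborated by assembly B.

    An A-record is retained when some B-record shares a local alignment at
    >= ``identity`` identity covering >= ``overlap_min`` of the shorter
    sequence.  At the default 100% identity this is a longest-common-
    substring criterion.  Exact duplicate sequences within the retained set
    are collapsed to their first (by id) occurrence.
    """
    if not assembly_a or not assembly_b:
        raise ValueError("both assemblies must be non-empty")
    local = _make_aligner(end_gaps_free=False, local=True)
    retained: List[TranscriptRecord] = []
    seen_seqs: Dict[str, str] = {}
    for rec in sorted(assembly_a, key=lambda r: r.id):
        if rec.sequence in seen_seqs:
            continue
        hit = False
        for other in assembly_b:
            shorter = min(rec.length, other.length)
            if shorter == 0:
                continue
            if identity >= 1.0:
                cov = _longest_common_substring(rec.sequence, other.sequence) / shorter
                if cov >= overlap_min:
                    hit = True
            else:
                ident, cov = alignment_identity_coverage(
                    rec.sequence, other.sequence, local
                )
                if ident >= identity and cov >= overlap_min:
                    hit = True
            if hit:
                break
        if hit:
            retained.append(rec)
            seen_seqs[rec.sequence] = rec.id
    return retained


def _is_periodic(motif: str) -> bool:
    """True when the motif is itself a repetition of a shorter unit."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return True
    return False


def canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def scan_ssr(
    record: TranscriptRecord,
    min_contig_nt: int = 1000,
    min_repeats: Optional[Dict[int, int]] = None,
) -> List[SSRHit]:
    """Perfect-microsatellite scan of contigs larger than ``min_contig_nt``.

    Maximal perfect tandem repeats of motif length 1-6 meeting the
    per-length minimum repeat count are reported, motifs in canonical
    rotation; periodic motifs (which would re-report a shorter motif's run)
    and runs nested in an already-reported run of the same period are
    suppressed.  Contigs of at most ``min_contig_nt`` yield no hits.
    """
    min_repeats = dict(DEFAULT_MIN_REPEATS if min_repeats is None else min_repeats)
    seq = record.sequence
    n = len(seq)
    if n <= min_contig_nt:
        return []
    hits: List[SSRHit] = []
    for k, min_rep in sorted(min_repeats.items()):
        i = 0
        while i + k * min_rep <= n:
            # extend the period-k run starting at i
            m = i
            while m + k < n and seq[m + k] == seq[m]:
                m += 1
            total = m + k - i  # maximal run length, partial unit included
            count = total // k
            motif = seq[i : i + k]
            if count >= min_rep and "N" not in motif and not _is_periodic(motif):
                hits.append(
                    SSRHit(
                        transcript_id=record.id,
                        motif=canonical_rotation(motif),
                        repeat_count=count,
                        start=i,
                        end=i + count * k,
                    )
                )
                i = i + total - k + 1
            else:
                i += 1 if count < min_rep else total - k + 1
    hits.sort(key=lambda h: (h.start, len(h.motif)))
    return hits
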