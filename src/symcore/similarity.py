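"""Pairwise nucleotide CDS comparison: exact local alignment and batch best-hit search.

This module stands in for the BLAST searches of classical reciprocal-best-hit
pipelines.  ``align_pair`` is an exact affine-gap Smith-Waterman (via
Biopython's C aligner) reporting percent identity, query coverage and score.
``best_hits`` is the all-vs-all engine: k-mer seeding, a BLAST-like ungapped
extension gate, a scoring-only rescan, and a single exact traceback for the
winning subject.  The heuristics only ever *skip* candidate pairs; every
reported number comes from the exact aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import _kernels
from .errors import ParameterError

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement; non-ACGT letters are left as-is (then reversed)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated CDS.

    locus_id must be unique within its genome; the sequence is stored
    uppercase.  Non-ACGT letters are tolerated and scored as universal
    mismatches downstream.
    """

    locus_id: str
    genome_id: str
    seq: str
    category: Optional[str] = None

    def __post_init__(self):
        if not self.seq:
            raise ParameterError(f"empty sequence for locus {self.locus_id!r}")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring and search-filter parameters.

    A gap of length L costs ``gap_open + L * gap_extend``.  ``min_score`` is
    the minimum reportable local score (suppresses spurious short hits, the
    role an E-value cutoff plays in BLAST).  ``seed_extension_gate`` is the
    ungapped-extension score a k-mer-seeded candidate must reach before the
    batch search spends a full dynamic-programming pass on it; set to None to
    disable the gate (``align_pair`` never uses it).
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    min_score: int = 50
    kmer_size: int = 11
    min_shared_kmers: int = 1
    seed_extension_gate: Optional[int] = 35
    both_strands: bool = True

    def __post_init__(self):
        if self.match <= 0 or self.mismatch >= 0:
            raise ParameterError("match must be > 0 and mismatch < 0")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ParameterError("gap penalties must be non-negative (extend > 0)")
        if self.kmer_size < 4:
            raise ParameterError("kmer_size must be >= 4")
        if self.min_shared_kmers < 1:
            raise ParameterError("min_shared_kmers must be >= 1")


DEFAULT_PARAMS = ScoringParams()


@dataclass(frozen=True)
class SimilarityHit:
    """A scored local alignment between two CDS.

    identity is matches over aligned columns (gap columns included);
    query_coverage is the fraction of the query inside the local alignment.
    """

    query_locus: str
    subject_locus: str
    identity: float
    query_coverage: float
    subject_coverage: float
    score: float
    strand: str = "+"
    matches: int = 0
    aligned_columns: int = 0
    query_range: Tuple[int, int] = (0, 0)
    subject_range: Tuple[int, int] = (0, 0)


@dataclass
class BestHitMap:
    """Best hit per query locus for one directed genome-vs-genome search."""

    query_genome: str
    subject_genome: str
    hits: Dict[str, SimilarityHit] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.hits)


def _nt_matrix(match: int, mismatch: int) -> substitution_matrices.Array:
    # N mismatches everything, including itself (universal mismatch).
    m = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGTN":
        for y in "ACGTN":
            m[x, y] = match if (x == y and x != "N") else mismatch
    return m


def _make_aligner(params: ScoringParams, mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _nt_matrix(params.match, params.mismatch)
    # Biopython charges open_gap_score for the first gap position.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


_NON_ACGT = str.maketrans(
    {c: "N" for c in map(chr, range(65, 91)) if c not in "ACGT"}
)


def _sanitize(seq: str) -> str:
    return seq.upper().translate(_NON_ACGT)


def _alignment_stats(alignment, qseq: str, sseq: str):
    """(matches, aligned_cols, total_cols, q_range, s_range) of a local alignment."""
    qblocks, sblocks = alignment.aligned
    matches = 0
    aligned_cols = 0
    for (q0, q1), (s0, s1) in zip(qblocks, sblocks):
        aligned_cols += q1 - q0
        for qc, sc in zip(qseq[q0:q1], sseq[s0:s1]):
            if qc == sc and qc in "ACGT":
                matches += 1
    q_range = (int(qblocks[0][0]), int(qblocks[-1][1]))
    s_range = (int(sblocks[0][0]), int(sblocks[-1][1]))
    gap_cols = (q_range[1] - q_range[0] - aligned_cols) + (
        s_range[1] - s_range[0] - aligned_cols
    )
    return matches, aligned_cols, aligned_cols + gap_cols, q_range, s_range


def _align_one_strand(
    query: GeneRecord, subject: GeneRecord, subject_seq: str, strand: str,
    params: ScoringParams, aligner: Align.PairwiseAligner,
) -> Optional[SimilarityHit]:
    qs = _sanitize(query.seq)
    ss = _sanitize(subject_seq)
    alignments = aligner.align(qs, ss)
    if len(alignments) == 0:
        return None
    aln = alignments[0]
    score = float(aln.score)
    if score <= 0 or not len(aln.aligned[0]):
        return None
    matches, aligned_cols, total_cols, q_range, s_range = _alignment_stats(
        aln, query.seq.upper(), subject_seq.upper()
    )
    if total_cols == 0:
        return None
    return SimilarityHit(
        query_locus=query.locus_id,
        subject_locus=subject.locus_id,
        identity=matches / total_cols,
        query_coverage=(q_range[1] - q_range[0]) / len(query.seq),
        subject_coverage=(s_range[1] - s_range[0]) / len(subject.seq),
        score=score,
        strand=strand,
        matches=matches,
        aligned_columns=total_cols,
        query_range=q_range,
        subject_range=s_range,
    )


def align_pair(
    a: GeneRecord, b: GeneRecord, params: ScoringParams = DEFAULT_PARAMS
) -> Optional[SimilarityHit]:
    """Exact local alignment of two CDS; None when the best score < min_score.

    Both the forward and the reverse-complement orientation of ``b`` are
    tried and the higher-scoring one kept (forward wins ties).
    """
    aligner = _make_aligner(params)
    best = _align_one_strand(a, b, b.seq, "+", params, aligner)
    if params.both_strands:
        rc = _align_one_strand(a, b, reverse_complement(b.seq), "-", params, aligner)
        if rc is not None and (best is None or rc.score > best.score):
            best = rc
    if best is None or best.score < params.min_score:
        return None
    return best


class SubjectIndex:
    """k-mer index over a set of subject CDS (both strands).

    Reused by the batch best-hit search and by the pan-genome scanner.
    """

    def __init__(self, subjects: Sequence[GeneRecord], params: ScoringParams):
        self.params = params
        self.subjects = list(subjects)
        self.encoded: List[np.ndarray] = []
        self.encoded_rc: List[np.ndarray] = []
        self.index: Dict[int, List[Tuple[int, int, int]]] = {}
        for idx, rec in enumerate(self.subjects):
            fwd = _kernels.encode_seq(rec.seq)
            self.encoded.append(fwd)
            strands = [(0, fwd)]
            if params.both_strands:
                rc = _kernels.revcomp_encoded(fwd)
                self.encoded_rc.append(rc)
                strands.append((1, rc))
            else:
                self.encoded_rc.append(fwd)
            for strand, arr in strands:
                for pos, kmer in _iter_kmers(arr, params.kmer_size):
                    self.index.setdefault(kmer, []).append((idx, strand, pos))

    def add(self, rec: GeneRecord) -> int:
        """Add one subject incrementally (used by greedy pan-genome clustering)."""
        idx = len(self.subjects)
        self.subjects.append(rec)
        fwd = _kernels.encode_seq(rec.seq)
        self.encoded.append(fwd)
        strands = [(0, fwd)]
        if self.params.both_strands:
            rc = _kernels.revcomp_encoded(fwd)
            self.encoded_rc.append(rc)
            strands.append((1, rc))
        else:
            self.encoded_rc.append(fwd)
        for strand, arr in strands:
            for pos, kmer in _iter_kmers(arr, self.params.kmer_size):
                self.index.setdefault(kmer, []).append((idx, strand, pos))
        return idx

    def candidates(self, query_arr: np.ndarray) -> Dict[Tuple[int, int], Dict]:
        """Map (subject_idx, strand) -> {'count': n_shared, 'diags': set}."""
        out: Dict[Tuple[int, int], Dict] = {}
        for qpos, kmer in _iter_kmers(query_arr, self.params.kmer_size):
            postings = self.index.get(kmer)
            if not postings:
                continue
            for idx, strand, spos in postings:
                entry = out.setdefault((idx, strand), {"count": 0, "diags": set()})
                entry["count"] += 1
                entry["diags"].add(spos - qpos)
        return out

    def subject_arr(self, idx: int, strand: int) -> np.ndarray:
        return self.encoded[idx] if strand == 0 else self.encoded_rc[idx]


def _iter_kmers(arr: np.ndarray, k: int):
    """Yield (position, packed-int k-mer) for every window free of ambiguity."""
    n = len(arr)
    if n < k:
        return
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (windows < 4).all(axis=1)
    powers = 4 ** np.arange(k, dtype=np.int64)
    values = windows.astype(np.int64) @ powers
    for pos in np.nonzero(valid)[0]:
        yield int(pos), int(values[pos])


def _candidate_score(
    index: SubjectIndex, query_arr: np.ndarray, key: Tuple[int, int], diags, params: ScoringParams
) -> Optional[int]:
    """Gate-then-score one candidate; None when the gate rejects it."""
    arr = index.subject_arr(*key)
    if params.seed_extension_gate is not None:
        gate = min(params.seed_extension_gate, params.min_score)
        dlist = np.fromiter(diags, dtype=np.int64, count=len(diags))
        if len(dlist) > 64:
            dlist = dlist[:64]
        ug = _kernels.ungapped_diag_best(
            query_arr, arr, dlist, params.match, params.mismatch
        )
        if ug < gate:
            return None
    return int(
        _kernels.sw_score(
            query_arr, arr, params.match, params.mismatch,
            params.gap_open, params.gap_extend,
        )
    )


def best_hits(
    queries: Sequence[GeneRecord],
    subjects: Sequence[GeneRecord],
    params: ScoringParams = DEFAULT_PARAMS,
    index: Optional[SubjectIndex] = None,
) -> BestHitMap:
    """Best-scoring subject per query over all queries.

    Ties on score break by higher identity, then lexicographically smallest
    subject locus.  Queries with no hit at ``min_score`` are absent from the
    result.
    """
    if not subjects:
        raise ParameterError("subject set is empty")
    qg = {r.genome_id for r in queries}
    sg = {r.genome_id for r in subjects}
    if len(qg) != 1 or len(sg) != 1:
        raise ParameterError("queries and subjects must each come from one genome")
    if index is None:
        index = SubjectIndex(subjects, params)
    aligner = _make_aligner(params)
    result = BestHitMap(query_genome=qg.pop(), subject_genome=sg.pop())
    for query in queries:
        qarr = _kernels.encode_seq(query.seq)
        cands = index.candidates(qarr)
        scored: List[Tuple[int, int, int]] = []  # (score, idx, strand)
        for key, info in cands.items():
            if info["count"] < params.min_shared_kmers:
                continue
            sc = _candidate_score(index, qarr, key, info["diags"], params)
            if sc is not None and sc >= params.min_score:
                scored.append((sc, key[0], key[1]))
        if not scored:
            continue
        best_score = max(s for s, _, _ in scored)
        tied = [(i, st) for s, i, st in scored if s == best_score]
        best_hit: Optional[SimilarityHit] = None
        for idx, strand in tied:
            subj = index.subjects[idx]
            sseq = subj.seq if strand == 0 else reverse_complement(subj.seq)
            hit = _align_one_strand(
                query, subj, sseq, "+" if strand == 0 else "-", params, aligner
            )
            if hit is None:
                continue
            # tie-break: higher identity first, then smaller subject locus
            if (
                best_hit is None
                or hit.identity > best_hit.identity
                or (
                    hit.identity == best_hit.identity
                    and hit.subject_locus < best_hit.subject_locus
                )
            ):
                best_hit = hit
        if best_hit is not None:
            result.hits[query.locus_id] = best_hit
    return result
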