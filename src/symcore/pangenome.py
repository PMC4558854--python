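"""Reference pan-genome construction and presence/absence scanning.

The pan-genome is built by greedy, length-descending representative
clustering: genes are processed longest-first and join the first existing
locus whose representative they match under the allelic-variant criterion
(identity >= identity_threshold over coverage >= coverage_threshold), else
found a new locus.  The same criterion drives presence/absence scanning of
whole genomes and targeted query-gene scans (the virulence-factor use case).

A hit must also clear the similarity module's ``min_score`` so that very
short high-identity local matches cannot join loci spuriously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .errors import ParameterError
from .similarity import (
    DEFAULT_PARAMS,
    GeneRecord,
    ScoringParams,
    SimilarityHit,
    SubjectIndex,
    _align_one_strand,
    _candidate_score,
    _make_aligner,
    reverse_complement,
)


@dataclass
class PanLocus:
    """One pan-genome locus: a representative plus its member genes."""

    locus_id: str
    representative: GeneRecord
    members: List[Tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PresenceAbsenceMatrix:
    """Boolean loci x genomes matrix with per-cell best-match bookkeeping."""

    loci: List[str]
    genomes: List[str]
    cells: np.ndarray
    assignments: Dict[Tuple[str, str], Tuple[str, float, float]] = field(
        default_factory=dict
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells.astype(int), index=self.loci, columns=self.genomes
        )

    def prevalence(self) -> pd.Series:
        return pd.Series(self.cells.sum(axis=1), index=self.loci)


def _coverage(hit: SimilarityHit, q_len: int, s_len: int, mode: str) -> float:
    q_cov = (hit.query_range[1] - hit.query_range[0]) / q_len
    s_cov = (hit.subject_range[1] - hit.subject_range[0]) / s_len
    if mode == "longer":
        return q_cov if q_len >= s_len else s_cov
    if mode == "shorter":
        return q_cov if q_len <= s_len else s_cov
    raise ParameterError(f"unknown coverage mode {mode!r}")


def _criterion_check(
    gene: GeneRecord,
    gene_arr: np.ndarray,
    rep_idx: int,
    index: SubjectIndex,
    cand_info: Mapping[Tuple[int, int], Dict],
    params: ScoringParams,
    identity_threshold: float,
    coverage_threshold: float,
    coverage_mode: str,
    aligner,
) -> Optional[Tuple[float, float]]:
    """(identity, coverage) when gene matches the representative, else None."""
    best = None
    rep = index.subjects[rep_idx]
    for strand in (0, 1):
        info = cand_info.get((rep_idx, strand))
        if info is None or info["count"] < params.min_shared_kmers:
            continue
        score = _candidate_score(index, gene_arr, (rep_idx, strand), info["diags"], params)
        if score is None or score < params.min_score:
            continue
        sseq = rep.seq if strand == 0 else reverse_complement(rep.seq)
        hit = _align_one_strand(
            gene, rep, sseq, "+" if strand == 0 else "-", params, aligner
        )
        if hit is None:
            continue
        cov = _coverage(hit, len(gene.seq), len(rep.seq), coverage_mode)
        if hit.identity >= identity_threshold and cov >= coverage_threshold:
            if best is None or hit.identity > best[0]:
                best = (hit.identity, cov)
    return best


def _gene_sort_key(rec: GeneRecord):
    return (-len(rec.seq), rec.genome_id, rec.locus_id)


def _flatten(genomes) -> List[GeneRecord]:
    if isinstance(genomes, Mapping):
        return [g for gid in genomes for g in genomes[gid]]
    return [g for genome in genomes for g in genome]


def build_reference_pangenome(
    genomes,
    identity_threshold: float = 0.70,
    coverage_threshold: float = 0.10,
    params: ScoringParams = DEFAULT_PARAMS,
    coverage_mode: str = "longer",
) -> List[PanLocus]:
    """Greedy length-descending clustering of all genes into pan-loci.

    ``genomes`` is a mapping genome id -> records, or a list of record lists.
    Deterministic: genes are processed by decreasing length with ties broken
    by (genome id, locus id); a gene joins the first (oldest) matching locus.
    """
    if not 0 < identity_threshold <= 1 or not 0 < coverage_threshold <= 1:
        raise ParameterError("thresholds must be in (0, 1]")
    genes = _flatten(genomes)
    if not genes:
        raise ParameterError("no genomes / genes supplied")
    genes.sort(key=_gene_sort_key)
    aligner = _make_aligner(params)
    index = SubjectIndex([], params)
    loci: List[PanLocus] = []
    width = max(5, len(str(len(genes))))
    for gene in genes:
        arr = _kernels.encode_seq(gene.seq)
        cands = index.candidates(arr)
        cand_loci = sorted({idx for idx, _ in cands})
        joined = False
        for rep_idx in cand_loci:
            ok = _criterion_check(
                gene, arr, rep_idx, index, cands, params,
                identity_threshold, coverage_threshold, coverage_mode, aligner,
            )
            if ok is not None:
                loci[rep_idx].members.append((gene.genome_id, gene.locus_id))
                joined = True
                break
        if not joined:
            rep_idx = index.add(gene)
            loci.append(
                PanLocus(
                    locus_id=f"PL{rep_idx + 1:0{width}d}",
                    representative=gene,
                    members=[(gene.genome_id, gene.locus_id)],
                )
            )
    return loci


def scan_presence(
    pangenome: Sequence[PanLocus],
    genomes: Mapping[str, Sequence[GeneRecord]],
    identity_threshold: float = 0.70,
    coverage_threshold: float = 0.10,
    params: ScoringParams = DEFAULT_PARAMS,
    coverage_mode: str = "longer",
) -> PresenceAbsenceMatrix:
    """Presence/absence of every pan-locus in every genome.

    A cell is present when some gene of the genome matches the locus
    representative under the allelic-variant criterion.  The best-identity
    matching gene per cell is recorded in ``assignments``.
    """
    if not pangenome:
        raise ParameterError("pan-genome is empty")
    reps = [p.representative for p in pangenome]
    index = SubjectIndex(reps, params)
    aligner = _make_aligner(params)
    locus_ids = [p.locus_id for p in pangenome]
    genome_ids = list(genomes)
    cells = np.zeros((len(pangenome), len(genome_ids)), dtype=bool)
    assignments: Dict[Tuple[str, str], Tuple[str, float, float]] = {}
    for gcol, gid in enumerate(genome_ids):
        for gene in genomes[gid]:
            arr = _kernels.encode_seq(gene.seq)
            cands = index.candidates(arr)
            for rep_idx in sorted({idx for idx, _ in cands}):
                ok = _criterion_check(
                    gene, arr, rep_idx, index, cands, params,
                    identity_threshold, coverage_threshold, coverage_mode, aligner,
                )
                if ok is None:
                    continue
                cells[rep_idx, gcol] = True
                key = (locus_ids[rep_idx], gid)
                prev = assignments.get(key)
                if prev is None or ok[0] > prev[1]:
                    assignments[key] = (gene.locus_id, ok[0], ok[1])
    return PresenceAbsenceMatrix(
        loci=locus_ids, genomes=genome_ids, cells=cells, assignments=assignments
    )


def core_loci(matrix: PresenceAbsenceMatrix, prevalence: float = 0.90) -> List[str]:
    """Loci present in at least ceil(prevalence * n_genomes) genomes."""
    if not 0 < prevalence <= 1:
        raise ParameterError("prevalence must be in (0, 1]")
    n = len(matrix.genomes)
    needed = math.ceil(prevalence * n - 1e-9)
    counts = matrix.cells.sum(axis=1)
    return [l for l, c in zip(matrix.loci, counts) if c >= needed]


def query_scan(
    queries: Sequence[GeneRecord],
    genomes: Mapping[str, Sequence[GeneRecord]],
    identity_threshold: float = 0.70,
    coverage_threshold: float = 0.10,
    params: ScoringParams = DEFAULT_PARAMS,
    coverage_mode: str = "longer",
) -> pd.DataFrame:
    """Presence/absence of named query genes in each genome.

    Returns a tidy frame with one row per (query, genome): ``present``,
    plus the best hit's identity, coverage and locus when any alignment at
    ``min_score`` exists (regardless of whether it clears the thresholds).
    """
    if not queries:
        raise ParameterError("query list is empty")
    aligner = _make_aligner(params)
    rows = []
    for gid in genomes:
        index = SubjectIndex(genomes[gid], params)
        for q in queries:
            arr = _kernels.encode_seq(q.seq)
            cands = index.candidates(arr)
            best = None  # (identity, coverage, locus, passes)
            for (sidx, strand), info in sorted(cands.items()):
                if info["count"] < params.min_shared_kmers:
                    continue
                score = _candidate_score(index, arr, (sidx, strand), info["diags"], params)
                if score is None or score < params.min_score:
                    continue
                subj = index.subjects[sidx]
                sseq = subj.seq if strand == 0 else reverse_complement(subj.seq)
                hit = _align_one_strand(
                    q, subj, sseq, "+" if strand == 0 else "-", params, aligner
                )
                if hit is None:
                    continue
                cov = _coverage(hit, len(q.seq), len(subj.seq), coverage_mode)
                passes = hit.identity >= identity_threshold and cov >= coverage_threshold
                cand = (hit.identity, cov, subj.locus_id, passes)
                if best is None or (cand[3], cand[0]) > (best[3], best[0]):
                    best = cand
            rows.append(
                {
                    "query": q.locus_id,
                    "genome": gid,
                    "present": bool(best[3]) if best else False,
                    "best_identity": best[0] if best else float("nan"),
                    "best_coverage": best[1] if best else float("nan"),
                    "best_locus": best[2] if best else "",
                }
            )
    return pd.DataFrame(rows)
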