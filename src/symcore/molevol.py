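"""Codon-aware pairwise alignment and Nei-Gojobori (NG86) dN/dS estimation.

Each ortholog pair is aligned at the protein level (table 11 translation,
global alignment), the gaps are mapped back onto codons, and columns with a
gap, an ambiguous base or a stop are dropped.  Synonymous/nonsynonymous
sites and differences are then counted in the NG86 fashion: per-position
synonymous site fractions averaged over the two sequences, multi-hit codons
resolved by equal-weight averaging over all minimal mutational pathways that
avoid stop codons, and a Jukes-Cantor correction applied to both proportions.
Pairs whose synonymous divergence is uncorrectable, or exceeds the
saturation threshold (default dS > 3), are flagged saturated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from . import genetics
from .errors import AlignmentFilterError, CodonAlignmentError
from .orthology import OrthologTable
from .similarity import GeneRecord

DEFAULT_SATURATION = 3.0
DEFAULT_MIN_CODONS = 30


@dataclass
class CodonAlignment:
    """Two gap-free codon index arrays of equal length after filtering."""

    a_locus: str
    b_locus: str
    codons_a: np.ndarray
    codons_b: np.ndarray
    dropped: int

    def __post_init__(self):
        if self.codons_a.shape != self.codons_b.shape:
            raise CodonAlignmentError("codon arrays differ in length")

    @property
    def n_codons(self) -> int:
        return int(self.codons_a.shape[0])


@dataclass
class DnDsEstimate:
    """NG86 counts and rates for one ortholog pair."""

    a_locus: str
    b_locus: str
    n_codons: int
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: Optional[float]
    dN: Optional[float]
    omega: Optional[float]
    saturated: bool


# ---------------------------------------------------------------------------
# codon-aware pairwise alignment
# ---------------------------------------------------------------------------

_protein_aligner = None


def _get_protein_aligner() -> Align.PairwiseAligner:
    global _protein_aligner
    if _protein_aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -12
        a.extend_gap_score = -1
        _protein_aligner = a
    return _protein_aligner


def _codon_strings(rec: GeneRecord) -> List[str]:
    """In-frame codons; trailing partial codon and terminal stop trimmed."""
    seq = rec.seq.upper()
    if len(seq) < 3:
        raise CodonAlignmentError(f"{rec.locus_id}: sequence shorter than one codon")
    seq = seq[: len(seq) - len(seq) % 3]
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in genetics.STOP_CODONS:
        codons = codons[:-1]
    for k, c in enumerate(codons):
        if c in genetics.STOP_CODONS:
            raise CodonAlignmentError(
                f"{rec.locus_id}: internal stop codon at codon {k + 1}"
            )
    if not codons:
        raise CodonAlignmentError(f"{rec.locus_id}: no codons left after trimming")
    return codons


def _aa_of(codon: str) -> str:
    if any(ch not in "ACGT" for ch in codon):
        return "X"
    return genetics.AA_BY_INDEX[genetics.CODON_INDEX[codon]]


def codon_align(
    a: GeneRecord, b: GeneRecord, min_codons: int = DEFAULT_MIN_CODONS
) -> CodonAlignment:
    """Protein-guided codon alignment of two CDS.

    Raises :class:`CodonAlignmentError` on frame problems and
    :class:`AlignmentFilterError` when fewer than ``min_codons`` columns
    survive the gap/ambiguity/stop filter (the gap-rich pair filter).
    """
    codons_a = _codon_strings(a)
    codons_b = _codon_strings(b)
    prot_a = "".join(_aa_of(c) for c in codons_a)
    prot_b = "".join(_aa_of(c) for c in codons_b)
    aln = _get_protein_aligner().align(prot_a, prot_b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    keep_a: List[int] = []
    keep_b: List[int] = []
    dropped = 0
    ia = ib = 0
    for x, y in zip(sa, sb):
        if x == "-":
            ib += 1
            dropped += 1
            continue
        if y == "-":
            ia += 1
            dropped += 1
            continue
        ca, cb = codons_a[ia], codons_b[ib]
        if x == "X" or y == "X":
            dropped += 1
        else:
            keep_a.append(genetics.CODON_INDEX[ca])
            keep_b.append(genetics.CODON_INDEX[cb])
        ia += 1
        ib += 1
    if len(keep_a) < min_codons:
        raise AlignmentFilterError(
            f"{a.locus_id}/{b.locus_id}: only {len(keep_a)} codon columns survive "
            f"filtering (< {min_codons})"
        )
    return CodonAlignment(
        a_locus=a.locus_id,
        b_locus=b.locus_id,
        codons_a=np.asarray(keep_a, dtype=np.int64),
        codons_b=np.asarray(keep_b, dtype=np.int64),
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# NG86 tables
# ---------------------------------------------------------------------------

def _codon_nts(c: int) -> Tuple[int, int, int]:
    return ((c >> 4) & 3, (c >> 2) & 3, c & 3)


def _syn_site_fractions() -> np.ndarray:
    """Per-codon synonymous site count: sum over positions of the fraction of
    the three possible changes that are synonymous (changes to stops count
    as nonsynonymous)."""
    out = np.zeros(64)
    for c in range(64):
        if genetics.IS_STOP[c]:
            out[c] = np.nan
            continue
        nts = _codon_nts(c)
        s = 0.0
        for pos in range(3):
            for alt in range(4):
                if alt == nts[pos]:
                    continue
                new = list(nts)
                new[pos] = alt
                nc = new[0] * 16 + new[1] * 4 + new[2]
                if not genetics.IS_STOP[nc] and (
                    genetics.AA_BY_INDEX[nc] == genetics.AA_BY_INDEX[c]
                ):
                    s += 1.0 / 3.0
        out[c] = s
    return out


def _pathway_counts(c1: int, c2: int) -> Tuple[float, float]:
    """(Sd, Nd) contribution of one codon pair: equal-weight average over all
    minimal mutational pathways that avoid stop codons (all pathways if every
    one is blocked)."""
    nts1, nts2 = _codon_nts(c1), _codon_nts(c2)
    diff_pos = [p for p in range(3) if nts1[p] != nts2[p]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    blocked_results = []
    for order in permutations(diff_pos):
        cur = list(nts1)
        sd = nd = 0.0
        blocked = False
        for p in order:
            prev_codon = cur[0] * 16 + cur[1] * 4 + cur[2]
            cur[p] = nts2[p]
            new_codon = cur[0] * 16 + cur[1] * 4 + cur[2]
            if genetics.IS_STOP[new_codon] and new_codon != c2:
                blocked = True
            if genetics.AA_BY_INDEX[new_codon] == genetics.AA_BY_INDEX[prev_codon]:
                sd += 1.0
            else:
                nd += 1.0
        (blocked_results if blocked else results).append((sd, nd))
    pool = results if results else blocked_results
    sd = sum(r[0] for r in pool) / len(pool)
    nd = sum(r[1] for r in pool) / len(pool)
    return sd, nd


_SYN_SITES: Optional[np.ndarray] = None
_PAIR_SD: Optional[np.ndarray] = None
_PAIR_ND: Optional[np.ndarray] = None


def _tables():
    global _SYN_SITES, _PAIR_SD, _PAIR_ND
    if _SYN_SITES is None:
        _SYN_SITES = _syn_site_fractions()
        sd = np.zeros((64, 64))
        nd = np.zeros((64, 64))
        for c1 in range(64):
            if genetics.IS_STOP[c1]:
                continue
            for c2 in range(64):
                if genetics.IS_STOP[c2]:
                    continue
                sd[c1, c2], nd[c1, c2] = _pathway_counts(c1, c2)
        _PAIR_SD, _PAIR_ND = sd, nd
    return _SYN_SITES, _PAIR_SD, _PAIR_ND


def _jc_correct(p: float) -> Optional[float]:
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0:
        return None
    return -0.75 * math.log(arg)


def ng86_estimate(
    ca: CodonAlignment, saturation_threshold: float = DEFAULT_SATURATION
) -> DnDsEstimate:
    """NG86 counts and Jukes-Cantor-corrected rates for one codon alignment."""
    syn, pair_sd, pair_nd = _tables()
    L = ca.n_codons
    s_a = float(syn[ca.codons_a].sum())
    s_b = float(syn[ca.codons_b].sum())
    S = 0.5 * (s_a + s_b)
    N = 3.0 * L - S
    Sd = float(pair_sd[ca.codons_a, ca.codons_b].sum())
    Nd = float(pair_nd[ca.codons_a, ca.codons_b].sum())
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    saturated = dS is None or dN is None or dS > saturation_threshold
    omega: Optional[float] = None
    if not saturated and dS is not None and dS > 0 and dN is not None:
        omega = dN / dS
    return DnDsEstimate(
        a_locus=ca.a_locus,
        b_locus=ca.b_locus,
        n_codons=L,
        S_sites=S,
        N_sites=N,
        Sd=Sd,
        Nd=Nd,
        pS=pS,
        pN=pN,
        dS=dS,
        dN=dN,
        omega=omega,
        saturated=saturated,
    )


# ---------------------------------------------------------------------------
# genome-wide scan
# ---------------------------------------------------------------------------

def genome_wide_dnds(
    orthologs: OrthologTable,
    genes_a: Sequence[GeneRecord],
    genes_b: Sequence[GeneRecord],
    saturation_threshold: float = DEFAULT_SATURATION,
    min_codons: int = DEFAULT_MIN_CODONS,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Pairwise dN/dS for every ortholog pair that passes codon alignment.

    Returns a scatter-ready table (one row per retained pair) and summary
    statistics: mean dS over unsaturated pairs, the fraction of pairs flagged
    saturated, and the fraction of defined estimates with omega > 1.
    """
    if not len(orthologs):
        raise CodonAlignmentError("ortholog table is empty")
    lookup_a = {g.locus_id: g for g in genes_a}
    lookup_b = {g.locus_id: g for g in genes_b}
    rows = []
    skipped: List[Tuple[str, str, str]] = []
    for a_locus, b_locus in orthologs.pairs:
        ra, rb = lookup_a.get(a_locus), lookup_b.get(b_locus)
        if ra is None or rb is None:
            skipped.append((a_locus, b_locus, "missing sequence"))
            continue
        try:
            ca = codon_align(ra, rb, min_codons=min_codons)
        except CodonAlignmentError as exc:
            skipped.append((a_locus, b_locus, str(exc)))
            continue
        est = ng86_estimate(ca, saturation_threshold)
        rows.append(
            {
                "a_locus": est.a_locus,
                "b_locus": est.b_locus,
                "codons_retained": est.n_codons,
                "S_sites": est.S_sites,
                "N_sites": est.N_sites,
                "Sd": est.Sd,
                "Nd": est.Nd,
                "dS": est.dS if est.dS is not None else float("nan"),
                "dN": est.dN if est.dN is not None else float("nan"),
                "omega": est.omega if est.omega is not None else float("nan"),
                "saturated": est.saturated,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "a_locus", "b_locus", "codons_retained", "S_sites", "N_sites",
            "Sd", "Nd", "dS", "dN", "omega", "saturated",
        ],
    )
    if df.empty:
        warnings.warn("all ortholog pairs were filtered out", stacklevel=2)
        summary = {
            "n_pairs": 0.0, "n_skipped": float(len(skipped)),
            "mean_dS_unsaturated": float("nan"),
            "fraction_saturated": float("nan"),
            "fraction_omega_gt_1": float("nan"),
        }
        return df, summary
    unsat = df[~df["saturated"]]
    defined = unsat[np.isfinite(unsat["omega"])]
    summary = {
        "n_pairs": float(len(df)),
        "n_skipped": float(len(skipped)),
        "mean_dS_unsaturated": float(unsat["dS"].mean()) if len(unsat) else float("nan"),
        "fraction_saturated": float(df["saturated"].mean()),
        "fraction_omega_gt_1": (
            float((defined["omega"] > 1).mean()) if len(defined) else float("nan")
        ),
    }
    return df, summary


def plot_dnds(df: pd.DataFrame, ax=None):
    """dN-vs-dS scatter with the dotted neutrality line (dN = dS)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sub = df[np.isfinite(df["dS"]) & np.isfinite(df["dN"])]
    ax.scatter(sub["dS"], sub["dN"], s=8, alpha=0.5, edgecolors="none")
    lim = max(1.0, sub["dS"].max() if len(sub) else 1.0, sub["dN"].max() if len(sub) else 1.0)
    ax.plot([0, lim], [0, lim], linestyle=":", color="grey", label="dN = dS")
    ax.set_xlabel("dS")
    ax.set_ylabel("dN")
    ax.legend(frameon=False)
    return ax
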