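"""Gene-by-gene multiple alignment, supermatrix concatenation, distance
models, neighbor-joining tree inference, and bootstrap support.

The tree engine is canonical Saitou-Nei neighbor joining over corrected
pairwise distances; gapped columns are handled by pairwise deletion so every
taxon pair uses all columns where both are ungapped.  Multiple alignment is
deterministic center-star: the center sequence minimizes the sum of pairwise
alignment distances and all other sequences are merged against it under
"once a gap, always a gap".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ParameterError
from .similarity import ScoringParams, _nt_matrix

GAP = "-"

NT_MODELS = ("p", "jc", "k2p")
AA_MODELS = ("p", "poisson")

#: distance assigned to saturated pairs (corrected distance undefined)
DEFAULT_SATURATION_CAP = 5.0


@dataclass
class MultipleAlignment:
    """Taxon-labelled aligned sequences of equal length."""

    taxa: List[str]
    rows: List[str]
    alphabet: str = "nt"
    name: Optional[str] = None

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ParameterError("taxa and rows differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ParameterError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ParameterError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


@dataclass
class Supermatrix:
    """Concatenated alignments with a gene -> column-interval partition map."""

    alignment: MultipleAlignment
    partitions: Dict[str, Tuple[int, int]]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a saturation mask."""

    taxa: List[str]
    values: np.ndarray
    saturated: np.ndarray

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


@dataclass
class PhyloTree:
    """An (un)rooted tree with branch lengths and optional bootstrap supports."""

    tree: dendropy.Tree
    taxa: List[str]
    supports: Optional[Dict[FrozenSet[str], float]] = None

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".6g"
        ).strip()

    def splits(self) -> Set[FrozenSet[str]]:
        return tree_splits(self.tree, self.taxa)


# ---------------------------------------------------------------------------
# multiple alignment
# ---------------------------------------------------------------------------

def _pairwise_aligner(alphabet: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "nt":
        p = ScoringParams()
        aligner.substitution_matrix = _nt_matrix(p.match, p.mismatch)
        aligner.open_gap_score = -(p.gap_open + p.gap_extend)
        aligner.extend_gap_score = -p.gap_extend
    else:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12
        aligner.extend_gap_score = -1
    return aligner


def _guess_alphabet(seqs: Sequence[str]) -> str:
    letters = set("".join(seqs).upper()) - set("ACGTN-")
    return "nt" if not letters else "aa"


_AA_SANITIZE = str.maketrans({"*": "X", "-": "X", ".": "X"})


def _sanitize_for(alphabet: str, seq: str) -> str:
    if alphabet == "nt":
        cleaned = "".join(c if c in "ACGT" else "N" for c in seq.upper())
        return cleaned
    return seq.upper().translate(_AA_SANITIZE)


def _merge_center(master: str, rows: List[str], c_new: str, s_new: str) -> Tuple[str, List[str], str]:
    """Merge a new pairwise (center, seq) alignment into the growing master.

    Both ``master`` and ``c_new`` are the center with gaps; gaps present in
    either are kept in the union ("once a gap, always a gap").
    """
    out_master: List[str] = []
    out_rows: List[List[str]] = [[] for _ in rows]
    out_new: List[str] = []
    i = j = 0
    n, m = len(master), len(c_new)
    while i < n or j < m:
        a = master[i] if i < n else None
        b = c_new[j] if j < m else None
        if a == GAP and (j >= m or b != GAP):
            out_master.append(GAP)
            for k, r in enumerate(rows):
                out_rows[k].append(r[i])
            out_new.append(GAP)
            i += 1
        elif b == GAP and (i >= n or a != GAP):
            out_master.append(GAP)
            for k in range(len(rows)):
                out_rows[k].append(GAP)
            out_new.append(s_new[j])
            j += 1
        else:
            out_master.append(a if a is not None else GAP)
            for k, r in enumerate(rows):
                out_rows[k].append(r[i])
            out_new.append(s_new[j])
            i += 1
            j += 1
    return (
        "".join(out_master),
        ["".join(r) for r in out_rows],
        "".join(out_new),
    )


def align_gene(
    seqs: Mapping[str, str],
    alphabet: Optional[str] = None,
    name: Optional[str] = None,
) -> MultipleAlignment:
    """Deterministic center-star multiple alignment.

    The center minimizes the sum of pairwise alignment distances (non-match
    columns of the pairwise global alignment); ties break on taxon order.
    """
    taxa = list(seqs)
    if len(taxa) < 2:
        raise ParameterError("need >= 2 sequences")
    for t in taxa:
        if not seqs[t]:
            raise ParameterError(f"empty sequence for taxon {t!r}")
    if alphabet is None:
        alphabet = _guess_alphabet(list(seqs.values()))
    aligner = _pairwise_aligner(alphabet)
    clean = {t: _sanitize_for(alphabet, seqs[t]) for t in taxa}

    def pair_distance_and_aln(a: str, b: str):
        aln = aligner.align(clean[a], clean[b])[0]
        sa, sb = str(aln[0]), str(aln[1])
        diff = sum(1 for x, y in zip(sa, sb) if x != y or x == GAP)
        return diff, sa, sb

    cache: Dict[Tuple[str, str], Tuple[int, str, str]] = {}
    sums = {t: 0 for t in taxa}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            d, sa, sb = pair_distance_and_aln(a, b)
            cache[(a, b)] = (d, sa, sb)
            sums[a] += d
            sums[b] += d
    center = min(taxa, key=lambda t: (sums[t], taxa.index(t)))

    master = clean[center]
    merged_taxa: List[str] = []
    merged_rows: List[str] = []
    for t in taxa:
        if t == center:
            continue
        key = (center, t) if (center, t) in cache else (t, center)
        d, sa, sb = cache[key]
        if key[0] != center:
            sa, sb = sb, sa
        master, merged_rows, new_row = _merge_center(master, merged_rows, sa, sb)
        merged_taxa.append(t)
        merged_rows.append(new_row)
    out_taxa = [center] + merged_taxa
    out_rows = [master] + merged_rows
    order = [out_taxa.index(t) for t in taxa]
    return MultipleAlignment(
        taxa=[out_taxa[i] for i in order],
        rows=[out_rows[i] for i in order],
        alphabet=alphabet,
        name=name,
    )


def concatenate(
    alignments: Sequence[MultipleAlignment], taxon_policy: str = "drop-incomplete"
) -> Supermatrix:
    """Concatenate gene alignments into a supermatrix.

    ``drop-incomplete`` keeps only taxa present in every gene (gap-free
    supermatrix in the taxon dimension); ``pad-gaps`` keeps the union and
    fills missing taxa with all-gap rows.
    """
    if not alignments:
        raise ParameterError("no alignments to concatenate")
    if taxon_policy not in ("drop-incomplete", "pad-gaps"):
        raise ParameterError(f"unknown taxon policy {taxon_policy!r}")
    if taxon_policy == "drop-incomplete":
        taxa = [t for t in alignments[0].taxa]
        shared = set(taxa)
        for a in alignments[1:]:
            shared &= set(a.taxa)
        taxa = [t for t in alignments[0].taxa if t in shared]
        if not taxa:
            raise ParameterError("no taxon is present in every gene alignment")
    else:
        taxa = []
        for a in alignments:
            for t in a.taxa:
                if t not in taxa:
                    taxa.append(t)
    parts: Dict[str, Tuple[int, int]] = {}
    rows = {t: [] for t in taxa}
    offset = 0
    for k, a in enumerate(alignments):
        gene = a.name or f"gene{k + 1}"
        if gene in parts:
            raise ParameterError(f"duplicate gene name {gene!r}")
        parts[gene] = (offset, offset + a.length)
        for t in taxa:
            rows[t].append(a.row(t) if t in a.taxa else GAP * a.length)
        offset += a.length
    alignment = MultipleAlignment(
        taxa=taxa,
        rows=["".join(rows[t]) for t in taxa],
        alphabet=alignments[0].alphabet,
    )
    return Supermatrix(alignment=alignment, partitions=parts)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _to_matrix(aln: MultipleAlignment) -> np.ndarray:
    return np.array(
        [np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in aln.rows]
    )


def _valid_mask(mat: np.ndarray, alphabet: str) -> np.ndarray:
    if alphabet == "nt":
        valid = np.zeros(mat.shape, dtype=bool)
        for c in b"ACGT":
            valid |= mat == c
        return valid
    bad = (mat == ord(GAP)) | (mat == ord("X")) | (mat == ord("*")) | (mat == ord("."))
    return ~bad


def distance_matrix(
    data,
    model: str = "jc",
    saturation_cap: float = DEFAULT_SATURATION_CAP,
) -> DistanceMatrix:
    """Pairwise distances under p, Jukes-Cantor, Kimura-2P or Poisson models.

    Pairwise deletion: each pair uses the columns where both taxa carry an
    unambiguous residue.  Pairs whose correction is undefined (log of a
    non-positive argument) are flagged saturated and capped.
    """
    aln = data.alignment if isinstance(data, Supermatrix) else data
    if len(aln.taxa) < 2:
        raise ParameterError("need >= 2 taxa")
    if aln.alphabet == "nt" and model not in NT_MODELS:
        raise ParameterError(f"model {model!r} not valid for nucleotides")
    if aln.alphabet == "aa" and model not in AA_MODELS:
        raise ParameterError(f"model {model!r} not valid for amino acids")
    mat = _to_matrix(aln)
    valid = _valid_mask(mat, aln.alphabet)
    n = len(aln.taxa)
    values = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total = int(both.sum())
            if total == 0:
                raise ParameterError(
                    f"no comparable columns between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
                )
            diff = mat[i, both] != mat[j, both]
            p = float(diff.sum()) / total
            d, sat = _correct(p, mat[i, both], mat[j, both], model, saturation_cap)
            values[i, j] = values[j, i] = d
            saturated[i, j] = saturated[j, i] = sat
    return DistanceMatrix(taxa=list(aln.taxa), values=values, saturated=saturated)


_PURINES = (ord("A"), ord("G"))


def _correct(p, ci, cj, model, cap):
    if model == "p":
        return p, False
    if model == "jc":
        arg = 1.0 - (4.0 / 3.0) * p
        if arg <= 0:
            return cap, True
        return -0.75 * math.log(arg), False
    if model == "poisson":
        arg = 1.0 - p
        if arg <= 0:
            return cap, True
        return -math.log(arg), False
    if model == "k2p":
        diff = ci != cj
        pur_i = np.isin(ci, _PURINES)
        pur_j = np.isin(cj, _PURINES)
        transitions = diff & (pur_i == pur_j)
        P = float(transitions.sum()) / len(ci)
        Q = p - P
        a1 = 1.0 - 2.0 * P - Q
        a2 = 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            return cap, True
        return -0.5 * math.log(a1) - 0.25 * math.log(a2), False
    raise ParameterError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _clamp_pair(la: float, lb: float) -> Tuple[float, float]:
    """Clamp negative branch lengths to 0, moving the deficit to the sister."""
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def nj_tree(d: DistanceMatrix, outgroup: Optional[str] = None) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining.

    Joins minimize the Q criterion (ties break on the smallest taxon-index
    pair); negative branch lengths are clamped to zero with the deficit
    transferred to the sister branch.  With an outgroup the tree is rooted
    at the midpoint of the outgroup's pendant edge.
    """
    n = len(d.taxa)
    if n < 3:
        raise ParameterError("need >= 3 taxa")
    if outgroup is not None and outgroup not in d.taxa:
        raise ParameterError(f"outgroup {outgroup!r} not among taxa")
    D = d.values.astype(float).copy()
    labels: List[str] = [_quote(t) for t in d.taxa]
    active = list(range(n))
    newick_of: Dict[int, str] = {i: labels[i] for i in range(n)}
    D_full = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    next_id = n

    def dist(i, j):
        return D_full[(i, j)] if i <= j else D_full[(j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, j) for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        u = next_id
        next_id += 1
        newick_of[u] = f"({newick_of[i]}:{_fmt(li)},{newick_of[j]}:{_fmt(lj)})"
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dist(i, k) + dist(j, k) - dij)
            key = (min(u, k), max(u, k))
            D_full[key] = duk
        D_full[(u, u)] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    dij, dik, djk = dist(i, j), dist(i, k), dist(j, k)
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    li, lj = _clamp_pair(li, lj)
    lk = max(lk, 0.0)
    newick = (
        f"({newick_of[i]}:{_fmt(li)},{newick_of[j]}:{_fmt(lj)},"
        f"{newick_of[k]}:{_fmt(lk)});"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    if outgroup is not None:
        _root_on_outgroup(tree, outgroup)
    return PhyloTree(tree=tree, taxa=list(d.taxa))


def _root_on_outgroup(tree: dendropy.Tree, outgroup: str) -> None:
    node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == outgroup:
            node = leaf
            break
    if node is None:
        raise ParameterError(f"outgroup {outgroup!r} not found in tree")
    edge = node.edge
    length = edge.length or 0.0
    tree.is_rooted = True
    tree.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0)


def tree_splits(tree: dendropy.Tree, taxa: Sequence[str]) -> Set[FrozenSet[str]]:
    """Non-trivial bipartitions, each canonicalized to the side without the anchor."""
    all_taxa = frozenset(taxa)
    anchor = min(taxa)
    splits: Set[FrozenSet[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = all_taxa - side
        if 1 < len(side) < len(all_taxa) - 1:
            splits.add(side)
    return splits


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Symmetric-difference (RF) distance between two trees on the same taxa."""
    if set(a.taxa) != set(b.taxa):
        raise ParameterError("trees are on different taxon sets")
    return len(a.splits() ^ b.splits())


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _resample_columns(
    sm: Supermatrix, rng: np.random.Generator, gene_resampling: bool
) -> MultipleAlignment:
    aln = sm.alignment
    L = aln.length
    if gene_resampling:
        genes = list(sm.partitions)
        picked = rng.choice(len(genes), size=len(genes), replace=True)
        cols: List[np.ndarray] = [
            np.arange(*sm.partitions[genes[g]]) for g in picked
        ]
        idx = np.concatenate(cols)
    else:
        idx = rng.integers(0, L, size=L)
    mat = _to_matrix(aln)[:, idx]
    rows = [bytes(row).decode("ascii") for row in mat]
    return MultipleAlignment(taxa=list(aln.taxa), rows=rows, alphabet=aln.alphabet)


def bootstrap_support(
    sm: Supermatrix,
    n_reps: int,
    model: str = "jc",
    seed: int = 0,
    outgroup: Optional[str] = None,
    gene_resampling: bool = False,
    saturation_cap: float = DEFAULT_SATURATION_CAP,
) -> PhyloTree:
    """NJ point tree with nonparametric bootstrap supports (0-100).

    Columns are resampled with replacement across the whole supermatrix
    (genes instead when ``gene_resampling``); support for each internal
    bipartition of the point tree is the percentage of replicate NJ trees
    containing it.  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    point = nj_tree(distance_matrix(sm, model, saturation_cap), outgroup=outgroup)
    target = point.splits()
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep_aln = _resample_columns(sm, rng, gene_resampling)
        rep_dm = distance_matrix(rep_aln, model, saturation_cap)
        rep_tree = nj_tree(rep_dm)
        rep_splits = rep_tree.splits()
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    _annotate_supports(point, supports)
    point.supports = supports
    return point


def _annotate_supports(point: PhyloTree, supports: Mapping[FrozenSet[str], float]) -> None:
    all_taxa = frozenset(point.taxa)
    anchor = min(point.taxa)
    for node in point.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = all_taxa - side
        if side in supports:
            node.label = f"{supports[side]:.0f}"
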