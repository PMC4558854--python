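"""Synthetic genome-evolution generator.

Produces clades of annotated bacterial genomes descended from a known
ancestral gene repertoire, with per-branch gene loss and gain and codon-level
sequence divergence at a controlled dN/dS, plus a ground-truth table for
parameter-recovery tests.  The regime it emulates is a pair of related
enterobacterial genera plus a gene-poor, host-associated relative: thousands
of single-copy genes, modest within-genus divergence, and a reduced genome
that has shed a noticeable fraction of the ancestral core.

The codon substitution process is proposal/acceptance: a kappa-weighted
single-nucleotide change is proposed, accepted with probability 1 if
synonymous and omega (relative) if nonsynonymous, and always rejected if it
would create a stop codon.  Branch lengths are expected *accepted*
substitutions per codon.  Gained genes are simulated de novo, never copied,
so they can never be reciprocal-best-hit partners of ancestral loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from . import genetics
from .errors import ParameterError
from .similarity import GeneRecord

ANCESTOR_ID = "ancestor"

#: COG-style functional category labels with sampling weights; the mix leans
#: on the classes that matter for loss accounting in reduced genomes.
DEFAULT_CATEGORY_WEIGHTS: Dict[str, float] = {
    "hypothetical": 0.35,
    "amino acid transport and metabolism": 0.08,
    "carbohydrate transport and metabolism": 0.07,
    "coenzyme metabolism": 0.04,
    "energy production and conversion": 0.05,
    "translation": 0.06,
    "transcription": 0.04,
    "replication, recombination and repair": 0.05,
    "signal transduction": 0.03,
    "motility": 0.03,
    "virulence": 0.02,
    "posttranslational modification": 0.03,
    "cell wall/membrane biogenesis": 0.05,
    "inorganic ion transport": 0.03,
    "nucleotide metabolism": 0.03,
    "lipid metabolism": 0.04,
}


@dataclass
class AncestralRepertoire:
    """The gene repertoire of the clade's last common ancestor."""

    genes: List[GeneRecord]
    gc_target: float

    def locus_ids(self) -> List[str]:
        return [g.locus_id for g in self.genes]

    def validate(self) -> None:
        seen = set()
        for g in self.genes:
            if g.locus_id in seen:
                raise ParameterError(f"duplicate locus id {g.locus_id!r}")
            seen.add(g.locus_id)
            if len(g.seq) % 3 or len(g.seq) < 150:
                raise ParameterError(f"{g.locus_id}: length must be a multiple of 3 and >= 150 nt")
            codons = genetics.encode_codons(g.seq)
            if genetics.CODONS[codons[0]] != "ATG":
                raise ParameterError(f"{g.locus_id}: does not start with ATG")
            if genetics.IS_STOP[codons].any():
                raise ParameterError(f"{g.locus_id}: internal stop codon")


@dataclass
class EvolutionScenario:
    """Tree plus per-branch event rates for one simulated clade.

    ``tree`` is a rooted newick string with branch lengths in expected
    accepted substitutions per codon.  Per-branch overrides are keyed by the
    name of the branch's child node (leaf name, or internal node label).
    """

    tree: str
    loss_prob: float = 0.05
    gain_rate: float = 10.0
    omega: float = 0.2
    kappa: float = 2.0
    seed: int = 0
    loss_overrides: Dict[str, float] = field(default_factory=dict)
    gain_overrides: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.loss_prob <= 1.0:
            raise ParameterError("loss_prob must be in [0, 1]")
        for v in self.loss_overrides.values():
            if not 0.0 <= v <= 1.0:
                raise ParameterError("loss override must be in [0, 1]")
        if self.gain_rate < 0 or any(v < 0 for v in self.gain_overrides.values()):
            raise ParameterError("gain rates must be >= 0")
        if self.omega <= 0:
            raise ParameterError("omega must be > 0")
        if self.kappa <= 0:
            raise ParameterError("kappa must be > 0")


@dataclass
class TruthTable:
    """Ground truth emitted alongside simulated genomes.

    ``inventories[leaf][locus]`` is ``"ancestral"`` or ``"gained@<branch>"``.
    ``clades`` maps every internal-node label (and ``"root"``) to its leaf
    set; the true core of a clade is the intersection of its leaf
    inventories restricted to ancestral loci.
    """

    ancestral_loci: Set[str]
    inventories: Dict[str, Dict[str, str]]
    clades: Dict[str, Tuple[str, ...]] = field(default_factory=dict)
    branch_events: Dict[str, Dict[str, List[str]]] = field(default_factory=dict)

    def core_of(self, leaves: Sequence[str]) -> Set[str]:
        core = set(self.ancestral_loci)
        for leaf in leaves:
            inv = self.inventories[leaf]
            core &= {l for l, prov in inv.items() if prov == "ancestral"}
        return core

    def clade_core(self, name: str) -> Set[str]:
        return self.core_of(self.clades[name])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("leaf\tlocus\tprovenance\tancestral_locus\n")
            for leaf in sorted(self.inventories):
                for locus, prov in sorted(self.inventories[leaf].items()):
                    anc = locus if prov == "ancestral" else ""
                    fh.write(f"{leaf}\t{locus}\t{prov}\t{anc}\n")

    @classmethod
    def from_tsv(cls, path, clades: Optional[Mapping[str, Sequence[str]]] = None) -> "TruthTable":
        inventories: Dict[str, Dict[str, str]] = {}
        ancestral: Set[str] = set()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("leaf\t"):
                raise ParameterError(f"{path}: not a truth table")
            for line in fh:
                leaf, locus, prov, anc = line.rstrip("\n").split("\t")
                inventories.setdefault(leaf, {})[locus] = prov
                if anc:
                    ancestral.add(anc)
        return cls(
            ancestral_loci=ancestral,
            inventories=inventories,
            clades={k: tuple(v) for k, v in (clades or {}).items()},
        )


# ---------------------------------------------------------------------------
# ancestor simulation
# ---------------------------------------------------------------------------

def _codon_probs(gc_target: float) -> np.ndarray:
    """Probabilities over sense codons from independent nucleotide frequencies."""
    g = c = gc_target / 2.0
    a = t = (1.0 - gc_target) / 2.0
    freqs = np.array([a, c, g, t])
    probs = np.empty(len(genetics.SENSE_CODONS))
    for i, codon in enumerate(genetics.SENSE_CODONS):
        p = 1.0
        for ch in codon:
            p *= freqs["ACGT".index(ch)]
        probs[i] = p
    return probs / probs.sum()


def _random_genes(
    rng: np.random.Generator,
    n_genes: int,
    mean_len_codons: int,
    gc_target: float,
    prefix: str,
    genome_id: str,
    category_weights: Mapping[str, float] = DEFAULT_CATEGORY_WEIGHTS,
) -> List[GeneRecord]:
    probs = _codon_probs(gc_target)
    sense = np.array([genetics.CODON_INDEX[c] for c in genetics.SENSE_CODONS])
    cats = list(category_weights)
    cat_p = np.array([category_weights[c] for c in cats])
    cat_p = cat_p / cat_p.sum()
    extra_mean = max(mean_len_codons - 50, 0)
    genes = []
    width = max(5, len(str(n_genes)))
    for i in range(n_genes):
        if extra_mean > 0:
            length = 50 + int(rng.geometric(1.0 / (extra_mean + 1))) - 1
        else:
            length = 50
        body = sense[rng.choice(len(sense), size=length - 1, p=probs)]
        codons = np.concatenate(([genetics.CODON_INDEX["ATG"]], body))
        category = cats[int(rng.choice(len(cats), p=cat_p))]
        genes.append(
            GeneRecord(
                locus_id=f"{prefix}{i + 1:0{width}d}",
                genome_id=genome_id,
                seq=genetics.decode_codons(codons),
                category=category,
            )
        )
    return genes


def simulate_ancestor(
    n_genes: int,
    mean_len_codons: int = 120,
    gc_target: float = 0.53,
    seed: int = 0,
    category_weights: Mapping[str, float] = DEFAULT_CATEGORY_WEIGHTS,
) -> AncestralRepertoire:
    """Simulate the ancestral gene repertoire.

    Codons are drawn from independent nucleotide frequencies tuned to
    ``gc_target`` (stops excluded, ATG start); gene lengths are geometric
    around ``mean_len_codons`` with a 50-codon floor.  Deterministic given
    ``seed``.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    if mean_len_codons < 50:
        raise ParameterError("mean_len_codons must be >= 50")
    if not 0.0 < gc_target < 1.0:
        raise ParameterError("gc_target must be in (0, 1)")
    rng = np.random.default_rng(seed)
    genes = _random_genes(
        rng, n_genes, mean_len_codons, gc_target, "anc", ANCESTOR_ID, category_weights
    )
    return AncestralRepertoire(genes=genes, gc_target=gc_target)


# ---------------------------------------------------------------------------
# codon substitution machinery
# ---------------------------------------------------------------------------

def _neighbor_tables():
    """Static proposal tables: for each codon, its 9 single-nucleotide neighbors."""
    neigh = np.zeros((64, 9), dtype=np.int64)
    is_ts = np.zeros((64, 9), dtype=bool)
    # type: 0 synonymous, 1 nonsynonymous, 2 stop
    ptype = np.zeros((64, 9), dtype=np.int64)
    for c in range(64):
        nts = [(c >> 4) & 3, (c >> 2) & 3, c & 3]
        k = 0
        for pos in range(3):
            cur = nts[pos]
            for alt in range(4):
                if alt == cur:
                    continue
                new_nts = list(nts)
                new_nts[pos] = alt
                nc = new_nts[0] * 16 + new_nts[1] * 4 + new_nts[2]
                neigh[c, k] = nc
                is_ts[c, k] = genetics.is_transition(cur, alt)
                if genetics.IS_STOP[nc]:
                    ptype[c, k] = 2
                elif genetics.AA_BY_INDEX[nc] == genetics.AA_BY_INDEX[c]:
                    ptype[c, k] = 0
                else:
                    ptype[c, k] = 1
                k += 1
    return neigh, is_ts, ptype


_NEIGH, _IS_TS, _PTYPE = _neighbor_tables()


def _proposal_weights(kappa: float) -> np.ndarray:
    w = np.where(_IS_TS, kappa, 1.0)
    return w / w.sum(axis=1, keepdims=True)


def _acceptance_by_codon(kappa: float, omega: float) -> np.ndarray:
    """Expected acceptance probability per current codon."""
    amax = max(1.0, omega)
    acc = np.array([1.0 / amax, omega / amax, 0.0])
    w = _proposal_weights(kappa)
    return (w * acc[_PTYPE]).sum(axis=1)


def evolve_codon_arrays(
    arrays: Sequence[np.ndarray],
    t: float,
    omega: float,
    kappa: float,
    rng: np.random.Generator,
    mean_accept: Optional[float] = None,
) -> List[np.ndarray]:
    """Apply the proposal/acceptance substitution process to codon arrays.

    ``t`` is the expected number of accepted substitutions per codon.  The
    proposal intensity is rescaled by the mean acceptance probability over
    the input codon composition (uniformization), so realized divergence
    tracks ``t`` without per-codon rate bookkeeping.
    """
    if t < 0:
        raise ParameterError("branch length must be >= 0")
    if not arrays or t == 0:
        return [a.copy() for a in arrays]
    flat = np.concatenate(arrays)
    acc_by_codon = _acceptance_by_codon(kappa, omega)
    if mean_accept is None:
        mean_accept = float(acc_by_codon[flat].mean())
    t_prop = t / mean_accept
    counts = rng.poisson(t_prop, size=flat.shape[0])
    w = _proposal_weights(kappa)
    wcum = np.cumsum(w, axis=1)
    amax = max(1.0, omega)
    accept_p = np.array([1.0 / amax, omega / amax, 0.0])
    remaining = counts.copy()
    while True:
        active = np.nonzero(remaining > 0)[0]
        if active.size == 0:
            break
        cur = flat[active]
        u = rng.random(active.size)
        j = (u[:, None] > wcum[cur]).sum(axis=1)
        proposed = _NEIGH[cur, j]
        ptype = _PTYPE[cur, j]
        accepted = rng.random(active.size) < accept_p[ptype]
        flat[active] = np.where(accepted, proposed, cur)
        remaining[active] -= 1
    out = []
    offset = 0
    for a in arrays:
        out.append(flat[offset : offset + a.shape[0]].copy())
        offset += a.shape[0]
    return out


# ---------------------------------------------------------------------------
# clade evolution
# ---------------------------------------------------------------------------

def _parse_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ParameterError("tree must have >= 2 leaves")
    if len(set(leaves)) != len(leaves):
        raise ParameterError("leaf names must be unique")
    counter = [0]
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node._symcore_name = node.taxon.label
        elif node.label:
            node._symcore_name = node.label
        elif node.parent_node is None:
            node._symcore_name = "root"
        else:
            counter[0] += 1
            node._symcore_name = f"node{counter[0]}"
        if node.edge.length is not None and node.edge.length < 0:
            raise ParameterError("branch lengths must be >= 0")
    return tree


def evolve_clade(
    ancestor: AncestralRepertoire, scenario: EvolutionScenario
) -> Tuple[Dict[str, List[GeneRecord]], TruthTable]:
    """Evolve an ancestor down a tree with loss, gain and codon substitution.

    Returns per-leaf CDS sets (keyed by leaf name) and the truth table.
    Deterministic given ``scenario.seed``; the tree is traversed preorder and
    one generator drives every stochastic choice.
    """
    if not ancestor.genes:
        raise ParameterError("ancestor has no genes")
    tree = _parse_tree(scenario.tree)
    # independent stream from the ancestor's even when the seeds coincide,
    # so gained genes can never replay the ancestral codon draws
    rng = np.random.default_rng(
        np.random.SeedSequence(scenario.seed, spawn_key=(1,))
    )
    mean_len = int(round(np.mean([len(g.seq) // 3 for g in ancestor.genes])))

    # state per node: list of (locus_id, provenance, category, codon_array)
    root_state = [
        (g.locus_id, "ancestral", g.category, genetics.encode_codons(g.seq))
        for g in ancestor.genes
    ]
    acc_by_codon = _acceptance_by_codon(scenario.kappa, scenario.omega)
    flat_root = np.concatenate([s[3] for s in root_state])
    mean_accept = float(acc_by_codon[flat_root].mean())

    genomes: Dict[str, List[GeneRecord]] = {}
    inventories: Dict[str, Dict[str, str]] = {}
    branch_events: Dict[str, Dict[str, List[str]]] = {}

    def descend(node, state):
        name = node._symcore_name
        if node.parent_node is not None:
            t = node.edge.length or 0.0
            loss_p = scenario.loss_overrides.get(name, scenario.loss_prob)
            gain_r = scenario.gain_overrides.get(name, scenario.gain_rate)
            arrays = [s[3] for s in state]
            evolved = evolve_codon_arrays(
                arrays, t, scenario.omega, scenario.kappa, rng, mean_accept
            )
            state = [
                (lid, prov, cat, arr)
                for (lid, prov, cat, _), arr in zip(state, evolved)
            ]
            keep = rng.random(len(state)) >= loss_p
            lost = [s[0] for s, k in zip(state, keep) if not k]
            state = [s for s, k in zip(state, keep) if k]
            n_gain = int(rng.poisson(gain_r))
            gained: List[str] = []
            if n_gain:
                new = _random_genes(
                    rng, n_gain, mean_len, ancestor.gc_target,
                    f"gain_{name}_", "gained",
                )
                for g in new:
                    state.append(
                        (g.locus_id, f"gained@{name}", g.category,
                         genetics.encode_codons(g.seq))
                    )
                    gained.append(g.locus_id)
            branch_events[name] = {"lost": lost, "gained": gained}
        if node.is_leaf():
            genomes[name] = [
                GeneRecord(
                    locus_id=lid, genome_id=name,
                    seq=genetics.decode_codons(arr), category=cat,
                )
                for lid, prov, cat, arr in state
            ]
            inventories[name] = {lid: prov for lid, prov, _, _ in state}
        else:
            for child in node.child_nodes():
                descend(child, state)

    descend(tree.seed_node, root_state)

    clades: Dict[str, Tuple[str, ...]] = {}
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            clades[node._symcore_name] = tuple(
                lf.taxon.label for lf in node.leaf_iter()
            )
    if "root" not in clades:
        clades["root"] = tuple(lf.taxon.label for lf in tree.leaf_node_iter())

    truth = TruthTable(
        ancestral_loci={g.locus_id for g in ancestor.genes},
        inventories=inventories,
        clades=clades,
        branch_events=branch_events,
    )
    return genomes, truth


def write_fixture(
    genomes: Mapping[str, Sequence[GeneRecord]], truth: TruthTable, out_dir
) -> Dict[str, Dict[str, str]]:
    """Write one CDS FASTA + one category TSV per genome and one truth TSV.

    Returns a manifest mapping genome id to its file paths.  Round-trips
    losslessly through :func:`symcore.io.read_cds_fasta`.
    """
    from . import io as sio

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ParameterError(f"cannot create output directory {out}: {exc}") from exc
    manifest: Dict[str, Dict[str, str]] = {}
    for genome_id in sorted(genomes):
        records = genomes[genome_id]
        fasta = out / f"{genome_id}.fasta"
        cats = out / f"{genome_id}.categories.tsv"
        sio.write_cds_fasta(records, fasta)
        sio.write_category_tsv(records, cats)
        manifest[genome_id] = {"fasta": str(fasta), "categories": str(cats)}
    truth_path = out / "truth.tsv"
    truth.to_tsv(truth_path)
    manifest["__truth__"] = {"truth": str(truth_path)}
    return manifest
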