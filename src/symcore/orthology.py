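"""Reciprocal-best-hit orthology, genus core genomes, last-common-ancestor
core reconstruction by intersection, and retained/lost gene accounting.

Orthology here is operational: two genes in different genomes are orthologs
when each is the other's highest-scoring match (RBH).  Core genomes are
expressed in the coordinates of a caller-designated reference genome, which
keeps intersections well-defined without multi-genome clustering; paralog
copy number is deliberately ignored (presence/absence only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .errors import ParameterError
from .similarity import BestHitMap, GeneRecord

#: category label used for loci without an assigned functional category
HYPOTHETICAL = "hypothetical"


@dataclass
class OrthologTable:
    """One-to-one reciprocal best hits between two genomes."""

    a_id: str
    b_id: str
    pairs: List[Tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def a_to_b(self) -> Dict[str, str]:
        return dict(self.pairs)

    def b_to_a(self) -> Dict[str, str]:
        return {b: a for a, b in self.pairs}

    def swapped(self) -> "OrthologTable":
        return OrthologTable(
            a_id=self.b_id, b_id=self.a_id, pairs=[(b, a) for a, b in self.pairs]
        )


@dataclass
class CoreGenome:
    """Loci of a reference genome conserved across all member genomes."""

    clade: str
    reference: str
    loci: Set[str]
    members: List[str]

    def __len__(self) -> int:
        return len(self.loci)


@dataclass
class LossLedger:
    """Partition of an ancestral core into retained and lost loci for a target."""

    lca_reference: str
    target: str
    lca_size: int
    retained: Set[str]
    lost: Set[str]
    lost_by_category: Dict[str, int]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_lost(self) -> int:
        return len(self.lost)


def reciprocal_best_hits(best_ab: BestHitMap, best_ba: BestHitMap) -> OrthologTable:
    """Pairs (x, y) with best_ab[x] = y and best_ba[y] = x.

    One-to-one by construction.  The two maps must cover the same two
    genomes in opposite directions.
    """
    if (
        best_ab.query_genome != best_ba.subject_genome
        or best_ab.subject_genome != best_ba.query_genome
    ):
        raise ParameterError(
            "best-hit maps do not describe the same genome pair in opposite "
            f"directions: ({best_ab.query_genome}->{best_ab.subject_genome}) vs "
            f"({best_ba.query_genome}->{best_ba.subject_genome})"
        )
    pairs = []
    for x, hit in best_ab.hits.items():
        y = hit.subject_locus
        back = best_ba.hits.get(y)
        if back is not None and back.subject_locus == x:
            pairs.append((x, y))
    pairs.sort()
    return OrthologTable(
        a_id=best_ab.query_genome, b_id=best_ab.subject_genome, pairs=pairs
    )


def genus_core(
    reference: Sequence[GeneRecord],
    members: Sequence[str],
    tables: Sequence[OrthologTable],
    clade: str = "",
) -> CoreGenome:
    """Reference loci with an RBH partner in every member genome.

    ``tables`` must contain an ortholog table linking the reference to each
    member; a missing table is an error, never an implicit absence.  A member
    equal to the reference itself is trivially satisfied.
    """
    ref_ids = {r.genome_id for r in reference}
    if len(ref_ids) != 1:
        raise ParameterError("reference records must come from one genome")
    ref_id = ref_ids.pop()
    by_member: Dict[str, OrthologTable] = {}
    for t in tables:
        if t.a_id == ref_id:
            by_member[t.b_id] = t
        elif t.b_id == ref_id:
            by_member[t.a_id] = t.swapped()
    loci = {r.locus_id for r in reference}
    for m in members:
        if m == ref_id:
            continue
        if m not in by_member:
            raise ParameterError(f"no ortholog table for member genome {m!r}")
        loci &= set(by_member[m].a_to_b())
    return CoreGenome(
        clade=clade or ref_id, reference=ref_id, loci=loci, members=list(members)
    )


def lca_core(
    core_a: CoreGenome, core_b: CoreGenome, bridge: OrthologTable, clade: str = "LCA"
) -> CoreGenome:
    """Intersection of two genus cores, in core_a's reference coordinates.

    A locus of core_a survives when its bridge RBH partner lies in core_b.
    """
    if bridge.a_id == core_a.reference and bridge.b_id == core_b.reference:
        mapping = bridge.a_to_b()
    elif bridge.b_id == core_a.reference and bridge.a_id == core_b.reference:
        mapping = bridge.b_to_a()
    else:
        raise ParameterError(
            f"bridge links {bridge.a_id!r}-{bridge.b_id!r}, expected "
            f"{core_a.reference!r}-{core_b.reference!r}"
        )
    loci = {
        a for a in core_a.loci if mapping.get(a) is not None and mapping[a] in core_b.loci
    }
    return CoreGenome(
        clade=clade,
        reference=core_a.reference,
        loci=loci,
        members=list(dict.fromkeys(core_a.members + core_b.members)),
    )


def loss_accounting(
    lca: CoreGenome,
    table: OrthologTable,
    target: str,
    categories: Optional[Mapping[str, str]] = None,
) -> LossLedger:
    """Split the ancestral core into loci retained vs lost by ``target``.

    ``table`` is the RBH table between the core's reference genome and the
    target.  Per-category lost counts use ``categories`` (reference locus ->
    label); loci without a label count under ``"hypothetical"``.
    """
    if table.a_id == lca.reference and table.b_id == target:
        mapping = table.a_to_b()
    elif table.b_id == lca.reference and table.a_id == target:
        mapping = table.b_to_a()
    else:
        raise ParameterError(
            f"ortholog table links {table.a_id!r}-{table.b_id!r}, expected "
            f"{lca.reference!r}-{target!r}"
        )
    retained = {l for l in lca.loci if l in mapping}
    lost = lca.loci - retained
    cats = categories or {}
    lost_by_category: Dict[str, int] = {}
    for locus in lost:
        label = cats.get(locus) or HYPOTHETICAL
        lost_by_category[label] = lost_by_category.get(label, 0) + 1
    return LossLedger(
        lca_reference=lca.reference,
        target=target,
        lca_size=len(lca.loci),
        retained=retained,
        lost=lost,
        lost_by_category=lost_by_category,
    )
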