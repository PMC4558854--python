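"""Pipeline driver: chains orthology, core/LCA reconstruction, loss
accounting, pan-genome scanning, the core-locus NJ tree and the genome-wide
dN/dS scan into one deterministic run.

The configuration is one YAML file (see :class:`PipelineConfig`); every
stage writes its tables under the output directory and a run manifest
records versions, thresholds and the seed so a run can be reproduced
bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from . import io as sio
from .errors import ParameterError, PipelineStageError
from .molevol import genome_wide_dnds
from .orthology import (
    CoreGenome,
    LossLedger,
    OrthologTable,
    genus_core,
    lca_core,
    loss_accounting,
    reciprocal_best_hits,
)
from .pangenome import (
    PresenceAbsenceMatrix,
    build_reference_pangenome,
    core_loci,
    scan_presence,
)
from .phylogeny import (
    MultipleAlignment,
    PhyloTree,
    Supermatrix,
    align_gene,
    bootstrap_support,
    concatenate,
    distance_matrix,
    nj_tree,
)
from .similarity import GeneRecord, ScoringParams, best_hits

log = logging.getLogger("symcore.pipeline")


@dataclass
class GenusSpec:
    reference: str
    members: List[str]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``genomes`` maps genome id to its CDS FASTA (and optional category TSV);
    ``genera`` lists at least two genera of at least two member genomes each,
    with a designated reference; ``targets`` are the genomes whose losses
    against the reconstructed LCA core are accounted.
    """

    genomes: Dict[str, Dict[str, Optional[str]]]
    genera: Dict[str, GenusSpec]
    targets: List[str]
    output_dir: str
    seed: int = 0
    identity: float = 0.70
    coverage: float = 0.10
    prevalence: float = 0.90
    saturation: float = 3.0
    min_score: int = 50
    bootstrap_replicates: int = 100
    distance_model: str = "jc"
    concat_policy: str = "pad-gaps"
    outgroup: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thresholds = raw.get("thresholds", {})
        genera = {
            name: GenusSpec(reference=g["reference"], members=list(g["members"]))
            for name, g in raw["genera"].items()
        }
        genomes = {
            gid: {"cds": entry["cds"], "categories": entry.get("categories")}
            for gid, entry in raw["genomes"].items()
        }
        cfg = cls(
            genomes=genomes,
            genera=genera,
            targets=list(raw.get("targets", [])),
            output_dir=raw["output_dir"],
            seed=int(raw.get("seed", 0)),
            identity=float(thresholds.get("identity", 0.70)),
            coverage=float(thresholds.get("coverage", 0.10)),
            prevalence=float(thresholds.get("prevalence", 0.90)),
            saturation=float(thresholds.get("saturation", 3.0)),
            min_score=int(thresholds.get("min_score", 50)),
            bootstrap_replicates=int(raw.get("bootstrap_replicates", 100)),
            distance_model=raw.get("distance_model", "jc"),
            concat_policy=raw.get("concat_policy", "pad-gaps"),
            outgroup=raw.get("outgroup"),
        )
        base = path.parent
        for gid, entry in cfg.genomes.items():
            for key in ("cds", "categories"):
                if entry.get(key) is not None:
                    p = Path(entry[key])
                    if not p.is_absolute():
                        entry[key] = str(base / p)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for frac, name in (
            (self.identity, "identity"), (self.coverage, "coverage"),
            (self.prevalence, "prevalence"),
        ):
            if not 0 < frac <= 1:
                raise ParameterError(f"threshold {name} must be in (0, 1]")
        if self.saturation <= 0 or self.min_score < 0:
            raise ParameterError("invalid saturation / min_score")
        if len(self.genera) < 2:
            raise ParameterError("need >= 2 genera")
        for name, genus in self.genera.items():
            if len(genus.members) < 2:
                raise ParameterError(f"genus {name!r} needs >= 2 member genomes")
            if genus.reference not in genus.members:
                raise ParameterError(f"genus {name!r}: reference must be a member")
            for m in genus.members:
                if m not in self.genomes:
                    raise ParameterError(f"genus {name!r}: unknown genome {m!r}")
        if not self.targets:
            raise ParameterError("need >= 1 target genome")
        for t in self.targets:
            if t not in self.genomes:
                raise ParameterError(f"unknown target genome {t!r}")
        for gid, entry in self.genomes.items():
            if not Path(entry["cds"]).exists():
                raise ParameterError(f"genome {gid!r}: missing CDS file {entry['cds']}")
            if entry.get("categories") and not Path(entry["categories"]).exists():
                raise ParameterError(
                    f"genome {gid!r}: missing category file {entry['categories']}"
                )

    def scoring_params(self) -> ScoringParams:
        return ScoringParams(min_score=self.min_score)


@dataclass
class PipelineResult:
    config: PipelineConfig
    genomes: Dict[str, List[GeneRecord]]
    ortholog_tables: Dict[Tuple[str, str], OrthologTable]
    genus_cores: Dict[str, CoreGenome]
    lca: CoreGenome
    ledgers: Dict[str, LossLedger]
    pangenome: list
    matrix: PresenceAbsenceMatrix
    core_locus_ids: List[str]
    supermatrix: Optional[Supermatrix]
    tree: Optional[PhyloTree]
    dnds: Dict[str, Tuple[pd.DataFrame, Dict[str, float]]]
    manifest_path: str


class _stage:
    """Context manager that names the failing stage and logs boundaries.

    Partial outputs written before the failure stay on disk.
    """

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is None:
            log.info("stage %s: done", self.name)
            return False
        if isinstance(exc, (ParameterError, PipelineStageError)):
            return False
        raise PipelineStageError(f"stage {self.name!r} failed: {exc}") from exc


def rbh_between(
    genes_a: List[GeneRecord], genes_b: List[GeneRecord], params: ScoringParams
) -> OrthologTable:
    """Reciprocal best hits between two genomes (both search directions)."""
    ab = best_hits(genes_a, genes_b, params)
    ba = best_hits(genes_b, genes_a, params)
    return reciprocal_best_hits(ab, ba)


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle under ``output_dir``.

    Fully deterministic given the configuration; stage failures raise
    :class:`PipelineStageError` naming the stage, with outputs written so
    far preserved on disk.
    """
    config.validate()
    params = config.scoring_params()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: List[str] = []

    with _stage("load-genomes"):
        genomes: Dict[str, List[GeneRecord]] = {}
        categories: Dict[str, Dict[str, str]] = {}
        for gid, entry in config.genomes.items():
            recs = sio.read_cds_fasta(entry["cds"], genome_id=gid)
            if entry.get("categories"):
                categories[gid] = sio.read_category_tsv(entry["categories"])
                recs = sio.attach_categories(recs, categories[gid])
            genomes[gid] = recs
            log.info("loaded %s: %d genes", gid, len(recs))

    tables: Dict[Tuple[str, str], OrthologTable] = {}

    def get_table(a: str, b: str) -> OrthologTable:
        if (a, b) in tables:
            return tables[(a, b)]
        if (b, a) in tables:
            return tables[(b, a)].swapped()
        t = rbh_between(genomes[a], genomes[b], params)
        tables[(a, b)] = t
        path = out / f"rbh.{a}.{b}.tsv"
        sio.write_ortholog_table(t, path)
        outputs.append(path.name)
        log.info("RBH %s-%s: %d pairs", a, b, len(t))
        return t

    with _stage("genus-cores"):
        genus_cores: Dict[str, CoreGenome] = {}
        for name, genus in config.genera.items():
            ref = genus.reference
            member_tables = [get_table(ref, m) for m in genus.members if m != ref]
            core = genus_core(genomes[ref], genus.members, member_tables, clade=name)
            genus_cores[name] = core
            path = out / f"core.{name}.tsv"
            sio.write_core_genome(core, path)
            outputs.append(path.name)
            log.info("genus core %s: %d loci (ref %s)", name, len(core), ref)

    with _stage("lca-core"):
        genus_names = list(config.genera)
        lca = genus_cores[genus_names[0]]
        for other in genus_names[1:]:
            bridge = get_table(lca.reference, genus_cores[other].reference)
            lca = lca_core(lca, genus_cores[other], bridge, clade="LCA")
        path = out / "core.LCA.tsv"
        sio.write_core_genome(lca, path)
        outputs.append(path.name)
        log.info("LCA core: %d loci", len(lca))

    with _stage("loss-accounting"):
        ref_categories = categories.get(lca.reference, {})
        ledgers: Dict[str, LossLedger] = {}
        for target in config.targets:
            table = get_table(lca.reference, target)
            ledger = loss_accounting(lca, table, target, ref_categories)
            ledgers[target] = ledger
            lp, cp = sio.write_loss_ledger(ledger, out / f"losses.{target}")
            outputs.extend([Path(lp).name, Path(cp).name])
            log.info(
                "losses %s: %d retained, %d lost of %d",
                target, ledger.n_retained, ledger.n_lost, ledger.lca_size,
            )

    with _stage("pan-genome"):
        pangenome = build_reference_pangenome(
            genomes, config.identity, config.coverage, params
        )
        fasta, members = sio.write_pangenome(pangenome, out / "pangenome")
        outputs.extend([Path(fasta).name, Path(members).name])
        matrix = scan_presence(
            pangenome, genomes, config.identity, config.coverage, params
        )
        path = out / "presence_matrix.tsv"
        sio.write_presence_matrix(matrix, path)
        outputs.append(path.name)
        core_ids = core_loci(matrix, config.prevalence)
        path = out / "core_loci.txt"
        with open(path, "w") as fh:
            fh.write("\n".join(core_ids) + "\n")
        outputs.append(path.name)
        log.info("pan-genome: %d loci, %d core at %.0f%%",
                 len(pangenome), len(core_ids), 100 * config.prevalence)

    with _stage("core-tree"):
        supermatrix = None
        tree = None
        lookup = {gid: {g.locus_id: g for g in genomes[gid]} for gid in genomes}
        alignments: List[MultipleAlignment] = []
        for locus_id in core_ids:
            seqs: Dict[str, str] = {}
            for gid in genomes:
                assigned = matrix.assignments.get((locus_id, gid))
                if assigned is not None:
                    seqs[gid] = lookup[gid][assigned[0]].seq
            if len(seqs) >= 2:
                alignments.append(align_gene(seqs, alphabet="nt", name=locus_id))
        if alignments and len(genomes) >= 3:
            supermatrix = concatenate(alignments, taxon_policy=config.concat_policy)
            path = out / "supermatrix.fasta"
            with open(path, "w") as fh:
                for t, row in zip(
                    supermatrix.alignment.taxa, supermatrix.alignment.rows
                ):
                    fh.write(f">{t}\n{row}\n")
            outputs.append(path.name)
            path = out / "partitions.txt"
            with open(path, "w") as fh:
                for gene, (start, end) in supermatrix.partitions.items():
                    fh.write(f"DNA, {gene} = {start + 1}-{end}\n")
            outputs.append(path.name)
            if config.bootstrap_replicates > 0:
                tree = bootstrap_support(
                    supermatrix,
                    n_reps=config.bootstrap_replicates,
                    model=config.distance_model,
                    seed=config.seed,
                    outgroup=config.outgroup,
                )
            else:
                tree = nj_tree(
                    distance_matrix(supermatrix, config.distance_model),
                    outgroup=config.outgroup,
                )
            path = out / "core_tree.nwk"
            with open(path, "w") as fh:
                fh.write(tree.newick() + "\n")
            outputs.append(path.name)
            log.info("NJ tree over %d taxa, %d core loci",
                     len(supermatrix.alignment.taxa), len(alignments))

    with _stage("dnds"):
        dnds: Dict[str, Tuple[pd.DataFrame, Dict[str, float]]] = {}
        pairs_to_scan: List[Tuple[str, str]] = []
        if len(genus_names) >= 2:
            pairs_to_scan.append(
                (genus_cores[genus_names[0]].reference,
                 genus_cores[genus_names[1]].reference)
            )
        for target in config.targets:
            pairs_to_scan.append((lca.reference, target))
        for a, b in dict.fromkeys(pairs_to_scan):
            table = get_table(a, b)
            if not len(table):
                continue
            df, summary = genome_wide_dnds(
                table, genomes[a], genomes[b],
                saturation_threshold=config.saturation,
            )
            dnds[f"{a}__{b}"] = (df, summary)
            path = out / f"dnds.{a}.{b}.tsv"
            df.to_csv(path, sep="\t", index=False, float_format="%.6g")
            outputs.append(path.name)
            log.info("dN/dS %s-%s: %d pairs, %.0f%% saturated",
                     a, b, summary["n_pairs"], 100 * summary["fraction_saturated"])

    with _stage("manifest"):
        manifest = {
            "package": "symcore",
            "version": __version__,
            "seed": config.seed,
            "thresholds": {
                "identity": config.identity,
                "coverage": config.coverage,
                "prevalence": config.prevalence,
                "saturation": config.saturation,
                "min_score": config.min_score,
            },
            "bootstrap_replicates": config.bootstrap_replicates,
            "distance_model": config.distance_model,
            "concat_policy": config.concat_policy,
            "genera": {n: {"reference": g.reference, "members": g.members}
                       for n, g in config.genera.items()},
            "targets": config.targets,
            "genomes": {gid: len(genomes[gid]) for gid in genomes},
            "results": {
                "genus_core_sizes": {n: len(c) for n, c in genus_cores.items()},
                "lca_core_size": len(lca),
                "losses": {t: {"retained": l.n_retained, "lost": l.n_lost}
                           for t, l in ledgers.items()},
                "pangenome_size": len(pangenome),
                "core_locus_count": len(core_ids),
                "dnds": {k: v[1] for k, v in dnds.items()},
            },
            "outputs": sorted(outputs),
        }
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return PipelineResult(
        config=config,
        genomes=genomes,
        ortholog_tables=tables,
        genus_cores=genus_cores,
        lca=lca,
        ledgers=ledgers,
        pangenome=pangenome,
        matrix=matrix,
        core_locus_ids=core_ids,
        supermatrix=supermatrix,
        tree=tree,
        dnds=dnds,
        manifest_path=str(manifest_path),
    )
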