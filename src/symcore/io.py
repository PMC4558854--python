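"""Readers and writers for the package's on-disk formats.

CDS sets travel as multi-FASTA with ``<genome_id>|<locus_id>`` headers (plain
ids are accepted when the genome id is supplied by the caller); gene
categories as 2-column TSV; ortholog tables, hit tables, presence/absence
matrices and loss ledgers as TSV.  Every writer's output re-parses under the
corresponding reader.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from .errors import FastaFormatError, ParameterError
from .orthology import CoreGenome, LossLedger, OrthologTable
from .pangenome import PanLocus, PresenceAbsenceMatrix
from .similarity import BestHitMap, GeneRecord


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_cds_fasta(path, genome_id: Optional[str] = None) -> List[GeneRecord]:
    """Read a CDS multi-FASTA into GeneRecords (order preserved, uppercased).

    Headers of the form ``genome|locus`` carry their own genome id;
    otherwise the whole id is the locus and ``genome_id`` (or the file stem)
    is used.  An empty file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FastaFormatError(f"{path}: no such file")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaFormatError(
                    f"{path}:{lineno}: expected a '>' header, got {stripped[:30]!r}"
                )
            break
    records: List[GeneRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if "|" in header:
            gid, locus = header.split("|", 1)
        else:
            gid = genome_id or path.stem
            locus = header
        if (gid, locus) in seen:
            raise FastaFormatError(f"{path}: duplicate locus {locus!r} in {gid!r}")
        seen.add((gid, locus))
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"{path}: empty sequence for {header!r}")
        records.append(GeneRecord(locus_id=locus, genome_id=gid, seq=seq))
    return records


def write_cds_fasta(records: Sequence[GeneRecord], path, line_width: int = 70) -> None:
    path = Path(path)
    try:
        with open(path, "w") as fh:
            for r in records:
                fh.write(f">{r.genome_id}|{r.locus_id}\n")
                for i in range(0, len(r.seq), line_width):
                    fh.write(r.seq[i : i + line_width] + "\n")
    except OSError as exc:
        raise ParameterError(f"cannot write FASTA to {path}: {exc}") from exc


def attach_categories(
    records: Sequence[GeneRecord], categories: Mapping[str, str]
) -> List[GeneRecord]:
    """Return copies of ``records`` with categories filled in from a map."""
    return [
        GeneRecord(
            locus_id=r.locus_id,
            genome_id=r.genome_id,
            seq=r.seq,
            category=categories.get(r.locus_id, r.category),
        )
        for r in records
    ]


# ---------------------------------------------------------------------------
# category tables
# ---------------------------------------------------------------------------

def read_category_tsv(path) -> Dict[str, str]:
    path = Path(path)
    out: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line == "locus_id\tcategory":
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParameterError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def write_category_tsv(records: Sequence[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tcategory\n")
        for r in records:
            fh.write(f"{r.locus_id}\t{r.category or ''}\n")


# ---------------------------------------------------------------------------
# hit and ortholog tables
# ---------------------------------------------------------------------------

HIT_COLUMNS = ["query_locus", "subject_locus", "identity", "query_coverage", "score"]


def write_hit_table(hits: BestHitMap, path) -> None:
    """Best-hit table; identity and coverage are percentages."""
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for q in sorted(hits.hits):
            h = hits.hits[q]
            fh.write(
                f"{h.query_locus}\t{h.subject_locus}\t{100 * h.identity:.2f}\t"
                f"{100 * h.query_coverage:.2f}\t{h.score:.0f}\n"
            )


def write_ortholog_table(table: OrthologTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#a={table.a_id}\tb={table.b_id}\n")
        fh.write("a_locus\tb_locus\n")
        for a, b in table.pairs:
            fh.write(f"{a}\t{b}\n")


def read_ortholog_table(path) -> OrthologTable:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#a="):
            raise ParameterError(f"{path}: missing genome-pair header")
        a_part, b_part = first[1:].split("\t")
        a_id = a_part.split("=", 1)[1]
        b_id = b_part.split("=", 1)[1]
        header = fh.readline()
        pairs = []
        for line in fh:
            line = line.rstrip("\n")
            if line:
                a, b = line.split("\t")
                pairs.append((a, b))
    return OrthologTable(a_id=a_id, b_id=b_id, pairs=pairs)


# ---------------------------------------------------------------------------
# core genomes and loss ledgers
# ---------------------------------------------------------------------------

def write_core_genome(core: CoreGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#clade={core.clade}\treference={core.reference}\t"
                 f"members={','.join(core.members)}\n")
        fh.write("locus\n")
        for locus in sorted(core.loci):
            fh.write(locus + "\n")


def read_core_genome(path) -> CoreGenome:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#clade="):
            raise ParameterError(f"{path}: missing core-genome header")
        fields = dict(part.split("=", 1) for part in first[1:].split("\t"))
        fh.readline()
        loci = {line.strip() for line in fh if line.strip()}
    return CoreGenome(
        clade=fields["clade"],
        reference=fields["reference"],
        loci=loci,
        members=[m for m in fields.get("members", "").split(",") if m],
    )


def write_loss_ledger(ledger: LossLedger, path_prefix) -> Tuple[str, str]:
    """Write <prefix>.loci.tsv (locus, status, i.e. the partition) and
    <prefix>.categories.tsv (category, n_lost)."""
    prefix = str(path_prefix)
    loci_path = prefix + ".loci.tsv"
    cat_path = prefix + ".categories.tsv"
    with open(loci_path, "w") as fh:
        fh.write(f"#lca_reference={ledger.lca_reference}\ttarget={ledger.target}\t"
                 f"lca_size={ledger.lca_size}\n")
        fh.write("locus\tstatus\n")
        for locus in sorted(ledger.retained):
            fh.write(f"{locus}\tretained\n")
        for locus in sorted(ledger.lost):
            fh.write(f"{locus}\tlost\n")
    with open(cat_path, "w") as fh:
        fh.write("category\tn_lost\n")
        for cat in sorted(ledger.lost_by_category):
            fh.write(f"{cat}\t{ledger.lost_by_category[cat]}\n")
    return loci_path, cat_path


# ---------------------------------------------------------------------------
# pan-genome artefacts
# ---------------------------------------------------------------------------

def write_pangenome(pangenome: Sequence[PanLocus], path_prefix) -> Tuple[str, str]:
    """Write <prefix>.representatives.fasta and <prefix>.members.tsv."""
    prefix = str(path_prefix)
    fasta = prefix + ".representatives.fasta"
    members = prefix + ".members.tsv"
    reps = [
        GeneRecord(locus_id=p.locus_id, genome_id="pan", seq=p.representative.seq)
        for p in pangenome
    ]
    write_cds_fasta(reps, fasta)
    with open(members, "w") as fh:
        fh.write("pan_locus\tgenome_id\tlocus_id\n")
        for p in pangenome:
            for gid, locus in p.members:
                fh.write(f"{p.locus_id}\t{gid}\t{locus}\n")
    return fasta, members


def write_presence_matrix(matrix: PresenceAbsenceMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="locus")


def read_presence_matrix(path) -> PresenceAbsenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="locus")
    return PresenceAbsenceMatrix(
        loci=list(df.index),
        genomes=list(df.columns),
        cells=df.to_numpy(dtype=bool),
    )
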