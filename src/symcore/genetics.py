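"""Genetic-code tables (bacterial code, translation table 11) shared by the
simulator and the dN/dS estimator."""

from __future__ import annotations

from itertools import product
from typing import Dict, List

import numpy as np
from Bio.Data import CodonTable

NUCS = "ACGT"

#: all 64 codons in lexicographic ACGT order
CODONS: List[str] = ["".join(p) for p in product(NUCS, repeat=3)]
CODON_INDEX: Dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_table = CodonTable.unambiguous_dna_by_id[11]

STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS: List[str] = [c for c in CODONS if c not in STOP_CODONS]

#: amino acid per codon index; '*' for stops
AA_BY_INDEX: List[str] = [
    "*" if c in STOP_CODONS else _table.forward_table[c] for c in CODONS
]

IS_STOP = np.array([c in STOP_CODONS for c in CODONS], dtype=bool)

#: purine/pyrimidine class per nucleotide index (A=0,G=2 purines)
_PURINE = {0: True, 1: False, 2: True, 3: False}


def is_transition(x: int, y: int) -> bool:
    """True when the nucleotide change x->y is a transition."""
    return x != y and _PURINE[x] == _PURINE[y]


def codon_str(idx: int) -> str:
    return CODONS[idx]


def encode_codons(seq: str) -> np.ndarray:
    """Encode an in-frame nucleotide string as an array of codon indices.

    Raises ValueError on length not divisible by 3 or ambiguous letters.
    """
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    lut = {c: i for i, c in enumerate(NUCS)}
    try:
        nts = [lut[c] for c in seq.upper()]
    except KeyError as exc:
        raise ValueError(f"non-ACGT letter {exc.args[0]!r} in codon sequence") from exc
    arr = np.asarray(nts, dtype=np.int64).reshape(-1, 3)
    return arr[:, 0] * 16 + arr[:, 1] * 4 + arr[:, 2]


def decode_codons(arr: np.ndarray) -> str:
    return "".join(CODONS[i] for i in arr)


def translate(seq: str) -> str:
    """Translate an in-frame CDS (table 11); stops become '*'."""
    return "".join(AA_BY_INDEX[i] for i in encode_codons(seq))
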