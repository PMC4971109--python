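"""Genetic-code bookkeeping shared by every codon-level computation.

The standard bacterial code (NCBI translation table 11) is identical to the
universal code over the 61 sense codons; degeneracy families, class sizes and
the 59 informative codons (sense minus ATG/TGG) are precomputed once and
reused everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = "TCAG"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; accepts RNA (U) and returns DNA."""
    return seq.translate(_COMPLEMENT)[::-1]


# per-codon one-hot base identity, shape (64, 3, 4) in TCAG order; used to
# turn a 64-vector of codon counts into positional nucleotide counts
POSITION_ONEHOT = np.zeros((64, 3, 4), dtype=np.int64)
for _i, _codon in enumerate(CODONS):
    for _p, _b in enumerate(_codon):
        POSITION_ONEHOT[_i, _p, BASE_INDEX[_b]] = 1


@dataclass(frozen=True)
class GeneticCode:
    """Codon->amino-acid map plus the degeneracy structure derived from it."""

    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    families: dict[str, tuple[str, ...]]            # aa -> sense codons
    degeneracy_classes: dict[int, tuple[str, ...]]  # family size -> aas
    informative_codons: tuple[str, ...]             # 59 codons, CODONS order
    sense_mask: np.ndarray = field(repr=False)      # (64,) bool
    informative_index: np.ndarray = field(repr=False)  # (59,) int
    family_indices: dict[str, np.ndarray] = field(repr=False)  # aa -> codon idx

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.sense_mask[CODON_INDEX[c]])

    def family_of(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def degenerate_families(self) -> dict[str, tuple[str, ...]]:
        return {aa: cods for aa, cods in self.families.items() if len(cods) >= 2}


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """The bacterial code (table 11) with precomputed degeneracy structure."""
    table = CodonTable.unambiguous_dna_by_id[11]
    codon_to_aa = dict(table.forward_table)
    stops = frozenset(table.stop_codons)
    for s in stops:
        codon_to_aa[s] = "*"

    families: dict[str, list[str]] = {}
    for codon in CODONS:
        aa = codon_to_aa[codon]
        if aa == "*":
            continue
        families.setdefault(aa, []).append(codon)
    fam = {aa: tuple(cods) for aa, cods in families.items()}

    classes: dict[int, list[str]] = {}
    for aa, cods in fam.items():
        classes.setdefault(len(cods), []).append(aa)
    degeneracy = {k: tuple(sorted(v)) for k, v in classes.items()}

    sense_mask = np.array([c not in stops for c in CODONS], dtype=bool)
    informative = tuple(
        c for c in CODONS if sense_mask[CODON_INDEX[c]] and c not in ("ATG", "TGG")
    )
    informative_index = np.array([CODON_INDEX[c] for c in informative], dtype=np.int64)
    family_indices = {
        aa: np.array([CODON_INDEX[c] for c in cods], dtype=np.int64)
        for aa, cods in fam.items()
    }
    return GeneticCode(
        codon_to_aa=codon_to_aa,
        stop_codons=stops,
        families=fam,
        degeneracy_classes=degeneracy,
        informative_codons=informative,
        sense_mask=sense_mask,
        informative_index=informative_index,
        family_indices=family_indices,
    )
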