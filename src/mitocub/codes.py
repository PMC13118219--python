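"""Genetic-code tables and codon bookkeeping.

A :class:`GeneticCode` wraps an NCBI translation table (via Biopython) and
precomputes the structures every codon-usage statistic needs: synonymous
families, the degenerate-codon set, degeneracy classes, and the
fourfold-degenerate codon groups used by PR2 analysis.

Sequences are handled in the DNA alphabet internally; :func:`to_rna`
converts codon labels to the RNA alphabet for reports (UUU, GGU, ...).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

#: Bases in classic codon-table order (TTT first).
BASES = "TCAG"
#: All 64 codons, DNA alphabet, fixed order used by count vectors.
CODONS: tuple[str, ...] = tuple("".join(p) for p in itertools.product(BASES, repeat=3))
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

STOP = "*"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(codon: str) -> str:
    return codon.replace("T", "U")


def to_dna(codon: str) -> str:
    return codon.replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table plus derived synonymous-family structure.

    Attributes
    ----------
    table_id:
        NCBI translation-table identifier (1 = standard, 4 = mold
        mitochondrial, the default for these fungal mitogenomes).
    codon_to_aa:
        Map of all 64 DNA codons to one-letter amino acids, ``"*"`` for stop.
    families:
        Amino acid -> tuple of synonymous codons (sense codons only),
        a partition of the sense codons.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]] = field(init=False)
    stop_codons: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError("codon_to_aa must map all 64 codons")
        stops = frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP)
        if not stops:
            raise ValueError("stop-codon set is empty")
        fams: dict[str, list[str]] = {}
        for codon in CODONS:  # fixed order keeps family tuples deterministic
            aa = self.codon_to_aa[codon]
            if aa != STOP:
                fams.setdefault(aa, []).append(codon)
        object.__setattr__(self, "families", {aa: tuple(cs) for aa, cs in fams.items()})
        object.__setattr__(self, "stop_codons", stops)

    # -- derived sets -------------------------------------------------

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.codon_to_aa[c] != STOP)

    @property
    def degenerate_codons(self) -> tuple[str, ...]:
        """Codons in families of size >= 2 (59 for the standard code)."""
        return tuple(
            c
            for c in self.sense_codons
            if len(self.families[self.codon_to_aa[c]]) >= 2
        )

    @property
    def single_codon_families(self) -> tuple[str, ...]:
        """Amino acids encoded by exactly one codon (Met, Trp in table 1)."""
        return tuple(aa for aa, cs in self.families.items() if len(cs) == 1)

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Map family size k -> amino acids whose family has size k."""
        classes: dict[int, list[str]] = {}
        for aa, cs in self.families.items():
            classes.setdefault(len(cs), []).append(aa)
        return {k: tuple(v) for k, v in sorted(classes.items())}

    def fourfold_groups(self) -> tuple[tuple[str, ...], ...]:
        """Codon quartets sharing a prefix and all encoding the same residue.

        These are the fourfold-degenerate sites of PR2 analysis; they include
        the fourfold subsets of sixfold families (e.g. CUN for Leu).
        """
        groups = []
        for b1 in BASES:
            for b2 in BASES:
                quartet = tuple(b1 + b2 + b3 for b3 in BASES)
                aas = {self.codon_to_aa[c] for c in quartet}
                if len(aas) == 1 and STOP not in aas:
                    groups.append(quartet)
        return tuple(groups)


@lru_cache(maxsize=None)
def get_code(table_id: int = 4) -> GeneticCode:
    """Build a :class:`GeneticCode` from the NCBI table registry."""
    try:
        table = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError as exc:
        raise ValueError(f"unknown NCBI translation table: {table_id}") from exc
    mapping = {}
    for codon in CODONS:
        if codon in table.stop_codons:
            mapping[codon] = STOP
        else:
            mapping[codon] = table.forward_table[codon]
    return GeneticCode(table_id=table_id, codon_to_aa=mapping)
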