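"""Reading CDS inputs and converting them to codon counts.

GenBank flat files are read with Biopython; each CDS feature becomes one
:class:`GeneRecord` with the spliced coding-strand sequence (``join``
locations honoured, complement features reverse-complemented by
``feature.extract``). FASTA inputs carry one gene per entry with the gene
name parsed from the header.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .codes import CODON_INDEX, CODONS, GeneticCode, get_code

logger = logging.getLogger(__name__)

#: The 11 core protein-coding genes shared by the study mitogenomes.
CORE_GENES = frozenset(
    {"atp6", "cob", "cox1", "cox2", "cox3",
     "nad1", "nad2", "nad3", "nad4", "nad5", "nad6"}
)

#: Synonym map applied after lower-casing (annotation dialects differ).
GENE_SYNONYMS = {
    "cytb": "cob", "cob": "cob", "cytochrome b": "cob",
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "coxi": "cox1", "coxii": "cox2", "coxiii": "cox3",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3",
    "nd4": "nad4", "nd5": "nad5", "nd6": "nad6",
    "atpase6": "atp6", "atp 6": "atp6",
}


def canonical_gene(name: str, synonyms: dict[str, str] | None = None) -> str:
    """Lower-case a gene label and resolve common annotation synonyms."""
    key = name.strip().lower()
    key = re.sub(r"^orf[_\-\s]*", "", key)
    table = GENE_SYNONYMS if synonyms is None else synonyms
    return table.get(key, key)


@dataclass
class GeneRecord:
    """One coding sequence: species label, gene label, DNA, genetic code."""

    species: str
    gene: str
    seq: str
    table_id: int = 4

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) < 3:
            raise ValueError(f"{self.species}/{self.gene}: sequence shorter than one codon")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.species}/{self.gene}: invalid characters {sorted(bad)}")

    @property
    def n_codons_raw(self) -> int:
        return len(self.seq) // 3


@dataclass
class CodonCounts:
    """64-entry codon count vector for one gene or a pooled gene set."""

    species: str
    gene: str
    counts: np.ndarray
    n_codons: int = field(init=False)
    skipped: int = 0          # triplets containing N
    internal_stops: int = 0   # internal stop codons found (excluded by default)
    had_terminal_stop: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (64,) or (self.counts < 0).any():
            raise ValueError("counts must be a nonnegative 64-vector")
        self.n_codons = int(self.counts.sum())

    def __getitem__(self, codon: str) -> int:
        return int(self.counts[CODON_INDEX[codon]])

    def as_dict(self) -> dict[str, int]:
        return {c: int(n) for c, n in zip(CODONS, self.counts)}


def pool_counts(counts_list: Sequence[CodonCounts], species: str = "pooled",
                gene: str = "pooled") -> CodonCounts:
    """Sum count vectors over a set of genes (or species)."""
    if not counts_list:
        raise ValueError("cannot pool an empty counts list")
    total = np.sum([c.counts for c in counts_list], axis=0)
    return CodonCounts(species=species, gene=gene, counts=total)


# ---------------------------------------------------------------------------
# readers


def _feature_gene_name(feature) -> str | None:
    for qual in ("gene", "product", "locus_tag"):
        if qual in feature.qualifiers:
            return feature.qualifiers[qual][0]
    return None


def read_genbank(path: str | Path, default_table: int = 4,
                 species: str | None = None) -> list[GeneRecord]:
    """Extract one GeneRecord per CDS feature of a GenBank flat file.

    The record's organism (or accession) is used as the species label unless
    ``species`` is given. CDS features without a resolvable gene name are
    skipped with a warning.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise ValueError(f"{path}: not a parseable GenBank file: {exc}") from exc
    if not parsed:
        raise ValueError(f"{path}: no GenBank records found")
    for rec in parsed:
        label = species or rec.annotations.get("organism") or rec.id
        for feature in rec.features:
            if feature.type != "CDS":
                continue
            name = _feature_gene_name(feature)
            if name is None:
                logger.warning("%s: CDS at %s has no gene/product qualifier; skipped",
                               path.name, feature.location)
                continue
            table_id = int(feature.qualifiers.get("transl_table", [default_table])[0])
            seq = str(feature.extract(rec.seq))
            records.append(GeneRecord(species=label, gene=canonical_gene(name),
                                      seq=seq, table_id=table_id))
    return records


def read_fasta_cds(path: str | Path, species: str,
                   gene_pattern: str = r"^(\S+)",
                   default_table: int = 4) -> list[GeneRecord]:
    """Read one GeneRecord per FASTA entry; gene token parsed from the header.

    Raises on a duplicate gene token for the species, which would silently
    shadow a CDS downstream.
    """
    regex = re.compile(gene_pattern)
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        m = regex.search(entry.description)
        if not m:
            raise ValueError(f"{path}: cannot parse gene from header {entry.description!r}")
        gene = canonical_gene(m.group(1))
        if gene in seen:
            raise ValueError(f"{path}: duplicate gene {gene!r} for species {species!r}")
        seen.add(gene)
        records.append(GeneRecord(species=species, gene=gene,
                                  seq=str(entry.seq), table_id=default_table))
    return records


def select_core_genes(records: Iterable[GeneRecord],
                      core_names: frozenset[str] = CORE_GENES,
                      min_codons: int = 100) -> list[GeneRecord]:
    """Keep core genes of at least ``min_codons`` codons (raw length / 3).

    The boundary is inclusive: a 300-nt gene is exactly 100 codons and is
    retained. Missing core genes are reported per species as warnings.
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    kept = [r for r in records
            if r.gene in core_names and r.n_codons_raw >= min_codons]
    by_species: dict[str, set[str]] = {}
    for r in kept:
        by_species.setdefault(r.species, set()).add(r.gene)
    for sp, genes in by_species.items():
        for missing in sorted(core_names - genes):
            logger.warning("species %s: core gene %s missing or too short", sp, missing)
    return kept


# ---------------------------------------------------------------------------
# codon counting


def to_codon_counts(record: GeneRecord, code: GeneticCode | None = None,
                    on_length_error: str = "error",
                    count_internal_stops: bool = False) -> CodonCounts:
    """Partition a CDS into codons and tally them.

    Frame 0 of the annotated CDS is used throughout. A terminal stop codon is
    dropped from the counts; triplets containing N are skipped and tallied;
    internal stop codons are warned about and, by default, excluded.

    Parameters
    ----------
    on_length_error:
        ``"error"`` (default) rejects sequences whose length is not a
        multiple of 3; ``"truncate"`` drops the trailing partial codon with a
        warning.
    """
    code = code if code is not None else get_code(record.table_id)
    seq = record.seq
    if len(seq) % 3 != 0:
        if on_length_error == "truncate":
            logger.warning("%s/%s: length %d not divisible by 3; truncating",
                           record.species, record.gene, len(seq))
            seq = seq[: 3 * (len(seq) // 3)]
        else:
            raise ValueError(
                f"{record.species}/{record.gene}: length {len(seq)} not divisible by 3")
    triplets = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    had_terminal_stop = bool(triplets) and triplets[-1] in code.stop_codons
    if had_terminal_stop:
        triplets = triplets[:-1]

    counts = np.zeros(64, dtype=np.int64)
    skipped = 0
    internal_stops = 0
    for pos, codon in enumerate(triplets):
        if "N" in codon:
            skipped += 1
            continue
        if codon in code.stop_codons:
            internal_stops += 1
            logger.warning("%s/%s: internal stop %s at codon %d",
                           record.species, record.gene, codon, pos + 1)
            if not count_internal_stops:
                continue
        counts[CODON_INDEX[codon]] += 1
    cc = CodonCounts(species=record.species, gene=record.gene, counts=counts,
                     skipped=skipped,
                     internal_stops=internal_stops,
                     had_terminal_stop=had_terminal_stop)
    return cc


def write_manifest(records: Sequence[GeneRecord], counts: Sequence[CodonCounts],
                   path: str | Path) -> None:
    """TSV manifest of extracted genes (species, gene, lengths, flags)."""
    import pandas as pd

    rows = []
    for rec, cc in zip(records, counts):
        flags = []
        if cc.internal_stops:
            flags.append(f"internal_stops={cc.internal_stops}")
        if cc.skipped:
            flags.append(f"skipped_N={cc.skipped}")
        rows.append({"species": rec.species, "gene": rec.gene,
                     "length_nt": len(rec.seq), "n_codons": cc.n_codons,
                     "table_id": rec.table_id, "flags": ";".join(flags) or "."})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
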