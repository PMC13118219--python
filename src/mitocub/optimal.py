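"""Optimal-codon determination from ENC-ranked expression pools.

Genes are ranked by ENC; the lowest-ENC tail is treated as the
high-expression pool (stronger bias) and the highest-ENC tail as the
low-expression pool. Codons are classified by the difference in RSCU
between the pools (dRSCU) and their overall RSCU:

* optimal           — dRSCU > 0.08 and overall RSCU > 1
* highly_expressed  — dRSCU > 0.08 only
* high_frequency    — overall RSCU > 1 only
* general           — neither
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codes import GeneticCode, to_rna
from .indices import rscu
from .seqio import CodonCounts

logger = logging.getLogger(__name__)

DELTA_RSCU_THRESHOLD = 0.08
POOL_FRACTION = 0.10


def expression_pools(enc_by_gene: Mapping[str, float],
                     fraction: float = POOL_FRACTION,
                     pool_size: int | None = None,
                     ) -> tuple[list[str], list[str]]:
    """Split genes into putative high/low expression pools by ENC.

    Pool size is ceil(fraction * n), at least 1 (``pool_size`` overrides).
    The high-expression pool holds the lowest-ENC genes. Ties are broken by
    gene name so the split is deterministic.
    """
    if len(enc_by_gene) < 2:
        raise ValueError("need at least 2 genes to form pools")
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    n = len(enc_by_gene)
    size = pool_size if pool_size is not None else max(1, math.ceil(fraction * n))
    if 2 * size > n:
        raise ValueError(f"pools of {size} genes overlap with only {n} genes")
    ranked = sorted(enc_by_gene, key=lambda g: (enc_by_gene[g], g))
    return ranked[:size], ranked[-size:][::-1]


@dataclass
class CodonClassification:
    """Per-codon RSCU summary and class assignment for one species."""

    table: pd.DataFrame  # index codon (DNA); columns amino_acid, rscu_overall, delta_rscu, klass

    @property
    def optimal_codons(self) -> list[str]:
        return list(self.table.index[self.table["klass"] == "optimal"])

    @property
    def high_frequency_codons(self) -> list[str]:
        return list(self.table.index[self.table["rscu_overall"] > 1.0])

    def to_report(self) -> pd.DataFrame:
        out = self.table.copy()
        out.index = [to_rna(c) for c in out.index]
        out.index.name = "codon"
        return out


def classify_codons(high_counts: CodonCounts, low_counts: CodonCounts,
                    all_counts: CodonCounts, code: GeneticCode,
                    delta_threshold: float = DELTA_RSCU_THRESHOLD,
                    ) -> CodonClassification:
    """Classify every degenerate sense codon from pooled pool counts.

    dRSCU is computed on pooled counts per pool (stable at small gene
    numbers). A family absent from either pool leaves dRSCU undefined, so
    its codons cannot be optimal or highly expressed; this is logged.
    """
    for name, cc in (("high", high_counts), ("low", low_counts), ("all", all_counts)):
        if cc.n_codons == 0:
            raise ValueError(f"{name} pool is empty")
    r_high = rscu(high_counts, code)
    r_low = rscu(low_counts, code)
    r_all = rscu(all_counts, code)
    rows = []
    for codon in code.degenerate_codons:
        overall = r_all[codon]
        delta = r_high[codon] - r_low[codon]
        if math.isnan(delta):
            logger.info("family of %s absent from a pool; dRSCU undefined", codon)
        is_high_delta = (not math.isnan(delta)) and delta > delta_threshold
        is_high_freq = (not math.isnan(overall)) and overall > 1.0
        if is_high_delta and is_high_freq:
            klass = "optimal"
        elif is_high_delta:
            klass = "highly_expressed"
        elif is_high_freq:
            klass = "high_frequency"
        else:
            klass = "general"
        rows.append({"codon": codon, "amino_acid": code.codon_to_aa[codon],
                     "rscu_overall": overall, "delta_rscu": delta, "klass": klass})
    table = pd.DataFrame(rows).set_index("codon")
    return CodonClassification(table=table)


def species_optimal_codons(counts_by_gene: Mapping[str, CodonCounts],
                           enc_by_gene: Mapping[str, float],
                           code: GeneticCode,
                           fraction: float = POOL_FRACTION,
                           delta_threshold: float = DELTA_RSCU_THRESHOLD,
                           pool_size: int | None = None,
                           ) -> CodonClassification:
    """End-to-end classification for one species' gene set."""
    from .seqio import pool_counts

    high, low = expression_pools(enc_by_gene, fraction=fraction, pool_size=pool_size)
    sp = next(iter(counts_by_gene.values())).species
    high_cc = pool_counts([counts_by_gene[g] for g in high], species=sp, gene="high_pool")
    low_cc = pool_counts([counts_by_gene[g] for g in low], species=sp, gene="low_pool")
    all_cc = pool_counts(list(counts_by_gene.values()), species=sp, gene="all")
    return classify_codons(high_cc, low_cc, all_cc, code,
                           delta_threshold=delta_threshold)
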