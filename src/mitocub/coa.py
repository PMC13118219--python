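"""Correspondence analysis of RSCU matrices.

Genes (or species) are projected into the space of degenerate sense codons
(59 dimensions for the standard code) according to their RSCU values, and
classical correspondence analysis decomposes the total inertia — the
chi-square distance structure of the matrix — into orthogonal axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codes import GeneticCode, to_rna
from .indices import rscu
from .seqio import CodonCounts, pool_counts

logger = logging.getLogger(__name__)


def build_rscu_matrix(counts_set: Sequence[CodonCounts], code: GeneticCode,
                      level: str = "gene") -> pd.DataFrame:
    """Rows = genes or species, columns = degenerate sense codons, values = RSCU.

    ``level="species"`` pools codon counts over each species' genes before
    computing RSCU. Families absent from a gene are imputed as 0 (no usage,
    no fabricated bias).
    """
    if not counts_set:
        raise ValueError("empty counts set")
    if level == "species":
        by_species: dict[str, list[CodonCounts]] = {}
        for cc in counts_set:
            by_species.setdefault(cc.species, []).append(cc)
        counts_set = [pool_counts(v, species=sp, gene="pooled")
                      for sp, v in by_species.items()]
        labels = [cc.species for cc in counts_set]
    elif level == "gene":
        labels = [f"{cc.species}:{cc.gene}" if cc.species else cc.gene
                  for cc in counts_set]
    else:
        raise ValueError(f"unknown level: {level}")

    cols = list(code.degenerate_codons)
    values = np.zeros((len(counts_set), len(cols)))
    for i, cc in enumerate(counts_set):
        r = rscu(cc, code)
        values[i] = [0.0 if np.isnan(r[c]) else r[c] for c in cols]
    return pd.DataFrame(values, index=labels, columns=cols)


@dataclass
class COAResult:
    """Principal coordinates and inertia decomposition of one CA run."""

    row_coords: pd.DataFrame    # rows x axes
    col_coords: pd.DataFrame    # codons x axes
    inertia_fractions: np.ndarray
    total_inertia: float


def correspondence_analysis(matrix: pd.DataFrame, n_axes: int = 4) -> COAResult:
    """Classical CA: SVD of the standardized residuals of the correspondence
    matrix; principal coordinates scale singular vectors by singular values
    and root margins.
    """
    m = matrix.copy()
    row_zero = m.sum(axis=1) == 0
    col_zero = m.sum(axis=0) == 0
    if row_zero.any() or col_zero.any():
        logger.warning("dropping %d all-zero rows, %d all-zero columns",
                       int(row_zero.sum()), int(col_zero.sum()))
        m = m.loc[~row_zero, ~col_zero]
    x = m.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("CA input must be nonnegative")
    grand = x.sum()
    if grand <= 0:
        raise ValueError("CA input must have a positive grand total")
    max_axes = min(x.shape) - 1
    if n_axes > max_axes:
        raise ValueError(f"n_axes={n_axes} exceeds rank bound {max_axes}")

    p = x / grand
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    s_resid = (p - expected) / np.sqrt(expected)
    u, sv, vt = np.linalg.svd(s_resid, full_matrices=False)
    total_inertia = float((sv ** 2).sum())
    if total_inertia <= 1e-12:
        raise ValueError("matrix fits the independence model; total inertia is 0")

    sv = sv[:max_axes]
    u = u[:, :max_axes]
    v = vt[:max_axes].T
    fractions = sv ** 2 / total_inertia

    row_pc = (u * sv) / np.sqrt(r)[:, None]
    col_pc = (v * sv) / np.sqrt(c)[:, None]
    axes = [f"axis{i+1}" for i in range(n_axes)]
    return COAResult(
        row_coords=pd.DataFrame(row_pc[:, :n_axes], index=m.index, columns=axes),
        col_coords=pd.DataFrame(col_pc[:, :n_axes], index=m.columns, columns=axes),
        inertia_fractions=fractions,
        total_inertia=total_inertia,
    )


def axis_index_correlations(result: COAResult, table: pd.DataFrame,
                            axis: int = 1,
                            indices: Sequence[str] = ("GC", "GC3s", "ENC",
                                                      "CAI", "CBI", "FOP"),
                            ) -> pd.DataFrame:
    """Pearson r/p between one CA axis and each usage index.

    ``table`` rows must align with the CA row labels (gene-level runs use
    "species:gene" labels built from the index table's MultiIndex).
    """
    coords = result.row_coords[f"axis{axis}"]
    if isinstance(table.index, pd.MultiIndex):
        labels = [f"{sp}:{g}" for sp, g in table.index]
    else:
        labels = list(table.index)
    if set(coords.index) != set(labels):
        raise ValueError("CA row labels do not align with index-table rows")
    aligned = table.copy()
    aligned.index = labels
    aligned = aligned.loc[coords.index]
    rows = []
    for name in indices:
        vals = aligned[name].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        r_val = p_val = float("nan")
        if ok.sum() >= 3 and np.std(vals[ok]) > 0 and np.std(coords[ok]) > 0:
            res = stats.pearsonr(coords[ok], vals[ok])
            r_val, p_val = float(res.statistic), float(res.pvalue)
        rows.append({"index": name, "r": r_val, "p": p_val})
    return pd.DataFrame(rows).set_index("index")


def rscu_matrix_rna(matrix: pd.DataFrame) -> pd.DataFrame:
    """Report helper: relabel codon columns in the RNA alphabet."""
    out = matrix.copy()
    out.columns = [to_rna(c) for c in out.columns]
    return out
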