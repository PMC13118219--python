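"""Per-gene composition and codon-usage indices.

Implements the classic CodonW-style index suite over codon count vectors:
nucleotide composition (overall and position-specific GC, GC3s, A3/T3/G3/C3
over synonymous third positions), RSCU, Wright's effective number of codons
(ENC), CAI with reference-derived relative-adaptiveness weights, CBI and FOP
against a designated optimal-codon set, and the Kyte-Doolittle protein
indices GRAVY and aromaticity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codes import BASES, CODONS, GeneticCode
from .seqio import CodonCounts

NAN = float("nan")

#: Kyte-Doolittle hydropathy values.
HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC = frozenset("FYW")


@dataclass
class CompositionProfile:
    """Percent-scale nucleotide composition of one gene's counted codons.

    ``GC3s`` and the third-position base fractions A3/T3/G3/C3 are computed
    over synonymous codons only: stop codons and single-codon families under
    the active code are excluded (Met and Trp for the standard code).
    """

    species: str
    gene: str
    n_codons: int
    pct_A: float
    pct_T: float
    pct_G: float
    pct_C: float
    GC: float
    GC1: float
    GC2: float
    GC3: float
    GC12: float
    GC3s: float
    A3: float
    T3: float
    G3: float
    C3: float


def _sense_mask(code: GeneticCode) -> np.ndarray:
    return np.array([code.codon_to_aa[c] != "*" for c in CODONS])


def _synonymous_mask(code: GeneticCode) -> np.ndarray:
    """Sense codons whose family has >= 2 members."""
    degen = set(code.degenerate_codons)
    return np.array([c in degen for c in CODONS])


def composition_profile(counts: CodonCounts, code: GeneticCode) -> CompositionProfile:
    """Position-wise base composition; stop codons excluded from all tallies."""
    n = counts.counts.copy()
    n[~_sense_mask(code)] = 0
    total = int(n.sum())
    if total < 1:
        raise ValueError(f"{counts.species}/{counts.gene}: no sense codons counted")

    pos_base = np.zeros((3, 4))  # position x base (order of BASES)
    base_idx = {b: i for i, b in enumerate(BASES)}
    for codon, k in zip(CODONS, n):
        if k == 0:
            continue
        for pos in range(3):
            pos_base[pos, base_idx[codon[pos]]] += k

    overall = pos_base.sum(axis=0)
    grand = overall.sum()
    pct = {b: 100.0 * overall[base_idx[b]] / grand for b in "ACGT"}
    gc_pos = [100.0 * (pos_base[p, base_idx["G"]] + pos_base[p, base_idx["C"]])
              / pos_base[p].sum() for p in range(3)]
    gc = 100.0 * (overall[base_idx["G"]] + overall[base_idx["C"]]) / grand

    # third positions of synonymous codons only
    syn = counts.counts.copy()
    syn[~_synonymous_mask(code)] = 0
    third = np.zeros(4)
    for codon, k in zip(CODONS, syn):
        if k:
            third[base_idx[codon[2]]] += k
    syn_total = third.sum()
    if syn_total > 0:
        a3, t3, g3, c3 = (100.0 * third[base_idx[b]] / syn_total for b in "ATGC")
        gc3s = g3 + c3
    else:
        a3 = t3 = g3 = c3 = gc3s = NAN

    return CompositionProfile(
        species=counts.species, gene=counts.gene, n_codons=total,
        pct_A=pct["A"], pct_T=pct["T"], pct_G=pct["G"], pct_C=pct["C"],
        GC=gc, GC1=gc_pos[0], GC2=gc_pos[1], GC3=gc_pos[2],
        GC12=(gc_pos[0] + gc_pos[1]) / 2.0,
        GC3s=gc3s, A3=a3, T3=t3, G3=g3, C3=c3,
    )


# ---------------------------------------------------------------------------
# RSCU


def rscu(counts: CodonCounts, code: GeneticCode) -> dict[str, float]:
    """Relative synonymous codon usage per sense codon.

    RSCU(c) = count(c) * |family| / family total. Families never observed
    yield NaN for all members; single-codon families are identically 1.
    """
    out: dict[str, float] = {}
    for aa, family in code.families.items():
        total = sum(counts[c] for c in family)
        size = len(family)
        for c in family:
            if size == 1:
                out[c] = 1.0
            elif total == 0:
                out[c] = NAN
            else:
                out[c] = counts[c] * size / total
    return out


# ---------------------------------------------------------------------------
# ENC (Wright's effective number of codons)


def _family_homozygosity(family_counts: Sequence[int]) -> float | None:
    """F-hat = (n * sum p_i^2 - 1) / (n - 1); None when n <= 1."""
    n = sum(family_counts)
    if n <= 1:
        return None
    p2 = sum((k / n) ** 2 for k in family_counts)
    return (n * p2 - 1.0) / (n - 1.0)


def enc(counts: CodonCounts, code: GeneticCode) -> float:
    """Wright's effective number of codons under the active genetic code.

    Family homozygosities are averaged within each degeneracy class; the
    class structure (sizes and multiplicities) is derived from the code, so
    the standard code yields ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6. A missing
    3-fold class is imputed as the mean of the 2- and 4-fold classes; any
    other missing class drops its term and the partial sum is rescaled over
    the remaining codon space. The result is clamped to
    [number of families, number of sense codons] ([20, 61] standard).
    """
    if counts.n_codons < 1:
        raise ValueError("empty codon counts")
    classes = code.degeneracy_classes()
    fbar: dict[int, float] = {}
    for size, aas in classes.items():
        if size == 1:
            continue
        vals = []
        for aa in aas:
            f = _family_homozygosity([counts[c] for c in code.families[aa]])
            if f is not None:
                vals.append(f)
        if vals:
            mean = float(np.mean(vals))
            if mean > 0:
                fbar[size] = mean

    n_singles = len(classes.get(1, ()))
    if 3 in classes and 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0  # CodonW-style imputation

    total = float(n_singles)
    covered = n_singles  # codons represented by estimable terms
    for size, aas in classes.items():
        if size == 1:
            continue
        if size in fbar:
            total += len(aas) / fbar[size]
            covered += len(aas) * size
    n_sense = len(code.sense_codons)
    if covered == 0:
        return float(len(code.families))
    if covered < n_sense:
        total *= n_sense / covered
    return float(min(max(total, len(code.families)), n_sense))


# ---------------------------------------------------------------------------
# CAI


def build_cai_weights(reference: CodonCounts, code: GeneticCode,
                      floor: float = 0.01) -> dict[str, float]:
    """Relative adaptiveness w = count / family max over a reference pool.

    Codons unobserved in the reference are floored at ``floor`` so the
    geometric mean stays finite. Only degenerate families carry weights;
    single-codon families are excluded from CAI by convention.
    """
    weights: dict[str, float] = {}
    for aa, family in code.families.items():
        if len(family) < 2:
            continue
        top = max(reference[c] for c in family)
        for c in family:
            weights[c] = max(reference[c] / top, floor) if top > 0 else 1.0
    return weights


def cai(counts: CodonCounts, weights: Mapping[str, float]) -> float:
    """Geometric mean of relative adaptiveness over counted weighted codons."""
    if not weights:
        raise ValueError("empty CAI weight table")
    log_sum = 0.0
    n = 0
    for codon, w in weights.items():
        k = counts[codon]
        if k:
            log_sum += k * math.log(w)
            n += k
    if n == 0:
        return NAN
    return math.exp(log_sum / n)


# ---------------------------------------------------------------------------
# CBI / FOP


def optimal_set_indices(counts: CodonCounts, optimal: Iterable[str],
                        code: GeneticCode) -> tuple[float, float]:
    """Codon bias index and frequency of optimal codons.

    FOP = N_opt / N_syn over degenerate-family codons; CBI compares N_opt to
    the random expectation N_rand = sum over families of
    (family count * |optimal ∩ family| / |family|).
    """
    optimal = set(optimal)
    degenerate = set(code.degenerate_codons)
    if not optimal <= degenerate:
        raise ValueError("optimal set must be degenerate sense codons")
    n_syn = 0
    n_opt = 0
    n_rand = 0.0
    for aa, family in code.families.items():
        if len(family) < 2:
            continue
        fam_total = sum(counts[c] for c in family)
        n_syn += fam_total
        hits = optimal & set(family)
        n_opt += sum(counts[c] for c in hits)
        n_rand += fam_total * len(hits) / len(family)
    if n_syn == 0:
        return NAN, NAN
    fop = n_opt / n_syn
    denom = n_syn - n_rand
    cbi_val = (n_opt - n_rand) / denom if denom != 0 else NAN
    return cbi_val, fop


# ---------------------------------------------------------------------------
# protein indices


def protein_indices(counts: CodonCounts, code: GeneticCode) -> tuple[float, float]:
    """GRAVY (mean Kyte-Doolittle hydropathy) and aromaticity of the protein."""
    total = 0
    hyd = 0.0
    arom = 0
    for codon in CODONS:
        k = counts[codon]
        if k == 0:
            continue
        aa = code.codon_to_aa[codon]
        if aa == "*":
            continue
        total += k
        hyd += k * HYDROPATHY[aa]
        if aa in AROMATIC:
            arom += k
    if total == 0:
        return NAN, NAN
    return hyd / total, arom / total


# ---------------------------------------------------------------------------
# index table + correlations

INDEX_COLUMNS = ["ENC", "CAI", "CBI", "FOP", "GRAVY", "AROMO"]


def build_index_table(counts_list: Sequence[CodonCounts], code: GeneticCode,
                      cai_weights: Mapping[str, float] | None = None,
                      optimal: Iterable[str] | None = None) -> pd.DataFrame:
    """One row per (species, gene) with composition and usage indices.

    CAI/CBI/FOP columns are NaN unless weights / an optimal set are supplied
    (both depend on a reference choice made at the pipeline level).
    """
    rows = []
    for cc in counts_list:
        prof = composition_profile(cc, code)
        row = {f.name: getattr(prof, f.name) for f in fields(prof)}
        row["ENC"] = enc(cc, code)
        row["CAI"] = cai(cc, cai_weights) if cai_weights else NAN
        if optimal is not None:
            row["CBI"], row["FOP"] = optimal_set_indices(cc, optimal, code)
        else:
            row["CBI"] = row["FOP"] = NAN
        row["GRAVY"], row["AROMO"] = protein_indices(cc, code)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.set_index(["species", "gene"])


def correlation_matrix(table: pd.DataFrame, columns: Sequence[str] | None = None,
                       method: str = "pearson") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p over the table's rows.

    Requires >= 3 complete rows per pair; zero-variance columns yield NaN.
    Returns (r, p) DataFrames.
    """
    if method != "pearson":
        raise ValueError("only Pearson correlation is supported")
    cols = list(columns) if columns is not None else list(table.columns)
    k = len(cols)
    r = np.full((k, k), NAN)
    p = np.full((k, k), NAN)
    for i in range(k):
        for j in range(i, k):
            pair = table[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                continue
            x = pair.iloc[:, 0].to_numpy(dtype=float)
            y = pair.iloc[:, 1].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


def significance_stars(p: float) -> str:
    if math.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
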