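"""Synthetic mitogenome-like CDS sets with known ground truth.

Two generative regimes mirror the competing hypotheses the diagnostics are
built to distinguish:

* **mutation regime** — every codon position samples G/C with the same
  per-gene probability ``g`` (drawn around the GC3 target), so
  GC1 = GC2 = GC3 in expectation and the neutrality slope across genes
  approaches 1, while ENC tracks the mutation-only expected curve;
* **selection regime** — the amino-acid sequence is drawn from a fixed
  hydrophobic, membrane-protein-like residue profile (pinning GC12), and
  synonymous codons are chosen with multiplicative weight
  ``exp(bias_strength)`` on a planted preferred set (A-ending by default),
  decoupling GC3 from GC12: slope near 0, ENC well below the expected
  curve, PR2 y-coordinate above 0.5.

Defaults emulate the target system: 8 species, the 11 core
protein-coding genes at realistic mitochondrial lengths (118-655 codons,
i.e. 354 to roughly 1966 bp), ~73% AT and ~13% GC3.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .codes import GeneticCode, get_code
from .seqio import GeneRecord

logger = logging.getLogger(__name__)

#: Core-gene codon lengths (nad3 = 354 bp shortest, nad5 longest).
DEFAULT_GENES: tuple[tuple[str, int], ...] = (
    ("atp6", 250), ("cob", 390), ("cox1", 530), ("cox2", 250),
    ("cox3", 270), ("nad1", 320), ("nad2", 480), ("nad3", 118),
    ("nad4", 490), ("nad5", 655), ("nad6", 200),
)

#: Hydrophobic membrane-protein-like residue frequencies (normalized below);
#: core mitochondrial PCGs are strongly hydrophobic.
RESIDUE_PROFILE: dict[str, float] = {
    "L": 0.155, "I": 0.095, "F": 0.085, "S": 0.085, "G": 0.070,
    "V": 0.065, "T": 0.060, "A": 0.060, "N": 0.050, "K": 0.040,
    "Y": 0.040, "P": 0.035, "M": 0.030, "W": 0.025, "Q": 0.020,
    "E": 0.020, "D": 0.020, "R": 0.020, "H": 0.015, "C": 0.010,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters for one simulated species set."""

    n_species: int = 8
    genes: tuple[tuple[str, int], ...] = DEFAULT_GENES
    at_content_target: float = 0.73
    gc3_target: float = 0.13
    regime: str = "mutation"
    bias_strength: float = 2.0
    preferred_codons: frozenset[str] | None = None
    seed: int = 0
    table_id: int = 4
    gc_spread: float = 0.05      # sd of per-gene GC pressure (mutation regime)
    bias_jitter: float = 0.3     # sd of per-gene bias (selection regime)
    gene_bias: Mapping[str, float] | None = None  # absolute per-gene overrides

    def __post_init__(self) -> None:
        if not 0 < self.gc3_target < 1 or not 0 < self.at_content_target < 1:
            raise ValueError("composition targets must be fractions in (0, 1)")
        for name, length in self.genes:
            if not 100 <= length <= 2000:
                raise ValueError(f"gene {name}: length {length} outside [100, 2000] codons")


def planted_preferred(code: GeneticCode, ending_priority: str = "ATGC",
                      ) -> frozenset[str]:
    """One preferred codon per degenerate family, picked by third-base priority.

    The default priority "ATGC" prefers A-ending codons (then T) — the
    AT-rich mitochondrial signature.
    """
    chosen = []
    for aa, family in sorted(code.families.items()):
        if len(family) < 2:
            continue
        for base in ending_priority:
            hits = [c for c in family if c[2] == base]
            if hits:
                chosen.append(sorted(hits)[0])
                break
    return frozenset(chosen)


# ---------------------------------------------------------------------------
# low-level draws

_AT = np.array(["A", "T"])
_GC = np.array(["G", "C"])


def _conditional_gc(g: float, code: GeneticCode) -> float:
    """Expected per-position GC of a codon drawn at pressure g, given that
    stop codons are rejected."""
    from .codes import CODONS

    def base_p(b: str) -> float:
        return g / 2 if b in "GC" else (1 - g) / 2

    total = 0.0
    gc_positions = 0.0
    for codon in CODONS:
        if codon in code.stop_codons:
            continue
        p = base_p(codon[0]) * base_p(codon[1]) * base_p(codon[2])
        total += p
        gc_positions += p * sum(b in "GC" for b in codon) / 3
    return gc_positions / total


def _compensated_pressure(target: float, code: GeneticCode) -> float:
    """Pressure g' whose post-rejection GC equals the target.

    Rejecting AT-rich stop codons inflates realized GC by up to ~1.4
    percentage points; inverting the conditional expectation removes that
    bias so realized composition converges to the stated target.
    """
    from scipy.optimize import brentq

    lo, hi = 1e-4, 1 - 1e-4
    if not _conditional_gc(lo, code) <= target <= _conditional_gc(hi, code):
        return target
    return float(brentq(lambda g: _conditional_gc(g, code) - target, lo, hi,
                        xtol=1e-10))


def _draw_gc_codons(rng: np.random.Generator, n: int, g: float,
                    code: GeneticCode) -> list[str]:
    """n codons with iid per-position GC probability g; stops rejected."""
    out = np.empty(n, dtype="<U3")
    todo = np.arange(n)
    stops = code.stop_codons
    while todo.size:
        gc_mask = rng.random((todo.size, 3)) < g
        pick = rng.integers(0, 2, size=(todo.size, 3))
        arr = np.where(gc_mask, _GC[pick], _AT[pick])
        drawn = np.array(["".join(row) for row in arr], dtype="<U3")
        ok = np.array([c not in stops for c in drawn])
        out[todo[ok]] = drawn[ok]
        todo = todo[~ok]
    return list(out)


def _draw_selection_codons(rng: np.random.Generator, n: int, bias: float,
                           preferred: frozenset[str], code: GeneticCode,
                           aa_names: np.ndarray, aa_probs: np.ndarray,
                           ) -> list[str]:
    """n codons: residues from the fixed profile, synonyms by biased weights."""
    aa_seq = rng.choice(aa_names, size=n, p=aa_probs)
    out = np.empty(n, dtype="<U3")
    for aa in np.unique(aa_seq):
        family = np.array(code.families[aa], dtype="<U3")
        w = np.array([np.exp(bias) if c in preferred else 1.0 for c in family])
        w /= w.sum()
        idx = np.where(aa_seq == aa)[0]
        out[idx] = rng.choice(family, size=idx.size, p=w)
    return list(out)


def _assemble(codons: Sequence[str], code: GeneticCode) -> str:
    """CDS string: start codon, body, AT-rich terminal stop."""
    stop = "TAA" if "TAA" in code.stop_codons else sorted(code.stop_codons)[0]
    return "ATG" + "".join(codons) + stop


# ---------------------------------------------------------------------------
# regimes


def simulate_mutation_regime(spec: SyntheticSpec,
                             rng: np.random.Generator | None = None,
                             ) -> list[GeneRecord]:
    """GC-pressure-only species set; see module docstring."""
    if spec.regime != "mutation":
        raise ValueError("spec.regime must be 'mutation'")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    code = get_code(spec.table_id)
    records = []
    for s in range(spec.n_species):
        species = f"sp{s + 1:02d}"
        for gene, length in spec.genes:
            g = float(np.clip(rng.normal(spec.gc3_target, spec.gc_spread),
                              0.02, 0.90))
            if g <= 0.0 or g >= 1.0:
                raise ValueError("infeasible GC pressure")
            codons = _draw_gc_codons(rng, length - 1,
                                     _compensated_pressure(g, code), code)
            records.append(GeneRecord(species=species, gene=gene,
                                      seq=_assemble(codons, code),
                                      table_id=spec.table_id))
    return records


def simulate_selection_regime(spec: SyntheticSpec,
                              rng: np.random.Generator | None = None,
                              preferred: frozenset[str] | None = None,
                              ) -> list[GeneRecord]:
    """Third-position-selection species set; see module docstring."""
    if spec.regime != "selection":
        raise ValueError("spec.regime must be 'selection'")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    code = get_code(spec.table_id)
    preferred = (preferred if preferred is not None
                 else spec.preferred_codons
                 if spec.preferred_codons is not None
                 else planted_preferred(code))
    if spec.bias_strength > 0 and not preferred:
        raise ValueError("selection regime with positive bias needs a preferred set")
    profile = {aa: f for aa, f in RESIDUE_PROFILE.items() if aa in code.families}
    aa_names = np.array(sorted(profile))
    aa_probs = np.array([profile[a] for a in aa_names])
    aa_probs /= aa_probs.sum()
    records = []
    for s in range(spec.n_species):
        species = f"sp{s + 1:02d}"
        for gene, length in spec.genes:
            if spec.gene_bias and gene in spec.gene_bias:
                bias = float(spec.gene_bias[gene])
            else:
                bias = float(max(0.0, rng.normal(spec.bias_strength,
                                                 spec.bias_jitter)))
            codons = _draw_selection_codons(rng, length - 1, bias, preferred,
                                            code, aa_names, aa_probs)
            records.append(GeneRecord(species=species, gene=gene,
                                      seq=_assemble(codons, code),
                                      table_id=spec.table_id))
    return records


def simulate(spec: SyntheticSpec, **kwargs) -> list[GeneRecord]:
    if spec.regime == "mutation":
        return simulate_mutation_regime(spec, **kwargs)
    if spec.regime == "selection":
        return simulate_selection_regime(spec, **kwargs)
    raise ValueError(f"unknown regime: {spec.regime}")


# ---------------------------------------------------------------------------
# species sets on disk


def simulate_species_set(spec: SyntheticSpec,
                         group_structure: Mapping[str, int] | None = None,
                         out_dir: str | Path | None = None,
                         force: bool = False,
                         ) -> tuple[list[GeneRecord], dict]:
    """Simulate a full species set, optionally with planted group structure.

    ``group_structure`` maps species label ("sp01"...) to group 0 or 1;
    group 0 prefers A-ending codons, group 1 T-ending, giving the clustering
    stage a recoverable bipartition. When ``out_dir`` is given, one FASTA
    per species plus a ``truth.json`` manifest are written.
    """
    rng = np.random.default_rng(spec.seed)
    code = get_code(spec.table_id)
    group_preferred = {0: planted_preferred(code, "ATGC"),
                       1: planted_preferred(code, "TAGC")}

    records: list[GeneRecord] = []
    truth: dict = {"regime": spec.regime, "seed": spec.seed,
                   "table_id": spec.table_id, "species": {}}
    for s in range(spec.n_species):
        species = f"sp{s + 1:02d}"
        group = group_structure.get(species) if group_structure else None
        preferred = (group_preferred[group] if group is not None
                     else spec.preferred_codons
                     if spec.preferred_codons is not None
                     else planted_preferred(code))
        one = replace(spec, n_species=1)
        if spec.regime == "mutation":
            sp_records = simulate_mutation_regime(one, rng=rng)
        else:
            sp_records = simulate_selection_regime(one, rng=rng, preferred=preferred)
        for rec in sp_records:
            rec.species = species
        records.extend(sp_records)
        truth["species"][species] = {
            "group": group,
            "preferred_codons": sorted(preferred) if spec.regime == "selection" else None,
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not force:
            raise FileExistsError(f"{out_dir} exists; pass force=True to overwrite")
        out_dir.mkdir(parents=True, exist_ok=True)
        by_species: dict[str, list[GeneRecord]] = {}
        for rec in records:
            by_species.setdefault(rec.species, []).append(rec)
        for species, recs in by_species.items():
            with open(out_dir / f"{species}.fasta", "w") as fh:
                for rec in recs:
                    fh.write(f">{rec.gene}\n{rec.seq}\n")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
    return records, truth


def read_truth(path: str | Path) -> dict:
    with open(Path(path)) as fh:
        return json.load(fh)
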