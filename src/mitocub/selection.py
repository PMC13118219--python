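"""Mutation-versus-selection diagnostics.

Three classic graphical tests of what drives codon bias:

* the neutrality plot — OLS regression of GC12 on GC3 across genes; slope
  near 1 means third-position mutation pressure carries over to all
  positions, slope near 0 means the first two positions are constrained;
* the ENC-GC3s plot — observed ENC against the curve expected when GC3s
  alone (i.e. mutation pressure) shapes usage, with ENC_Ratio measuring the
  relative shortfall;
* the PR2 bias plot — strand-symmetry of third-position base usage at
  fourfold-degenerate sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .codes import BASES, GeneticCode
from .indices import CompositionProfile
from .seqio import CodonCounts

NAN = float("nan")


@dataclass
class NeutralityFit:
    species: str
    slope: float
    intercept: float
    r_squared: float
    n_genes: int


def neutrality_fit(profiles: Sequence[CompositionProfile],
                   species: str | None = None) -> NeutralityFit:
    """OLS of GC12 (y) on GC3 (x), both on the percent scale."""
    pts = [(p.GC3, p.GC12) for p in profiles
           if not (math.isnan(p.GC3) or math.isnan(p.GC12))]
    if len(pts) < 3:
        raise ValueError("neutrality fit needs >= 3 genes with defined GC12/GC3")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("GC3 has zero variance; neutrality fit undefined")
    label = species if species is not None else profiles[0].species
    if np.ptp(y) == 0:  # constant GC12: flat line, no explained variance
        return NeutralityFit(species=label, slope=0.0, intercept=float(y[0]),
                             r_squared=0.0, n_genes=len(pts))
    res = stats.linregress(x, y)
    return NeutralityFit(species=label, slope=float(res.slope),
                         intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2), n_genes=len(pts))


def enc_expected(gc3s: float) -> float:
    """Expected ENC under pure mutation pressure: 2 + s + 29/(s^2 + (1-s)^2)."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"gc3s must be a fraction in [0, 1], got {gc3s}")
    return 2.0 + gc3s + 29.0 / (gc3s ** 2 + (1.0 - gc3s) ** 2)


def enc_ratio(enc_obs: float, enc_exp: float) -> float:
    """(expected - observed) / expected; positive when usage is more biased
    than mutation alone predicts."""
    if enc_exp <= 0:
        raise ValueError("expected ENC must be positive")
    return (enc_exp - enc_obs) / enc_exp


@dataclass
class ENCPoint:
    species: str
    gene: str
    gc3s: float       # fraction in [0, 1]
    enc_obs: float
    enc_exp: float
    enc_ratio: float


def enc_point(species: str, gene: str, gc3s_fraction: float,
              enc_obs: float) -> ENCPoint:
    exp = enc_expected(gc3s_fraction)
    return ENCPoint(species=species, gene=gene, gc3s=gc3s_fraction,
                    enc_obs=enc_obs, enc_exp=exp,
                    enc_ratio=enc_ratio(enc_obs, exp))


@dataclass
class PR2Point:
    species: str
    gene: str
    x: float  # G3 / (G3 + C3)
    y: float  # A3 / (A3 + T3)
    quadrant: int | None


def _assign_quadrant(x: float, y: float) -> int:
    """Quadrants around (0.5, 0.5), mathematical orientation; ties at 0.5
    resolve to the lowest consistent quadrant index."""
    candidates = []
    if x >= 0.5 and y >= 0.5:
        candidates.append(1)
    if x <= 0.5 and y >= 0.5:
        candidates.append(2)
    if x <= 0.5 and y <= 0.5:
        candidates.append(3)
    if x >= 0.5 and y <= 0.5:
        candidates.append(4)
    return min(candidates)


def pr2_point(counts: CodonCounts, code: GeneticCode,
              mode: str = "fourfold") -> PR2Point:
    """Third-position strand-bias coordinates.

    ``mode="fourfold"`` (default, standard PR2 practice) tallies third
    positions over fourfold-degenerate codon groups only;
    ``"all_synonymous"`` uses every degenerate-family codon.
    """
    if mode == "fourfold":
        codons = [c for group in code.fourfold_groups() for c in group]
    elif mode == "all_synonymous":
        codons = list(code.degenerate_codons)
    else:
        raise ValueError(f"unknown PR2 mode: {mode}")
    tally = dict.fromkeys("ACGT", 0)
    for c in codons:
        tally[c[2]] += counts[c]
    at = tally["A"] + tally["T"]
    gc = tally["G"] + tally["C"]
    y = tally["A"] / at if at > 0 else NAN
    x = tally["G"] / gc if gc > 0 else NAN
    quadrant = None
    if not (math.isnan(x) or math.isnan(y)):
        quadrant = _assign_quadrant(x, y)
    return PR2Point(species=counts.species, gene=counts.gene,
                    x=x, y=y, quadrant=quadrant)
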