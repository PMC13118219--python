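"""Full-pipeline orchestration: extract -> indices -> diagnostics -> COA ->
optimal codons -> RSCU clustering, with a flat-file config and a per-species
summary report.

Outputs are a pure function of (inputs, config, seed). TSVs are written with
4 decimal places; ``summary.json`` keeps full precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .codes import get_code, to_rna
from .coa import axis_index_correlations, build_rscu_matrix, correspondence_analysis
from .clustering import euclidean_distances, species_rscu_features, upgma, write_newick
from .indices import (build_cai_weights, build_index_table, composition_profile,
                      correlation_matrix, enc)
from .optimal import species_optimal_codons
from .selection import enc_point, neutrality_fit, pr2_point
from .seqio import (CORE_GENES, CodonCounts, GeneRecord, pool_counts,
                    read_fasta_cds, read_genbank, select_core_genes,
                    to_codon_counts, write_manifest)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat run configuration; round-trips through a key=value file."""

    input_dir: str = ""
    input_format: str = "fasta"          # "fasta" | "genbank"
    out_dir: str = "mitocub_out"
    table_id: int = 4
    core_genes: tuple[str, ...] = tuple(sorted(CORE_GENES))
    min_codons: int = 100
    delta_rscu: float = 0.08
    enc_strong_bias: float = 35.0
    pool_fraction: float = 0.10
    coa_axes: int = 4
    pr2_mode: str = "fourfold"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_rscu <= 0 or self.enc_strong_bias <= 0:
            raise ValueError("thresholds must be positive")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                value = getattr(self, f.name)
                if isinstance(value, tuple):
                    value = ",".join(value)
                fh.write(f"{f.name}={value}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in types:
                raise ValueError(f"unknown config key: {key}")
            if key == "core_genes":
                kwargs[key] = tuple(g.strip() for g in raw.split(",") if g.strip())
            elif key in ("table_id", "min_codons", "coa_axes", "seed"):
                kwargs[key] = int(raw)
            elif key in ("delta_rscu", "enc_strong_bias", "pool_fraction"):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)


def load_records(config: RunConfig) -> list[GeneRecord]:
    """Read every CDS file under the input directory."""
    input_dir = Path(config.input_dir)
    records: list[GeneRecord] = []
    if config.input_format == "fasta":
        paths = sorted(p for p in input_dir.iterdir()
                       if p.suffix in (".fa", ".fasta"))
        for path in paths:
            records.extend(read_fasta_cds(path, species=path.stem,
                                          default_table=config.table_id))
    elif config.input_format == "genbank":
        paths = sorted(p for p in input_dir.iterdir()
                       if p.suffix in (".gb", ".gbk", ".genbank"))
        for path in paths:
            records.extend(read_genbank(path, default_table=config.table_id))
    else:
        raise ValueError(f"unknown input format: {config.input_format}")
    if not records:
        raise ValueError(f"no CDS records found under {input_dir}")
    return records


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.4f", na_rep="NA")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the report directory.

    On stage failure, partial outputs are retained and ``MANIFEST`` records
    the completion state before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    code = get_code(config.table_id)
    completed: list[str] = []
    manifest_path = out / "MANIFEST"

    logging.basicConfig(level=logging.INFO)
    log_lines = [f"mitocub {__version__}",
                 f"config: {dataclasses.asdict(config)}"]

    try:
        # -- extract -------------------------------------------------------
        records = load_records(config)
        records = select_core_genes(records, frozenset(config.core_genes),
                                    config.min_codons)
        counts = [to_codon_counts(r, code) for r in records]
        write_manifest(records, counts, out / "genes.tsv")
        by_species: dict[str, dict[str, CodonCounts]] = {}
        for cc in counts:
            by_species.setdefault(cc.species, {})[cc.gene] = cc
        completed.append("extract")

        # -- per-species indices, optimal codons --------------------------
        index_frames = []
        summary_rows = []
        neutrality_rows = []
        enc_rows = []
        pr2_rows = []
        for species in sorted(by_species):
            gene_counts = by_species[species]
            enc_by_gene = {g: enc(cc, code) for g, cc in gene_counts.items()}
            classification = species_optimal_codons(
                gene_counts, enc_by_gene, code,
                fraction=config.pool_fraction,
                delta_threshold=config.delta_rscu)
            optimal_set = classification.optimal_codons
            # CAI reference: the low-ENC (high-expression) pool
            from .optimal import expression_pools
            high_pool, _ = expression_pools(enc_by_gene,
                                            fraction=config.pool_fraction)
            weights = build_cai_weights(
                pool_counts([gene_counts[g] for g in high_pool],
                            species=species, gene="ref"), code)
            table = build_index_table(list(gene_counts.values()), code,
                                      cai_weights=weights,
                                      optimal=optimal_set or None)
            index_frames.append(table)
            _fmt(classification.to_report(), out / f"optimal_codons_{species}.tsv")

            r_mat, p_mat = correlation_matrix(
                table, ["GC1", "GC2", "GC3", "GC", "GC3s", "ENC",
                        "CAI", "CBI", "FOP", "GRAVY", "AROMO"])
            _fmt(r_mat, out / f"correlations_{species}.tsv")
            _fmt(p_mat, out / f"correlations_{species}_p.tsv")

            profiles = [composition_profile(cc, code)
                        for cc in gene_counts.values()]
            fit = neutrality_fit(profiles, species=species)
            neutrality_rows.append({"species": species, "slope": fit.slope,
                                    "intercept": fit.intercept,
                                    "r_squared": fit.r_squared,
                                    "n_genes": fit.n_genes})
            points = []
            for g, cc in gene_counts.items():
                prof = composition_profile(cc, code)
                if np.isnan(prof.GC3s):
                    continue
                pt = enc_point(species, g, prof.GC3s / 100.0, enc_by_gene[g])
                points.append(pt)
                enc_rows.append({"species": species, "gene": g,
                                 "gc3s": pt.gc3s, "enc_obs": pt.enc_obs,
                                 "enc_exp": pt.enc_exp,
                                 "enc_ratio_pct": 100.0 * pt.enc_ratio})
                p2 = pr2_point(cc, code, mode=config.pr2_mode)
                pr2_rows.append({"species": species, "gene": g, "x": p2.x,
                                 "y": p2.y, "quadrant": p2.quadrant})

            mean_enc = float(np.mean(list(enc_by_gene.values())))
            summary_rows.append({
                "species": species,
                "mean_ENC": mean_enc,
                "mean_GC3": float(np.mean([p.GC3 for p in profiles])),
                "neutrality_slope": fit.slope,
                "neutrality_r2": fit.r_squared,
                "mean_ENC_ratio_pct": float(np.mean([100 * p.enc_ratio
                                                     for p in points])),
                "n_high_frequency": len(classification.high_frequency_codons),
                "n_optimal": len(classification.optimal_codons),
                "strong_bias": mean_enc < config.enc_strong_bias,
            })
        indices_table = pd.concat(index_frames)
        _fmt(indices_table, out / "indices.tsv")
        _fmt(pd.DataFrame(neutrality_rows).set_index("species"),
             out / "neutrality.tsv")
        _fmt(pd.DataFrame(enc_rows).set_index(["species", "gene"]),
             out / "enc_plot.tsv")
        _fmt(pd.DataFrame(pr2_rows).set_index(["species", "gene"]),
             out / "pr2.tsv")
        completed.append("indices")
        completed.append("diagnostics")

        # -- COA per species ----------------------------------------------
        for species in sorted(by_species):
            gene_counts = by_species[species]
            matrix = build_rscu_matrix(list(gene_counts.values()), code,
                                       level="gene")
            n_axes = min(config.coa_axes, min(matrix.shape) - 1)
            result = correspondence_analysis(matrix, n_axes=n_axes)
            _fmt(result.row_coords, out / f"coa_rows_{species}.tsv")
            coa_cols = result.col_coords.copy()
            coa_cols.index = [to_rna(c) for c in coa_cols.index]
            _fmt(coa_cols, out / f"coa_cols_{species}.tsv")
            inertia = pd.DataFrame({
                "axis": [f"axis{i+1}" for i in range(len(result.inertia_fractions))],
                "inertia_fraction": result.inertia_fractions,
            }).set_index("axis")
            _fmt(inertia, out / f"coa_inertia_{species}.tsv")
            sp_table = indices_table.loc[[species]]
            corr = axis_index_correlations(result, sp_table, axis=1)
            _fmt(corr, out / f"coa_axis1_correlations_{species}.tsv")
        completed.append("coa")
        completed.append("optimal")

        # -- clustering across species ------------------------------------
        if len(by_species) >= 2:
            species_matrix = build_rscu_matrix(counts, code, level="species")
            features = species_rscu_features(species_matrix)
            dist = euclidean_distances(features)
            _fmt(dist, out / "rscu_distance.tsv")
            tree = upgma(dist)
            write_newick(tree, out / "rscu_upgma.nwk")
            completed.append("cluster")

        # -- summary -------------------------------------------------------
        summary = pd.DataFrame(summary_rows).set_index("species")
        _fmt(summary, out / "summary.tsv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary.reset_index().to_dict(orient="records"), fh,
                      indent=2, default=float)
        completed.append("summary")
    finally:
        with open(manifest_path, "w") as fh:
            fh.write("completed_stages=" + ",".join(completed) + "\n")
        with open(out / "run.log", "w") as fh:
            fh.write("\n".join(log_lines + [f"completed: {completed}"]) + "\n")
    return out
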