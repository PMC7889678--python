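"""End-to-end pipeline driver and machine-readable run report.

Executes normalize -> network -> eigengenes -> enrichment ->
differential/contingency statistics in order, writing every stage
artifact plus a JSON report that records parameters, the samples and
genes surviving each filter, selected reference genes, module sizes,
and all test results.  Identical configuration and inputs give a
byte-identical results hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .enrichment import GeneSetCollection, module_ora
from .network import (
    NetworkConfig,
    correlation_matrix,
    detect_modules,
    module_eigengenes,
    scale_free_fit,
    signed_adjacency,
    tom_similarity,
)
from .normalize import normalize_dataset
from .simulate import SampleMeta
from .stats import (
    DegenerateDataError,
    PairedDesign,
    bh_fdr,
    cluster_samples,
    detection_timepoint_table,
    holm_sidak,
    mcnemar_from_square_table,
    neighbour_arm_table,
    neighbour_pairs,
    paired_cluster_contingency,
    paired_t,
    pearson_chi2,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat configuration of one pipeline run.

    Defaults mirror the analysis conventions this pipeline implements:
    soft threshold beta = 8, minimum module size 10, static cut height
    0.5, geNorm V cutoff 0.15, >50% undetected sample QC, ORA p < 0.01,
    per-gene FDR q = 0.05.
    """

    counts_path: str = ""
    metadata_path: str = ""
    gmt_path: str | None = None
    output_dir: str = "panelnet_out"
    network: NetworkConfig = field(default_factory=NetworkConfig)
    v_cutoff: float = 0.15
    max_undetected_fraction: float = 0.5
    n_ref_genes: int | None = None
    ora_p_cutoff: float = 0.01
    fdr_q: float = 0.05
    me_correction: str = "holm-sidak"
    chi2_yates: bool = False
    ifng_gene: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        net = NetworkConfig(**raw.pop("network", {}))
        return cls(network=net, **raw)

    def param_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir")
        d.pop("log_level")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()


def _adjust(p_values: np.ndarray, method: str) -> np.ndarray:
    if method == "holm-sidak":
        return holm_sidak(p_values)
    if method == "bh":
        return bh_fdr(p_values)
    raise ValueError(f"unknown correction method: {method}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the run report (also written as JSON)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"name": "panelnet", "version": __version__},
        "config": config.to_dict(),
        "config_hash": config.param_hash(),
        "stages": {},
    }

    stage = "read_inputs"
    try:
        raw = pio.read_counts(config.counts_path)
        meta = pio.read_metadata(config.metadata_path)
        gene_sets: GeneSetCollection | None = (
            pio.read_gmt(config.gmt_path) if config.gmt_path else None
        )
        report["stages"]["inputs"] = {
            "n_probes": len(raw.probe_ids),
            "n_samples": len(raw.sample_ids),
            "probe_class_counts": raw.probe_class.value_counts().to_dict(),
            "n_gene_sets": len(gene_sets.sets) if gene_sets else 0,
        }

        stage = "normalize"
        norm_out = normalize_dataset(
            raw,
            v_cutoff=config.v_cutoff,
            max_undetected_fraction=config.max_undetected_fraction,
            n_ref_genes=config.n_ref_genes,
        )
        pio.write_normalized(norm_out.normalized, out / "normalized.tsv")
        pio.write_detection(norm_out.detection, out / "detection.tsv")
        norm_out.genorm.to_json(out / "genorm.json")
        kept = norm_out.normalized.kept_samples
        expr = norm_out.normalized.values[kept]
        report["stages"]["normalize"] = {
            "selected_reference_genes": norm_out.genorm.selected_genes,
            "stability_M": norm_out.genorm.stability_M,
            "pairwise_variation_V": norm_out.genorm.pairwise_variation_V,
            "n_samples_kept": len(kept),
            "samples_removed": norm_out.dropped_samples,
            "n_genes": int(expr.shape[0]),
        }

        stage = "network"
        variances = expr.std(axis=1, ddof=1)
        net_expr = expr.loc[variances > 0]
        n_excluded = int((variances == 0).sum())
        cor = correlation_matrix(net_expr)
        adj = signed_adjacency(cor, beta=config.network.beta)
        tom = tom_similarity(adj)
        assignment = detect_modules(tom, config.network)
        r2, signed_r2 = scale_free_fit(adj)
        pd.DataFrame(
            {"gene": assignment.module_of_gene.index,
             "module": assignment.module_of_gene.to_numpy()}
        ).to_csv(out / "modules.tsv", sep="\t", index=False)
        if assignment.linkage_matrix is not None:
            (out / "gene_dendrogram.newick").write_text(
                pio.linkage_to_newick(
                    assignment.linkage_matrix, list(net_expr.index)
                )
                + "\n"
            )
        report["stages"]["network"] = {
            "beta": config.network.beta,
            "n_genes_in_network": int(net_expr.shape[0]),
            "n_zero_variance_excluded": n_excluded,
            "n_modules": len(assignment.labels),
            "module_sizes": assignment.sizes(),
            "scale_free_r2": r2,
            "scale_free_signed_r2": signed_r2,
        }

        stage = "eigengenes"
        me = module_eigengenes(net_expr, assignment)
        me.values.to_csv(out / "eigengenes.tsv", sep="\t")
        report["stages"]["eigengenes"] = {
            "variance_explained": {
                str(k): v for k, v in me.variance_explained.items()
            }
        }

        stage = "enrichment"
        if gene_sets is not None and assignment.labels:
            ora = module_ora(
                assignment,
                gene_sets,
                background=list(expr.index),
                p_cutoff=config.ora_p_cutoff,
            )
            ora.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            report["stages"]["enrichment"] = {
                "n_tests": int(len(ora)),
                "n_significant": int(ora["significant"].sum()),
                "significant_terms": {
                    str(m): grp.loc[grp["significant"], "term"].tolist()
                    for m, grp in ora.groupby("module")
                },
            }
        else:
            report["stages"]["enrichment"] = {"n_tests": 0, "n_significant": 0}

        stage = "statistics"
        pairs = [
            (b, r)
            for b, r in meta.pairs()
            if b in expr.columns and r in expr.columns
        ]
        stats_report: dict = {"n_pairs": len(pairs)}

        # paired t on module eigengenes with multiplicity correction
        me_rows = []
        if assignment.labels and len(pairs) >= 2:
            for label in assignment.labels:
                design = PairedDesign.from_series(me.values.loc[label], pairs)
                try:
                    res = paired_t(design)
                except DegenerateDataError:
                    continue
                me_rows.append(
                    {
                        "module": label,
                        "mean_diff": float(np.mean(design.differences())),
                        "t": res.statistic,
                        "df": res.df,
                        "p_value": res.p_value,
                    }
                )
        me_table = pd.DataFrame(me_rows)
        if len(me_table):
            me_table["adjusted_p"] = _adjust(
                me_table["p_value"].to_numpy(), config.me_correction
            )
            me_table["significant"] = me_table["adjusted_p"] < 0.05
            me_table.to_csv(out / "module_tests.tsv", sep="\t", index=False)
            stats_report["module_eigengene_tests"] = me_table.to_dict("records")

        # per-gene paired t within the largest module, BH FDR
        if assignment.labels and len(pairs) >= 2:
            largest = assignment.labels[0]
            gene_rows = []
            for gene in assignment.members(largest):
                design = PairedDesign.from_series(expr.loc[gene], pairs)
                try:
                    res = paired_t(design)
                except DegenerateDataError:
                    continue
                gene_rows.append(
                    {"gene": gene, "t": res.statistic, "p_value": res.p_value}
                )
            gene_table = pd.DataFrame(gene_rows)
            if len(gene_table):
                gene_table["q_value"] = bh_fdr(gene_table["p_value"].to_numpy())
                gene_table["significant"] = gene_table["q_value"] < config.fdr_q
                gene_table = gene_table.sort_values(
                    ["p_value", "gene"], kind="mergesort"
                ).reset_index(drop=True)
                gene_table.to_csv(out / "gene_tests.tsv", sep="\t", index=False)
                stats_report["gene_tests_module"] = largest
                stats_report["n_genes_significant_fdr"] = int(
                    gene_table["significant"].sum()
                )
                stats_report["significant_genes"] = gene_table.loc[
                    gene_table["significant"], "gene"
                ].tolist()

        # sample clustering: two-group cut, McNemar, neighbour calls
        if len(pairs) >= 2 and expr.shape[1] >= 2:
            labels, zmat, leaf_order = cluster_samples(expr, k=2)
            (out / "sample_dendrogram.newick").write_text(
                pio.linkage_to_newick(zmat, list(expr.columns)) + "\n"
            )
            pair_table = paired_cluster_contingency(labels, pairs)
            pair_table.to_frame().to_csv(out / "pair_cluster_table.tsv", sep="\t")
            mcn = mcnemar_from_square_table(pair_table)
            stats_report["cluster_separation"] = {
                "table": pair_table.counts.tolist(),
                "mcnemar_p": mcn.p_value,
            }
            neigh = neighbour_pairs(zmat, list(expr.columns), pairs)
            arm_of_patient = meta.arm_of_patient()
            patient_of_sample = dict(
                meta.table[["sample", "patient"]].itertuples(index=False, name=None)
            )
            arms = [arm_of_patient[patient_of_sample[b]] for b, _ in pairs]
            stats_report["neighbour_pairs"] = {
                "n_neighbours": int(neigh.sum()),
                "fraction": float(neigh.mean()),
            }
            try:
                arm_table = neighbour_arm_table(neigh, arms)
                arm_table.to_frame().to_csv(
                    out / "neighbour_arm_table.tsv", sep="\t"
                )
                chi = pearson_chi2(arm_table, yates=config.chi2_yates)
                stats_report["neighbour_by_arm"] = {
                    "table": arm_table.counts.tolist(),
                    "chi2": chi.statistic,
                    "p_value": chi.p_value,
                }
            except ValueError as err:
                stats_report["neighbour_by_arm"] = {"error": str(err)}

        # low-abundance marker detection contingency
        ifng = config.ifng_gene
        if ifng and ifng in norm_out.detection.values.index:
            det = norm_out.detection.values.loc[ifng]
            tp = dict(
                meta.table[["sample", "timepoint"]].itertuples(index=False, name=None)
            )
            base_samples = [s for s in kept if tp.get(s) == SampleMeta.BASELINE]
            prog_samples = [s for s in kept if tp.get(s) == SampleMeta.PROGRESSION]
            table = detection_timepoint_table(
                int(det[base_samples].sum()),
                len(base_samples),
                int(det[prog_samples].sum()),
                len(prog_samples),
                gene=ifng,
            )
            entry: dict = {"table": table.counts.tolist()}
            try:
                chi = pearson_chi2(table, yates=config.chi2_yates)
                entry["chi2_p"] = chi.p_value
            except ValueError as err:
                entry["chi2_error"] = str(err)
            flips_pos_neg = sum(
                1 for b, r in pairs if det[b] and not det[r]
            )
            flips_neg_pos = sum(
                1 for b, r in pairs if not det[b] and det[r]
            )
            from .stats import mcnemar_exact

            entry["paired"] = {
                "b_pos_to_neg": flips_pos_neg,
                "c_neg_to_pos": flips_neg_pos,
                "mcnemar_p": mcnemar_exact(flips_pos_neg, flips_neg_pos).p_value,
            }
            stats_report["detection_marker"] = entry

        report["stages"]["statistics"] = stats_report
    except Exception as err:
        report["failed_stage"] = stage
        report["error"] = str(err)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, default=_json_default)
        )
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    results_blob = json.dumps(
        report["stages"], sort_keys=True, default=_json_default
    )
    report["results_hash"] = hashlib.sha256(results_blob.encode()).hexdigest()
    (out / "report.json").write_text(
        json.dumps(report, indent=1, default=_json_default)
    )
    return report
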