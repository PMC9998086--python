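"""End-to-end orchestration: regions -> quantify -> diff -> link -> cluster -> survive.

Each stage reads/writes plain-text files (BED/TSV/JSON) through the module
readers and records its input/output record counts, so any run reproduces a
stage-funnel summary (union peaks -> intergenic -> transcribed candidates ->
cohort-specific eRNAs).  All thresholds come from the config with the study
defaults (2000/500 bp exclusions, 250 bp merge, count >= 3, FPM >= 1.5,
|log2FC| > 0.5 at padj < 0.05, +/-100 kb correlation window, +/-200 kb net
window, Cox screen q < 0.1, signature size 6); there are no hidden
constants.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import classify, differential, linkage, quantify, survival
from .intervals import (
    RegionSet,
    TruncationParams,
    build_exclusion_zones,
    filter_intergenic_peaks,
    merge_peak_sets,
    read_annotation,
    read_bed,
    read_chrom_sizes,
)
from .quantify import QuantParams, read_fragments

logger = logging.getLogger("erna_scout")

__all__ = ["PipelineConfig", "ConfigError", "DataError", "run_pipeline"]


class ConfigError(ValueError):
    """Bad or inconsistent pipeline configuration."""


class DataError(ValueError):
    """Input data missing or malformed."""


@dataclass
class PipelineConfig:
    """All inputs, outputs and stage parameters of one pipeline run."""

    gtf: str
    chrom_sizes: str
    peaks: list[str]
    fragments: list[str]
    meta: str
    out_dir: str
    gene_expr: str | None = None
    survival_table: str | None = None
    upstream_exclude: int = 2000
    downstream_exclude: int = 500
    merge_distance: int = 250
    min_mean_count: float = 3.0
    min_mean_fpm: float = 1.5
    lfc_threshold: float = 0.5
    alpha: float = 0.05
    corr_half_window: int = 100_000
    net_half_window: int = 200_000
    screen_q: float = 0.1
    signature_size: int = 6
    cluster_k: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        missing = {"gtf", "chrom_sizes", "peaks", "fragments", "meta", "out_dir"} - set(raw)
        if missing:
            raise ConfigError(f"missing config key(s): {sorted(missing)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def _expand(patterns: list[str]) -> list[str]:
    out: list[str] = []
    for p in patterns:
        hits = sorted(glob.glob(p)) if any(ch in p for ch in "*?[") else [p]
        out.extend(hits)
    for p in out:
        if not os.path.exists(p):
            raise DataError(f"input not found: {p}")
    return out


def _sample_of(path: str, prefix: str) -> str:
    base = os.path.splitext(os.path.basename(path))[0]
    return base[len(prefix):] if base.startswith(prefix) else base


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns a report dict (also written to disk)."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    log_path = os.path.join(cfg.out_dir, "pipeline.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("run start: config_hash=%s seed=%d", cfg.config_hash(), cfg.seed)

    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "funnel": {}}
    funnel = report["funnel"]
    try:
        # ---- stage 1: regions --------------------------------------------
        stage = "regions"
        ann = read_annotation(cfg.gtf, read_chrom_sizes(cfg.chrom_sizes))
        peak_paths = _expand(cfg.peaks)
        peak_sets = [read_bed(p) for p in peak_paths]
        funnel["pooled_peaks"] = int(sum(len(ps) for ps in peak_sets))
        union = merge_peak_sets(peak_sets, cfg.merge_distance)
        funnel["union_peaks"] = len(union)
        tp = TruncationParams(cfg.upstream_exclude, cfg.downstream_exclude, cfg.merge_distance)
        zones = build_exclusion_zones(ann, tp)
        intergenic = filter_intergenic_peaks(union, zones)
        funnel["intergenic_regions"] = len(intergenic)
        intergenic.write_bed(os.path.join(cfg.out_dir, "regions.bed"))
        logger.info("%s: %d pooled -> %d union -> %d intergenic",
                    stage, funnel["pooled_peaks"], len(union), len(intergenic))

        # ---- stage 2: quantify -------------------------------------------
        stage = "quantify"
        meta = pd.read_csv(cfg.meta, sep="\t")
        if not {"sample_id", "cohort"} <= set(meta.columns):
            raise DataError("meta table needs sample_id and cohort columns")
        frag_paths = _expand(cfg.fragments)
        frag_by_sample = {_sample_of(p, "fragments_"): p for p in frag_paths}
        missing = [s for s in meta["sample_id"] if s not in frag_by_sample]
        if missing:
            raise DataError(f"no fragment file for sample(s): {missing}")
        frag_sets = [
            read_fragments(frag_by_sample[s], sample_id=s) for s in meta["sample_id"]
        ]
        cm = quantify.build_count_matrix(intergenic, frag_sets)
        qp = QuantParams(cfg.min_mean_count, cfg.min_mean_fpm)
        mask, cand = quantify.filter_candidates(cm, qp)
        funnel["candidate_regions"] = int(mask.sum())
        cand_regions = RegionSet(
            [iv for iv, keep in zip(intergenic, mask) if keep], sorted=True, merged=True
        )
        cm.to_frame("total").rename_axis("region_id").to_csv(
            os.path.join(cfg.out_dir, "counts.tsv"), sep="\t"
        )
        fpm = pd.DataFrame(
            quantify.compute_fpm(cand), index=cand.region_ids, columns=cand.sample_ids
        )
        fpm.rename_axis("region_id").to_csv(os.path.join(cfg.out_dir, "fpm.tsv"), sep="\t")
        quantify.region_directionality(cand).rename_axis("region_id").to_csv(
            os.path.join(cfg.out_dir, "directionality.tsv"), sep="\t"
        )
        cand_regions.write_bed(os.path.join(cfg.out_dir, "candidates.bed"))
        logger.info("%s: %d candidates pass count/FPM filter", stage, int(mask.sum()))

        # ---- stage 3: differential ---------------------------------------
        stage = "diff"
        cohorts = meta.set_index("sample_id").loc[cand.sample_ids, "cohort"].to_numpy()
        de = differential.run_differential(
            cand, cohorts, differential.DEParams(cfg.lfc_threshold, cfg.alpha)
        )
        de.to_csv(os.path.join(cfg.out_dir, "de.tsv"), sep="\t", index=False)
        n_a_spec = int((de["label"] == differential.LABEL_A).sum())
        n_b_spec = int((de["label"] == differential.LABEL_B).sum())
        funnel["A_specific"] = n_a_spec
        funnel["B_specific"] = n_b_spec
        funnel["discarded_undefined"] = int(de["pvalue"].isna().sum())
        logger.info("%s: %d A-specific, %d B-specific", stage, n_a_spec, n_b_spec)

        # ---- stage 4: linkage --------------------------------------------
        stage = "link"
        labels = pd.Series(de["label"].to_numpy(), index=de["region_id"])
        near = linkage.nearest_gene(cand_regions, ann)
        link = near
        if cfg.gene_expr:
            gene_expr = pd.read_csv(cfg.gene_expr, sep="\t", index_col=0)
            best, _rho = linkage.windowed_best_correlation(
                fpm, gene_expr, ann, cand_regions, cfg.corr_half_window
            )
            link = near.merge(best, on="region_id", how="left")
            nct = linkage.net_enhancer_change(ann, cand_regions, labels, cfg.net_half_window)
            in_a = meta["cohort"] == sorted(meta["cohort"].unique())[0]
            glfc = gene_expr.loc[:, meta.loc[~in_a, "sample_id"]].mean(axis=1) - gene_expr.loc[
                :, meta.loc[in_a, "sample_id"]
            ].mean(axis=1)
            nct["log2FC"] = nct["gene_id"].map(glfc)
            nct.to_csv(os.path.join(cfg.out_dir, "netchange.tsv"), sep="\t", index=False)
            try:
                summary, H, kw_p = linkage.bin_expression_shift(nct)
            except ValueError:
                # degenerate binning (e.g. no differential eRNAs called)
                logger.warning("link: <2 non-empty net-change bins; summary skipped")
                report["net_change_kw"] = None
            else:
                summary.to_csv(
                    os.path.join(cfg.out_dir, "netchange_bins.tsv"), sep="\t", index=False
                )
                report["net_change_kw"] = {"H": H, "p": kw_p}
        link.to_csv(os.path.join(cfg.out_dir, "linkage.tsv"), sep="\t", index=False)
        logger.info("%s: %d regions linked", stage, len(link))

        # ---- stage 5: classification -------------------------------------
        # samples cluster on the disease-specific (differential) eRNA
        # regions; all candidates are the fallback when too few are called
        stage = "cluster"
        de_regions = de.loc[de["label"] != differential.LABEL_NONE, "region_id"]
        clust_expr = fpm.loc[de_regions] if len(de_regions) >= 2 else fpm
        clust = classify.correlation_cluster(clust_expr, k=cfg.cluster_k)
        cohort_by_sample = meta.set_index("sample_id")["cohort"]
        mis = classify.misclassification_count(
            clust.labels.to_numpy(), cohort_by_sample.loc[clust.labels.index].to_numpy()
        )
        clust.misclassified_count = mis
        pd.DataFrame(
            {"sample_id": clust.labels.index, "cluster": clust.labels.to_numpy(),
             "cohort": cohort_by_sample.loc[clust.labels.index].to_numpy()}
        ).to_csv(os.path.join(cfg.out_dir, "clusters.tsv"), sep="\t", index=False)
        report["misclassified"] = mis
        logger.info("%s: %d samples misclassified", stage, mis)

        # ---- stage 6: survival (optional) --------------------------------
        stage = "survive"
        if cfg.survival_table and cfg.gene_expr and os.path.exists(cfg.survival_table):
            st = pd.read_csv(cfg.survival_table, sep="\t")
            surv = survival.SurvivalData(
                st["time"].to_numpy(), st["event"].to_numpy(), st["sample_id"].tolist()
            )
            gene_expr = pd.read_csv(cfg.gene_expr, sep="\t", index_col=0)
            gene_expr = gene_expr[st["sample_id"]]
            screen = survival.univariate_screen(gene_expr, surv, q=cfg.screen_q)
            screen.to_csv(os.path.join(cfg.out_dir, "cox_screen.tsv"), sep="\t", index=False)
            signature = survival.select_signature(screen, k=cfg.signature_size)
            report["signature"] = signature
            if signature:
                model = survival.build_risk_model(gene_expr, surv, signature)
                scores = model.risk_scores(gene_expr)
                groups = survival.median_split(scores, model.threshold)
                curves, chi2, p = survival.km_logrank(groups.to_numpy(), surv)
                with open(os.path.join(cfg.out_dir, "risk_model.json"), "w") as fh:
                    json.dump(
                        {"genes": model.gene_ids, "beta": model.beta.tolist(),
                         "threshold": model.threshold, "logrank_chi2": chi2, "logrank_p": p},
                        fh, indent=1,
                    )
                pd.concat(
                    [c.assign(group=g) for g, c in curves.items()]
                ).to_csv(os.path.join(cfg.out_dir, "km.tsv"), sep="\t", index=False)
                report["logrank"] = {"chi2": chi2, "p": p}
            else:
                logger.warning("survive: empty signature; no risk model built")
                report["signature"] = []
        else:
            logger.info("survive: no survival table supplied; stage skipped")
            report["survival_skipped"] = True
    except Exception:
        logger.exception("stage %s failed", stage)
        logger.removeHandler(handler)
        handler.close()
        raise
    pd.Series(funnel, name="count").rename_axis("stage").to_csv(
        os.path.join(cfg.out_dir, "funnel.tsv"), sep="\t"
    )
    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    with open(os.path.join(cfg.out_dir, "effective_config.yaml"), "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    logger.info("run complete")
    logger.removeHandler(handler)
    handler.close()
    return report
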