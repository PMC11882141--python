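"""End-to-end pipeline: surrogate discovery -> RCS -> deviations -> clusters.

``run_all`` executes the full analysis from files on disk and writes a
self-describing artifact directory (scores, deviations, clusters, rank
files and a JSON manifest carrying the tool version, seed and config
hash).  Outputs are byte-identical across reruns with the same seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import cluster_deviation, export_rank, ward_cluster
from .discovery import surrogate_ancestors, surrogate_descendants
from .io import (
    config_hash,
    read_bulk,
    read_perturb,
    write_matrix_tsv,
    write_surrogates,
)
from .qc import drop_missing_phenotype, filter_low_expression, intersect_genes
from .rcs import covariate_scores, rcs_scores, sd_scores
from .regression import RegressorSpec

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger("rcsp")


@dataclass
class RunConfig:
    bulk_counts: str
    bulk_samples: str
    perturb_mtx: str
    perturb_features: str
    perturb_barcodes: str
    perturb_targets: str
    out_dir: str
    regressor: str = "adaptive-splines"
    alpha: float = 0.05
    correction: str = "bh"
    min_mean_count: float = 0.0
    k_clusters: int | None = None  # None -> elbow suggestion
    k_range_max: int = 10
    seed: int = 0
    log_level: str = "INFO"

    def analysis_params(self) -> dict:
        """The parameters that determine outputs; paths excluded so reruns
        into a different directory stay byte-identical."""
        return {
            "regressor": self.regressor,
            "alpha": self.alpha,
            "correction": self.correction,
            "min_mean_count": self.min_mean_count,
            "k_clusters": self.k_clusters,
            "k_range_max": self.k_range_max,
            "seed": self.seed,
        }

    def validate(self) -> None:
        for name in (
            "bulk_counts",
            "bulk_samples",
            "perturb_mtx",
            "perturb_features",
            "perturb_barcodes",
            "perturb_targets",
        ):
            path = Path(getattr(self, name))
            if not path.exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    conf_dict = config.analysis_params()
    seed = config.seed
    artifacts: list[str] = []
    stage = "read"
    try:
        bulk = read_bulk(config.bulk_counts, config.bulk_samples)
        perturb = read_perturb(
            config.perturb_mtx,
            config.perturb_features,
            config.perturb_barcodes,
            config.perturb_targets,
        )
        stage = "qc"
        bulk = drop_missing_phenotype(bulk)
        if config.min_mean_count > 0:
            bulk = filter_low_expression(bulk, config.min_mean_count)
        bulk, perturb = intersect_genes(bulk, perturb)
        logger.info("aligned data: %d samples, %d cells, %d genes",
                    bulk.n_samples, perturb.n_cells, bulk.n_genes)

        stage = "surrogate-discovery"
        sets = surrogate_ancestors(
            surrogate_descendants(perturb, alpha=config.alpha, correction=config.correction)
        )
        write_surrogates(sets, bulk.gene_names, out / "surrogates.tsv", seed=seed)
        artifacts.append("surrogates.tsv")

        stage = "rcs"
        spec = RegressorSpec(method=config.regressor, seed=seed)
        res = rcs_scores(bulk, sets, spec)
        sd = sd_scores(bulk, spec)
        for name, matrix in (
            ("gamma", res.gamma),
            ("phi", res.phi),
            ("omega", sd.omega),
        ):
            write_matrix_tsv(
                matrix, bulk.sample_names, bulk.gene_names, out / f"{name}.tsv",
                seed=seed, config=conf_dict,
            )
            artifacts.append(f"{name}.tsv")

        stage = "deviation"
        flags = res.flags
        drcs = pd.DataFrame(
            {"drcs": res.drcs, "flag": flags}, index=pd.Index(bulk.gene_names, name="gene")
        )
        dsd = pd.DataFrame(
            {"dsd": sd.dsd, "flag": sd.flags}, index=pd.Index(bulk.gene_names, name="gene")
        )
        for name, frame in (("drcs", drcs), ("dsd", dsd)):
            header = "\n".join([f"# rcsp\tversion={__version__}\tseed={seed}", ""])
            with open(out / f"{name}.tsv", "w") as fh:
                fh.write(header)
                frame.to_csv(fh, sep="\t")
            artifacts.append(f"{name}.tsv")
        if bulk.covariates is not None and bulk.covariates.shape[1] > 0:
            cov = covariate_scores(bulk, spec)
            cov_frame = pd.DataFrame(
                {"drcs": pd.Series(cov.covariate_drcs)}
            ).rename_axis("covariate")
            cov_frame.to_csv(out / "covariate_drcs.tsv", sep="\t")
            artifacts.append("covariate_drcs.tsv")

        stage = "cluster"
        k_range = range(1, min(config.k_range_max, bulk.n_samples) + 1)
        clusters = ward_cluster(res.phi, k_range=k_range, k=config.k_clusters)
        pd.DataFrame(
            {"cluster": clusters.assignments},
            index=pd.Index(bulk.sample_names, name="sample"),
        ).to_csv(out / "clusters.tsv", sep="\t")
        clusters.wss_curve.rename_axis("k").to_csv(out / "wss.tsv", sep="\t")
        artifacts += ["clusters.tsv", "wss.tsv"]

        stage = "rank-export"
        export_rank(pd.Series(res.drcs, index=bulk.gene_names), out / "drcs.rnk")
        artifacts.append("drcs.rnk")
        per_cluster = cluster_deviation(res.phi, clusters.assignments, bulk.gene_names)
        for c in per_cluster.index:
            name = f"drcs_cluster{c}.rnk"
            export_rank(per_cluster.loc[c], out / name)
            artifacts.append(name)
    except Exception as exc:
        manifest = {
            "version": __version__,
            "seed": seed,
            "config_hash": config_hash(conf_dict),
            "status": "failed",
            "failed_stage": stage,
            "error": str(exc),
            "artifacts": artifacts,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(conf_dict),
        "status": "ok",
        "n_samples": int(bulk.n_samples),
        "n_genes": int(bulk.n_genes),
        "n_cells": int(perturb.n_cells),
        "k_selected": int(clusters.k_selected),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
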