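"""Quality-control filters for bulk / Perturb-seq integration.

Mirrors the preprocessing applied to public cohort data before scoring:
drop samples without a phenotype, remove weakly expressed genes, and
restrict both modalities to the genes measured *and* perturbed in the
screen (only those genes have usable interventional evidence).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import BulkData, PerturbSeqData

__all__ = ["drop_missing_phenotype", "filter_low_expression", "intersect_genes"]


def drop_missing_phenotype(bulk: BulkData) -> BulkData:
    """Remove samples whose phenotype is NaN."""
    keep = ~np.isnan(bulk.y)
    return BulkData(
        counts=bulk.counts[keep],
        y=bulk.y[keep],
        batch=bulk.batch[keep],
        gene_names=list(bulk.gene_names),
        sample_names=[s for s, k in zip(bulk.sample_names, keep) if k],
        covariates=None if bulk.covariates is None else bulk.covariates.loc[keep].reset_index(drop=True),
    )


def filter_low_expression(bulk: BulkData, min_mean: float = 5.0) -> BulkData:
    """Keep genes whose mean count is at least ``min_mean``."""
    keep = bulk.counts.mean(axis=0) >= min_mean
    return BulkData(
        counts=bulk.counts[:, keep],
        y=bulk.y,
        batch=bulk.batch,
        gene_names=[g for g, k in zip(bulk.gene_names, keep) if k],
        sample_names=list(bulk.sample_names),
        covariates=bulk.covariates,
    )


def intersect_genes(
    bulk: BulkData, perturb: PerturbSeqData
) -> tuple[BulkData, PerturbSeqData]:
    """Restrict both datasets to their shared gene symbols (bulk order).

    Perturbation targets outside the intersection become control-excluded:
    their cells are dropped, since the perturbed transcript is no longer
    measured.
    """
    shared = [g for g in bulk.gene_names if g in set(perturb.gene_names)]
    if not shared:
        raise ValueError("no shared genes between bulk and perturb-seq data")
    b_idx = [bulk.gene_names.index(g) for g in shared]
    p_index = {g: i for i, g in enumerate(perturb.gene_names)}
    p_idx = [p_index[g] for g in shared]
    new_bulk = BulkData(
        counts=bulk.counts[:, b_idx],
        y=bulk.y,
        batch=bulk.batch,
        gene_names=shared,
        sample_names=list(bulk.sample_names),
        covariates=bulk.covariates,
    )
    # remap perturbation labels into the shared ordering
    old_to_new = {p_index[g]: k for k, g in enumerate(shared)}
    labels = perturb.perturbation
    keep_cells = np.array(
        [t == -1 or t in old_to_new for t in labels], dtype=bool
    )
    remapped = np.array(
        [-1 if t == -1 else old_to_new[t] for t in labels[keep_cells]], dtype=int
    )
    new_perturb = PerturbSeqData(
        counts=perturb.counts[np.ix_(keep_cells, p_idx)],
        perturbation=remapped,
        batch=perturb.batch[keep_cells],
        gene_names=shared,
        cell_names=[c for c, k in zip(perturb.cell_names, keep_cells) if k],
    )
    return new_bulk, new_perturb
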