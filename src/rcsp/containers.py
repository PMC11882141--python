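"""Shared data containers for bulk RNA-seq and Perturb-seq matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BulkData", "PerturbSeqData", "CONTROL_LABEL", "CONTROL_ALIASES"]

CONTROL_LABEL = "control"
#: Accepted spellings of the non-targeting control condition.
CONTROL_ALIASES = {"control", "non-targeting", "non targeting", "ntc", "nt", "neg"}


@dataclass
class BulkData:
    """Bulk RNA-seq counts with per-sample phenotype, batch and covariates.

    ``counts`` is samples x genes, integer valued.  ``covariates`` (optional)
    is a DataFrame aligned to samples (e.g. age, sex).
    """

    counts: np.ndarray
    y: np.ndarray
    batch: np.ndarray
    gene_names: list[str]
    sample_names: list[str] = field(default_factory=list)
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)):
                raise ValueError("bulk counts must be integers")
            self.counts = self.counts.astype(np.int64)
        self.y = np.asarray(self.y, dtype=float)
        self.batch = np.asarray(self.batch, dtype=int)
        n, p = self.counts.shape
        if len(self.y) != n or len(self.batch) != n:
            raise ValueError("y and batch must have one entry per sample")
        if len(self.gene_names) != p:
            raise ValueError("gene_names must have one entry per gene")
        if not self.sample_names:
            self.sample_names = [f"S{j}" for j in range(n)]
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariates must align with samples")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def library_size(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class PerturbSeqData:
    """Single-cell counts with a per-cell perturbation target and batch.

    ``perturbation`` holds the index of the knocked-down gene, or -1 for
    control cells.
    """

    counts: np.ndarray
    perturbation: np.ndarray
    batch: np.ndarray
    gene_names: list[str]
    cell_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)):
                raise ValueError("perturb-seq counts must be integers")
            self.counts = self.counts.astype(np.int64)
        self.perturbation = np.asarray(self.perturbation, dtype=int)
        self.batch = np.asarray(self.batch, dtype=int)
        n, p = self.counts.shape
        if len(self.perturbation) != n or len(self.batch) != n:
            raise ValueError("perturbation and batch must have one entry per cell")
        if len(self.gene_names) != p:
            raise ValueError("gene_names must have one entry per gene")
        bad = (self.perturbation < -1) | (self.perturbation >= p)
        if np.any(bad):
            raise ValueError("perturbation labels must be gene indices or -1")
        if not np.any(self.perturbation == -1):
            raise ValueError("at least one control cell is required")
        if not self.cell_names:
            self.cell_names = [f"C{j}" for j in range(n)]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def perturbed_genes(self) -> np.ndarray:
        return np.unique(self.perturbation[self.perturbation >= 0])
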