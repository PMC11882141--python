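"""Surrogate descendant/ancestor discovery from Perturb-seq.

Perturbing a gene shifts the marginal distribution of every downstream
gene, so an unpaired two-sided Welch t-test of each measured gene between
the cells of one knockdown condition and the control cells flags the
perturbed gene's surrogate descendants.  Inverting the descendant sets
yields each gene's surrogate ancestors, the conditioning sets of the root
causal strength regressions.  Tests run on raw per-cell counts without
normalization — the t statistic averages over cells, mimicking a bulk
measurement — and pool cells across batches, since the perturbation
indicator is not a child of the batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import PerturbSeqData

__all__ = ["SurrogateSets", "two_sided_ttest", "surrogate_descendants", "surrogate_ancestors"]

Correction = Literal["none", "bonferroni", "bh"]


@dataclass
class SurrogateSets:
    """Per-gene surrogate descendant (SD) and ancestor (SA) index sets.

    ``descendants[i]`` holds the genes whose counts shifted under the
    knockdown of gene ``i``; defined only for perturbed genes.
    ``ancestors[i]`` = { j != i : i in SD(j) } and never contains ``i``.
    ``pvalues[k, i]`` is the raw p-value of gene ``k`` under perturbation
    ``i`` (NaN when gene ``i`` was never perturbed).
    """

    n_genes: int
    descendants: dict[int, set[int]]
    pvalues: np.ndarray
    alpha: float
    correction: Correction
    ancestors: dict[int, set[int]] = field(default_factory=dict)
    unperturbed: set[int] = field(default_factory=set)

    def sa(self, i: int) -> set[int]:
        return self.ancestors.get(i, set())


def two_sided_ttest(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Welch unequal-variance t-test (two-sided).

    Degenerate inputs (zero variance in both groups) are reported as
    non-significant (statistic 0, p-value 1) with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        warnings.warn("both groups degenerate with unequal means; p undefined, reported as 1")
        return 0.0, 1.0
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)


def _significant(pvals: np.ndarray, alpha: float, correction: Correction) -> np.ndarray:
    clean = np.where(np.isnan(pvals), 1.0, pvals)
    if correction == "none":
        return clean <= alpha
    if correction == "bonferroni":
        return multipletests(clean, alpha=alpha, method="bonferroni")[0]
    if correction == "bh":
        return multipletests(clean, alpha=alpha, method="fdr_bh")[0]
    raise ValueError(f"unknown correction {correction!r}")


def surrogate_descendants(
    data: PerturbSeqData,
    alpha: float = 0.05,
    correction: Correction = "bh",
) -> SurrogateSets:
    """Find SD(i) for every perturbed gene i by control-vs-knockdown tests.

    The multiplicity correction is applied within each perturbation (one
    family of p tests per knockdown).  Genes never perturbed receive
    ``SD = {self}`` and are flagged in ``unperturbed``.
    """
    control = data.counts[data.perturbation == -1]
    if control.shape[0] < 2:
        raise ValueError("at least two control cells are required")
    p = data.counts.shape[1]
    pmat = np.full((p, p), np.nan)
    descendants: dict[int, set[int]] = {}
    unperturbed = set(range(p))
    control_f = control.astype(float)
    for i in np.unique(data.perturbation[data.perturbation >= 0]):
        cells = data.counts[data.perturbation == i].astype(float)
        if cells.shape[0] < 2:
            raise ValueError(f"perturbation of gene {i} has fewer than two cells")
        with np.errstate(divide="ignore", invalid="ignore"):
            _, pvals = stats.ttest_ind(cells, control_f, axis=0, equal_var=False)
        # zero variance in both groups -> identical constant counts -> p=1
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        pmat[:, i] = pvals
        sig = _significant(pvals, alpha, correction)
        descendants[int(i)] = set(np.nonzero(sig)[0].tolist())
        unperturbed.discard(int(i))
    for i in unperturbed:
        descendants[i] = {i}
    return SurrogateSets(
        n_genes=p,
        descendants=descendants,
        pvalues=pmat,
        alpha=alpha,
        correction=correction,
        unperturbed=unperturbed,
    )


def surrogate_ancestors(sd: SurrogateSets) -> SurrogateSets:
    """Fill in SA(i) = { j != i : i in SD(j) } by inverting the SD sets.

    Only perturbed genes j contribute: the placeholder ``SD = {self}`` of
    an unperturbed gene carries no interventional evidence.
    """
    ancestors: dict[int, set[int]] = {i: set() for i in range(sd.n_genes)}
    for j, desc in sd.descendants.items():
        if j in sd.unperturbed:
            continue
        for i in desc:
            if i != j:
                ancestors[i].add(j)
    sd.ancestors = ancestors
    return sd
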