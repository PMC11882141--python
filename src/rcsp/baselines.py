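"""Comparator scorers and the RMSE benchmarking harness.

Four baselines are scored against the root causal strength estimator on
identical simulated data:

* ANM — additive-noise-model error extraction: nonlinear regression of
  each gene on its parents and the batch recovers residuals as error-term
  estimates; the score is |E(Y | errors except i) - E(Y | X, B)|.
* LiNGAM — the same construction with ordinary least squares.
* Uni Reg — per-gene absolute residual |Y - E(Y | X_i, B)|.
* Multi Reg — leave-one-gene-out absolute residual |Y - E(Y | X \\ X_i, B)|.

All methods consume the same z-scored predictor matrix; the phenotype is
left on its original scale so every score is comparable to the ground
truth Phi in Y's units.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BulkData
from .discovery import surrogate_ancestors, surrogate_descendants
from .graph import relatives
from .rcs import _prepare, rcs_scores
from .regression import RegressorSpec, fit_conditional_mean
from .simulate import oracle_rcs, sample_sem, simulate_bulk, simulate_perturbseq

__all__ = [
    "BenchmarkReport",
    "anm_scores",
    "lingam_scores",
    "unireg_scores",
    "multireg_scores",
    "rmse",
    "benchmark",
]

METHODS = ("rcsp", "anm", "lingam", "uni", "multi")


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class BenchmarkReport:
    """Per-method, per-replicate RMSE to the ground-truth Phi."""

    rmse: pd.DataFrame  # replicates x methods
    runtime: pd.DataFrame  # replicates x methods, seconds
    seeds: list[int]
    pairwise_p: pd.DataFrame = field(default=None)

    def paired_tests(self) -> pd.DataFrame:
        """Paired two-sided t-tests between all method pairs."""
        methods = list(self.rmse.columns)
        out = pd.DataFrame(np.ones((len(methods), len(methods))), index=methods, columns=methods)
        for i, a in enumerate(methods):
            for b in methods[i + 1 :]:
                diff = self.rmse[a] - self.rmse[b]
                if np.allclose(diff, 0):
                    p = 1.0
                else:
                    p = float(stats.ttest_rel(self.rmse[a], self.rmse[b]).pvalue)
                out.loc[a, b] = out.loc[b, a] = p
        return out


def _ols_fit(x: np.ndarray, y: np.ndarray):
    design = np.column_stack([np.ones(len(y)), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return lambda z: np.column_stack([np.ones(z.shape[0]), z]) @ coef


def _residual_matrix(
    z: np.ndarray, extra: np.ndarray, parent_sets: dict[int, set[int]], spec, linear: bool
) -> np.ndarray:
    """Per-gene regression residuals of X_i on Pa(X_i) u B: the additive
    noise model's error-term estimates.  A parentless gene's residual is
    its (standardized) observed value."""
    n, p = z.shape
    resid = np.empty((n, p))
    for i in range(p):
        pa = sorted(j for j in parent_sets.get(i, set()) if j != i)
        feats = np.column_stack([z[:, pa], extra]) if pa or extra.size else None
        if feats is None or feats.shape[1] == 0:
            resid[:, i] = z[:, i]
            continue
        if linear:
            pred = _ols_fit(feats, z[:, i])(feats)
        else:
            pred = fit_conditional_mean(feats, z[:, i], spec)(feats)
        resid[:, i] = z[:, i] - pred
    return resid


def _error_based_scores(
    bulk: BulkData,
    parent_sets: dict[int, set[int]],
    spec: RegressorSpec | None,
    linear: bool,
) -> np.ndarray:
    spec = spec or RegressorSpec()
    z, _, extra, _ = _prepare(bulk)
    n, p = z.shape
    resid = _residual_matrix(z, extra, parent_sets, spec, linear)
    y = bulk.y
    full_feats = np.column_stack([z, extra]) if extra.size else z
    if linear:
        ref = _ols_fit(full_feats, y)(full_feats)
    else:
        ref = fit_conditional_mean(full_feats, y, spec)(full_feats)
    scores = np.empty((n, p))
    for i in range(p):
        others = np.delete(resid, i, axis=1)
        feats = np.column_stack([others, extra]) if extra.size else others
        if feats.shape[1] == 0:
            pred = np.full(n, y.mean())
        elif linear:
            pred = _ols_fit(feats, y)(feats)
        else:
            pred = fit_conditional_mean(feats, y, spec)(feats)
        scores[:, i] = np.abs(pred - ref)
    return scores


def anm_scores(
    bulk: BulkData, parent_sets: dict[int, set[int]], spec: RegressorSpec | None = None
) -> np.ndarray:
    """Additive noise model scores |E(Y|E\\E_i) - E(Y|X,B)| per sample."""
    return _error_based_scores(bulk, parent_sets, spec, linear=False)


def lingam_scores(bulk: BulkData, parent_sets: dict[int, set[int]]) -> np.ndarray:
    """LiNGAM-style scores: as ANM with ordinary least squares."""
    return _error_based_scores(bulk, parent_sets, None, linear=True)


def unireg_scores(bulk: BulkData, spec: RegressorSpec | None = None) -> np.ndarray:
    """Univariate-regression absolute residuals |Y - E(Y|X_i,B)|."""
    spec = spec or RegressorSpec()
    z, _, extra, _ = _prepare(bulk)
    n, p = z.shape
    out = np.empty((n, p))
    for i in range(p):
        feats = np.column_stack([z[:, [i]], extra]) if extra.size else z[:, [i]]
        pred = fit_conditional_mean(feats, bulk.y, spec)(feats)
        out[:, i] = np.abs(bulk.y - pred)
    return out


def multireg_scores(bulk: BulkData, spec: RegressorSpec | None = None) -> np.ndarray:
    """Leave-one-gene-out absolute residuals |Y - E(Y|X\\X_i,B)|."""
    spec = spec or RegressorSpec()
    z, _, extra, _ = _prepare(bulk)
    n, p = z.shape
    out = np.empty((n, p))
    for i in range(p):
        others = np.delete(z, i, axis=1)
        feats = np.column_stack([others, extra]) if extra.size else others
        if feats.shape[1] == 0:
            pred = np.full(n, bulk.y.mean())
        else:
            pred = fit_conditional_mean(feats, bulk.y, spec)(feats)
        out[:, i] = np.abs(bulk.y - pred)
    return out


def _true_parent_sets(sem) -> dict[int, set[int]]:
    genes = sem.gene_indices()
    pos = {int(g): k for k, g in enumerate(genes)}
    out = {}
    for k, g in enumerate(genes):
        out[k] = {pos[a] for a in sem.graph.parents(int(g)) if a in pos}
    return out


def _oracle_sa_sets(sem) -> dict[int, set[int]]:
    genes = sem.gene_indices()
    pos = {int(g): k for k, g in enumerate(genes)}
    out = {}
    for k, g in enumerate(genes):
        anc = relatives(sem.graph, int(g), "ancestors") - {int(g)}
        out[k] = {pos[a] for a in anc if a in pos}
    return out


def benchmark(
    methods: tuple[str, ...] = METHODS,
    n_replicates: int = 10,
    n_vertices: int = 51,
    n_bulk: int = 200,
    cells_per_condition: int = 50,
    n_batches_perturb: int = 10,
    seed: int = 0,
    spec: RegressorSpec | None = None,
    alpha: float = 0.05,
    use_true_parents: bool = True,
) -> BenchmarkReport:
    """Replicated RMSE comparison of all scorers on fresh simulated data.

    Each replicate draws a new SEM, bulk cohort and Perturb-seq screen.
    RCSP discovers ancestors from the Perturb-seq screen; ANM/LiNGAM are
    given the true parent sets (``use_true_parents=False`` hands them the
    perturbation-derived sets instead).  All methods score identical data.
    """
    if not methods:
        raise ValueError("no methods requested")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    spec = spec or RegressorSpec()
    edge_prob = 2.0 / (n_vertices - 2)  # expected neighborhood size 2
    rows, times = [], []
    seeds = [seed + 1000 * r for r in range(n_replicates)]
    for rep_seed in seeds:
        rng = np.random.default_rng(rep_seed)
        sem = sample_sem(n_vertices, edge_prob, rng)
        bulk, latent = simulate_bulk(sem, n_bulk, seed=rng)
        truth = oracle_rcs(sem, latent)
        row, trow = {}, {}
        for method in methods:
            t0 = time.perf_counter()
            if method == "rcsp":
                perturb = simulate_perturbseq(
                    sem, cells_per_condition, n_batches_perturb, seed=rng
                )
                sets = surrogate_ancestors(surrogate_descendants(perturb, alpha=alpha))
                scores = rcs_scores(bulk, sets, spec).phi
            elif method in ("anm", "lingam"):
                psets = (
                    _true_parent_sets(sem)
                    if use_true_parents
                    else None
                )
                if psets is None:
                    perturb = simulate_perturbseq(
                        sem, cells_per_condition, n_batches_perturb, seed=rng
                    )
                    sets = surrogate_ancestors(surrogate_descendants(perturb, alpha=alpha))
                    psets = {i: sets.sa(i) for i in range(bulk.n_genes)}
                scores = (
                    anm_scores(bulk, psets, spec)
                    if method == "anm"
                    else lingam_scores(bulk, psets)
                )
            elif method == "uni":
                scores = unireg_scores(bulk, spec)
            else:
                scores = multireg_scores(bulk, spec)
            row[method] = rmse(scores, truth.phi_true)
            trow[method] = time.perf_counter() - t0
        rows.append(row)
        times.append(trow)
    report = BenchmarkReport(
        rmse=pd.DataFrame(rows, columns=list(methods)),
        runtime=pd.DataFrame(times, columns=list(methods)),
        seeds=seeds,
    )
    report.pairwise_p = report.paired_tests()
    return report
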