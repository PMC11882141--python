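"""Readers and writers for the package's external formats.

Bulk counts travel as TSV (genes x samples by default, orientation
recorded in a header comment), sample metadata as TSV with ``sample``,
``y`` and ``batch`` columns plus optional covariates.  Perturb-seq counts
use Matrix Market coordinate format (genes x cells, the single-cell
convention) with positionally aligned features/barcodes/perturbations
TSVs.  Every writer emits ``#`` header comments carrying the tool version,
seed and config hash; every reader tolerates them.  Count matrices are
read and written integer-exact.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import __version__
from .containers import CONTROL_ALIASES, CONTROL_LABEL, BulkData, PerturbSeqData
from .discovery import SurrogateSets

__all__ = [
    "header_lines",
    "write_bulk",
    "read_bulk",
    "write_perturb",
    "read_perturb",
    "write_surrogates",
    "read_surrogates",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def header_lines(seed=None, config: dict | None = None, **extra) -> list[str]:
    items = {"version": __version__}
    if seed is not None:
        items["seed"] = seed
    if config is not None:
        items["config"] = config_hash(config)
    items.update(extra)
    joined = "\t".join(f"{k}={v}" for k, v in items.items())
    return [f"# rcsp\t{joined}"]


def _write_frame(frame: pd.DataFrame, path: Path, seed=None, config=None, **extra) -> None:
    with open(path, "w") as fh:
        for line in header_lines(seed=seed, config=config, **extra):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Bulk RNA-seq


def write_bulk(
    bulk: BulkData, counts_path: str | Path, samples_path: str | Path, seed=None
) -> None:
    counts = pd.DataFrame(
        bulk.counts.T, index=bulk.gene_names, columns=bulk.sample_names
    ).rename_axis("gene")
    _write_frame(counts, Path(counts_path), seed=seed, orientation="genes-by-samples")
    meta = pd.DataFrame(
        {"y": bulk.y, "batch": bulk.batch}, index=pd.Index(bulk.sample_names, name="sample")
    )
    if bulk.covariates is not None:
        for col in bulk.covariates.columns:
            meta[col] = np.asarray(bulk.covariates[col])
    _write_frame(meta, Path(samples_path), seed=seed)


def _read_tsv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            for part in line[1:].strip().split("\t"):
                if "=" in part:
                    k, v = part.split("=", 1)
                    meta[k] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    return frame, meta


def read_bulk(
    counts_path: str | Path,
    samples_path: str | Path,
    orientation: str = "auto",
) -> BulkData:
    """Read bulk counts + sample metadata into an aligned :class:`BulkData`.

    ``orientation`` is ``genes-by-samples``, ``samples-by-genes`` or
    ``auto`` (use the header flag, defaulting to genes-by-samples).
    """
    counts, meta = _read_tsv(counts_path)
    samples, _ = _read_tsv(samples_path)
    if orientation == "auto":
        orientation = meta.get("orientation", "genes-by-samples")
    if orientation == "genes-by-samples":
        counts = counts.T  # -> samples x genes
    elif orientation != "samples-by-genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    genes = [str(g) for g in counts.columns]
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
    for col in ("y", "batch"):
        if col not in samples.columns:
            raise ValueError(f"samples table lacks required column {col!r}")
    missing = [s for s in counts.index.astype(str) if s not in samples.index.astype(str)]
    if missing:
        raise ValueError(f"samples present in counts but absent from metadata: {missing[:5]}")
    samples = samples.loc[counts.index]
    bad = samples.index[samples["y"].isna()].tolist()
    if bad:
        raise ValueError(f"missing phenotype y for samples (rows): {bad[:5]}")
    covar_cols = [c for c in samples.columns if c not in ("y", "batch")]
    covariates = samples[covar_cols].copy() if covar_cols else None
    return BulkData(
        counts=counts.to_numpy(dtype=np.int64),
        y=samples["y"].to_numpy(dtype=float),
        batch=samples["batch"].to_numpy(dtype=int),
        gene_names=genes,
        sample_names=[str(s) for s in counts.index],
        covariates=covariates,
    )


# ---------------------------------------------------------------------------
# Perturb-seq


def write_perturb(data: PerturbSeqData, out_dir: str | Path, seed=None) -> None:
    """MTX (genes x cells) + features.tsv + barcodes.tsv + perturbations.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(
        out / "matrix.mtx",
        sparse.csr_matrix(data.counts.T),
        field="integer",
        comment="rcsp perturb-seq counts, genes x cells",
    )
    (out / "features.tsv").write_text("\n".join(data.gene_names) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(data.cell_names) + "\n")
    labels = [
        CONTROL_LABEL if t < 0 else data.gene_names[t] for t in data.perturbation
    ]
    lines = header_lines(seed=seed) + ["cell_id\ttarget\tbatch"]
    for cell, lab, batch in zip(data.cell_names, labels, data.batch):
        lines.append(f"{cell}\t{lab}\t{batch}")
    (out / "perturbations.tsv").write_text("\n".join(lines) + "\n")


def read_perturb(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    perturbations_path: str | Path,
    gene_map: dict[str, str] | None = None,
) -> PerturbSeqData:
    """Read an MTX-based Perturb-seq deposit.

    Target labels are matched case-sensitively against the feature list
    (``gene_map`` translates deposit-specific symbols first); control
    aliases such as "non-targeting" are accepted.  Cells with unknown
    target labels are dropped with a reported count.
    """
    mat = spio.mmread(str(mtx_path)).tocsr()  # genes x cells
    features = [ln.split("\t")[0] for ln in Path(features_path).read_text().splitlines() if ln]
    barcodes = [ln.strip() for ln in Path(barcodes_path).read_text().splitlines() if ln]
    if mat.shape[0] != len(features) or mat.shape[1] != len(barcodes):
        raise ValueError(
            f"MTX dimensions {mat.shape} disagree with features ({len(features)}) "
            f"/ barcodes ({len(barcodes)})"
        )
    pert, _ = _read_tsv(perturbations_path)
    pert.index = pert.index.astype(str)
    index = {g: i for i, g in enumerate(features)}
    targets = np.empty(len(barcodes), dtype=int)
    keep = np.ones(len(barcodes), dtype=bool)
    for j, cell in enumerate(barcodes):
        if cell not in pert.index:
            keep[j] = False
            continue
        raw = str(pert.loc[cell, "target"])
        label = gene_map.get(raw, raw) if gene_map else raw
        if label.lower() in CONTROL_ALIASES:
            targets[j] = -1
        elif label in index:
            targets[j] = index[label]
        else:
            keep[j] = False
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} cells with unknown perturbation targets")
    counts = np.asarray(mat.T.todense())[keep].astype(np.int64)
    batch = pert.loc[np.array(barcodes)[keep], "batch"].to_numpy(dtype=int)
    return PerturbSeqData(
        counts=counts,
        perturbation=targets[keep],
        batch=batch,
        gene_names=features,
        cell_names=[b for b, k in zip(barcodes, keep) if k],
    )


# ---------------------------------------------------------------------------
# Surrogate sets and score matrices


def write_surrogates(sets: SurrogateSets, gene_names: list[str], path: str | Path, seed=None) -> None:
    """SA/SD adjacency pairs as TSV: gene, relative, role, p_value."""
    lines = header_lines(
        seed=seed, alpha=sets.alpha, correction=sets.correction, n_genes=sets.n_genes
    )
    lines.append("gene\trelative\trole\tp_value")
    for i in sorted(sets.descendants):
        flag = "unperturbed" if i in sets.unperturbed else "perturbed"
        if not sets.descendants[i]:
            # explicit marker so empty sets survive the round trip
            lines.append(f"{gene_names[i]}\t-\tdescendant:{flag}\t")
        for k in sorted(sets.descendants[i]):
            p = sets.pvalues[k, i]
            ptxt = "" if np.isnan(p) else f"{p:.6g}"
            lines.append(f"{gene_names[i]}\t{gene_names[k]}\tdescendant:{flag}\t{ptxt}")
    for i in sorted(sets.ancestors):
        for j in sorted(sets.ancestors[i]):
            lines.append(f"{gene_names[i]}\t{gene_names[j]}\tancestor\t")
    Path(path).write_text("\n".join(lines) + "\n")


def read_surrogates(path: str | Path, gene_names: list[str]) -> SurrogateSets:
    index = {g: i for i, g in enumerate(gene_names)}
    meta: dict[str, str] = {}
    descendants: dict[int, set[int]] = {}
    ancestors: dict[int, set[int]] = {i: set() for i in range(len(gene_names))}
    unperturbed: set[int] = set()
    p = len(gene_names)
    pvals = np.full((p, p), np.nan)
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            for part in line[1:].strip().split("\t"):
                if "=" in part:
                    k, v = part.split("=", 1)
                    meta[k] = v
            continue
        if not line or line.startswith("gene\t"):
            continue
        gene, rel, role, ptxt = line.split("\t")
        i = index[gene]
        if rel == "-":
            descendants.setdefault(i, set())
            if role.endswith("unperturbed"):
                unperturbed.add(i)
            continue
        k = index[rel]
        if role.startswith("descendant"):
            descendants.setdefault(i, set()).add(k)
            if role.endswith("unperturbed"):
                unperturbed.add(i)
            if ptxt:
                pvals[k, i] = float(ptxt)
        else:
            ancestors[i].add(k)
    return SurrogateSets(
        n_genes=p,
        descendants=descendants,
        pvalues=pvals,
        alpha=float(meta.get("alpha", 0.05)),
        correction=meta.get("correction", "bh"),
        ancestors=ancestors,
        unperturbed=unperturbed,
    )


def write_matrix_tsv(
    matrix: np.ndarray,
    row_names: list[str],
    col_names: list[str],
    path: str | Path,
    seed=None,
    config=None,
) -> None:
    frame = pd.DataFrame(matrix, index=row_names, columns=col_names).rename_axis("sample")
    _write_frame(frame, Path(path), seed=seed, config=config)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    frame, _ = _read_tsv(path)
    return frame
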