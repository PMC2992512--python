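"""Expression-variance (EV) statistics.

EV is the sample variance of a gene's normalized log2 expression across
samples — a measure of how strongly a gene's mRNA level is modulated
across conditions. Two pipelines are provided:

* :func:`ev_expo` for tissue-compendium data: quantile normalization of
  samples, per-row median-ratio normalization, log2, then row variance.
* :func:`ev_ck` for treatment/control data: each treatment column is
  divided by its paired control, controls discarded, log2, each column
  standardized to mean 0 / variance 1, then row variance.
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix
from .errors import ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the identical value distribution.

    The target distribution is the per-rank mean of the column-sorted
    values. Ties within a column receive the average of the target values
    at the ranks they occupy, so the transform is deterministic and
    idempotent.
    """
    if matrix.scale != "intensity":
        raise ValidationError("quantile normalization expects intensity scale")
    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("missing values in input to quantile normalization")
    n, p = X.shape
    if p < 2:
        log.warning("quantile_normalize: single column, returned unchanged")
        return ExpressionMatrix(matrix.values.copy(), matrix.samples.copy(),
                                matrix.scale, matrix.probe_to_gene)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(p):
        order = np.argsort(X[:, j], kind="mergesort")
        col = np.empty(n)
        col[order] = ref
        # average the target values over within-column ties
        ser = pd.Series(col)
        out[:, j] = ser.groupby(X[:, j]).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.samples.copy(), "intensity", matrix.probe_to_gene)


def median_log2_rows(
    matrix: ExpressionMatrix, return_dropped: bool = False
) -> ExpressionMatrix | tuple[ExpressionMatrix, list[tuple[str, str]]]:
    """Divide each row by its median and log2-transform.

    Rows whose median is not strictly positive, or which contain
    nonpositive values (log2 undefined), are dropped and reported rather
    than silently kept.

    Returns the log-ratio matrix, plus a ``[(row_id, reason), ...]`` list
    when ``return_dropped`` is true.
    """
    if matrix.scale != "intensity":
        raise ValidationError("median_log2_rows expects intensity scale")
    vals = matrix.values
    med = vals.median(axis=1)
    dropped: list[tuple[str, str]] = []
    keep = []
    for rid in vals.index:
        if med[rid] <= 0:
            dropped.append((rid, f"nonpositive row median ({med[rid]:g})"))
        elif (vals.loc[rid] <= 0).any():
            dropped.append((rid, "nonpositive value in row (log2 undefined)"))
        else:
            keep.append(rid)
    for rid, reason in dropped:
        log.warning("median_log2_rows: dropped row %s: %s", rid, reason)
    kept = vals.loc[keep]
    out = np.log2(kept.div(med.loc[keep], axis=0))
    result = ExpressionMatrix(out, matrix.samples.copy(), "log_ratio", matrix.probe_to_gene)
    if return_dropped:
        return result, dropped
    return result


# ---------------------------------------------------------------------------
# EV pipelines
# ---------------------------------------------------------------------------

def _ev_frame(ev: pd.Series, mean_expr: pd.Series, n_used: int, tag: str) -> pd.DataFrame:
    table = pd.DataFrame({
        "ev": ev,
        "mean_expr": mean_expr.reindex(ev.index),
        "n_samples_used": n_used,
        "dataset_tag": tag,
    })
    table.index.name = "gene"
    return table


def ev_expo(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Tissue-compendium EV: quantile + median-ratio + log2, then row variance.

    ``mean_expr`` is the per-row mean of the quantile-normalized pre-log
    intensities (the scale on which abundance windows are expressed).
    Returns an EV table (index = row id of the input) with columns
    ``ev, mean_expr, n_samples_used, dataset_tag``.
    """
    qn = quantile_normalize(matrix)
    logm = median_log2_rows(qn)
    ev = logm.values.var(axis=1, ddof=1)
    mean_expr = qn.values.loc[logm.values.index].mean(axis=1)
    return _ev_frame(ev, mean_expr, logm.values.shape[1], "expo_style")


def ck_log_ratios(
    matrix: ExpressionMatrix, return_dropped: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Control-relative log2 fold changes, one column per treatment sample.

    Each treatment column is divided elementwise by its declared control
    column and log2-transformed; control columns are discarded. Columns
    identical to their control (zero variance after log2) are dropped and
    reported, since standardization is undefined for them.
    """
    if matrix.samples is None or "control_id" not in matrix.samples.columns:
        raise ValidationError("sample metadata with a control_id column is required")
    vals = matrix.values
    meta = matrix.samples
    cols = {}
    dropped: list[tuple[str, str]] = []
    for sid in vals.columns:
        ctrl = meta.loc[sid, "control_id"]
        if ctrl is None or (isinstance(ctrl, float) and np.isnan(ctrl)) or ctrl == "":
            continue  # a control column itself
        if ctrl not in vals.columns:
            raise ValidationError(f"control column {ctrl!r} of sample {sid!r} not found")
        ratio = vals[sid] / vals[ctrl]
        if (ratio <= 0).any():
            raise ValidationError(f"nonpositive fold change in column {sid!r}")
        lr = np.log2(ratio)
        if lr.var(ddof=1) == 0:
            dropped.append((sid, "zero variance after log2 (identical to control)"))
            log.warning("ck_log_ratios: dropped column %s", sid)
            continue
        cols[sid] = lr
    out = pd.DataFrame(cols, index=vals.index)
    if return_dropped:
        return out, dropped
    return out


def ev_ck(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Treatment-compendium EV on control-relative standardized fold changes.

    After :func:`ck_log_ratios`, every retained column is standardized to
    mean 0 and variance 1 (sample variance); EV is the per-row variance
    of the standardized log fold changes. ``mean_expr`` is the mean raw
    intensity of the row over all original columns, kept as the abundance
    covariate for abundance-control analyses.
    """
    logfc = ck_log_ratios(matrix)
    if logfc.shape[1] == 0:
        raise ValidationError("no treatment columns available after control pairing")
    if logfc.shape[0] < 3:
        raise ValidationError(
            f"CK standardization requires >=3 genes, got {logfc.shape[0]}"
        )
    std = (logfc - logfc.mean(axis=0)) / logfc.std(axis=0, ddof=1)
    ev = std.var(axis=1, ddof=1)
    mean_expr = matrix.values.mean(axis=1)
    return _ev_frame(ev, mean_expr, std.shape[1], "ck_style")


# ---------------------------------------------------------------------------
# probe collapsing and sample subsets
# ---------------------------------------------------------------------------

def collapse_probes(
    ev: pd.DataFrame, probe_to_gene: dict, seed: int = 0
) -> tuple[pd.DataFrame, float]:
    """Collapse a probe-level EV table to gene level by per-gene median.

    Also computes a QC statistic: across genes with >=2 probes, the
    Spearman rank correlation of EV between two randomly chosen probes
    per gene (seeded). High values indicate EV is gene-specific rather
    than probe noise. Returns ``(gene_table, qc_rho)``; the QC is NaN
    when fewer than 3 multi-probe genes exist.
    """
    unmapped = [p for p in ev.index if p not in probe_to_gene]
    if unmapped:
        raise ValidationError(f"probes missing from mapping: {unmapped[:10]}")
    genes = pd.Series({p: probe_to_gene[p] for p in ev.index}, name="gene")
    grouped = ev.groupby(genes)
    out = pd.DataFrame({
        "ev": grouped["ev"].median(),
        "mean_expr": grouped["mean_expr"].median(),
        "n_samples_used": grouped["n_samples_used"].max(),
        "dataset_tag": grouped["dataset_tag"].first(),
    })
    out.index.name = "gene"

    rng = np.random.default_rng(seed)
    a, b = [], []
    for gene, probes in sorted(genes.groupby(genes).groups.items()):
        probes = sorted(probes)
        if len(probes) < 2:
            continue
        i, j = rng.choice(len(probes), size=2, replace=False)
        a.append(ev.loc[probes[i], "ev"])
        b.append(ev.loc[probes[j], "ev"])
    if len(a) >= 3:
        from .stats import spearman

        qc = spearman(np.asarray(a), np.asarray(b)).estimate
    else:
        qc = float("nan")
    return out, qc


def subset_ev(
    matrix: ExpressionMatrix,
    sample_filter: Callable[[pd.Series], bool],
    min_samples: int = 10,
) -> pd.DataFrame:
    """Recompute tissue-compendium EV on a metadata-selected sample subset.

    Quantile normalization is redone within the subset so the subset EV
    is self-contained (tissue-specific EV analyses).
    """
    keep = [sid for sid in matrix.values.columns if sample_filter(matrix.samples.loc[sid])]
    if len(keep) < min_samples:
        raise ValidationError(
            f"sample filter retained {len(keep)} samples; floor is {min_samples}"
        )
    return ev_expo(matrix.subset_samples(keep))
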