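"""Pearson similarity matrices for replicate QC and global correlation structure.

Correlations are computed over pairwise-complete observations: for each pair
of samples (or proteins) only positions observed in both vectors enter the
sum, and pairs with fewer than ``min_overlap`` shared observations — or with
zero variance on the overlap — are reported missing rather than zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, SampleMetadata, ValidationError

DEFAULT_MIN_OVERLAP = 3


@dataclass
class CorrelationMatrix:
    """Symmetric correlation matrix plus per-pair overlap counts."""

    values: pd.DataFrame
    n_overlap: pd.DataFrame

    @property
    def ids(self) -> pd.Index:
        return self.values.index

    def defined_pairs(self) -> pd.DataFrame:
        """Long-format (id_a, id_b, r, n) table of defined upper-triangle pairs."""
        ids = list(self.values.index)
        vals = self.values.to_numpy()
        ns = self.n_overlap.to_numpy()
        rows = []
        n = len(ids)
        iu, ju = np.triu_indices(n, k=1)
        for i, j in zip(iu, ju):
            r = vals[i, j]
            if np.isfinite(r):
                rows.append((ids[i], ids[j], r, int(ns[i, j])))
        return pd.DataFrame(rows, columns=["id_a", "id_b", "r", "n"])


def _pairwise_pearson(columns: pd.DataFrame, min_overlap: int) -> CorrelationMatrix:
    """Pairwise-complete Pearson over the columns of ``columns``."""
    mask = columns.notna()
    overlap = mask.T.astype(int) @ mask.astype(int)
    if columns.isna().any().any():
        corr = columns.corr(method="pearson", min_periods=min_overlap)
    else:
        arr = columns.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(arr, rowvar=False)
        corr = pd.DataFrame(c, index=columns.columns, columns=columns.columns)
    # zero-variance columns (on the overlap) give non-finite r -> missing
    corr = corr.where(np.isfinite(corr))
    corr = corr.where(overlap >= min_overlap)
    np.fill_diagonal(corr.values, np.where(mask.sum(axis=0) > 0, 1.0, np.nan))
    low = (overlap < min_overlap).to_numpy()
    np.fill_diagonal(low, False)
    if low.any():
        warnings.warn(f"{int(low.sum()) // 2} pairs below the minimum overlap of {min_overlap}")
    return CorrelationMatrix(values=corr, n_overlap=overlap)


def sample_correlation(
    matrix: AbundanceMatrix, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> CorrelationMatrix:
    """All-by-all Pearson correlation between samples."""
    if matrix.data.shape[1] < 2:
        raise ValidationError("sample correlation needs at least two samples")
    return _pairwise_pearson(matrix.data, min_overlap)


def protein_correlation(
    matrix: AbundanceMatrix,
    subset: list[str] | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> CorrelationMatrix:
    """All-by-all Pearson correlation between protein time courses.

    Computed across every column of the input (typically replicate-summed
    time points from both batches).  Zero-variance proteins yield missing
    entries with a warning.
    """
    data = matrix.data
    if subset is not None:
        data = data.loc[[p for p in subset if p in data.index]]
    cm = _pairwise_pearson(data.T, min_overlap)
    flat = data.std(axis=1, skipna=True) == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance proteins have undefined correlations")
    return cm


def replicate_qc(
    matrix: AbundanceMatrix,
    metadata: SampleMetadata,
    log_scale: bool = True,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> pd.DataFrame:
    """Per-time-point replicate agreement.

    Returns one row per time point with the replicate Pearson r and the
    number of proteins detected in exactly one replicate.  Because
    intensities are log-normal, agreement is assessed on log2 values when
    the matrix is still on the raw/ppm scale (``log_scale=True``).
    """
    data = matrix.data
    if log_scale and matrix.state in ("raw", "ppm", "replicate_summed"):
        data = np.log2(data.where(data > 0))
    rows = []
    for key in metadata.timepoints():
        reps = [s for s in metadata.replicate_samples(key) if s in data.columns]
        if len(reps) < 2:
            continue
        block = data[reps]
        detected = block.notna()
        discordant = int((detected.sum(axis=1) == 1).sum())
        pair = block.iloc[:, :2].dropna()
        if len(pair) >= min_overlap and pair.iloc[:, 0].std() > 0 and pair.iloc[:, 1].std() > 0:
            r = float(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1])
        else:
            r = float("nan")
        rows.append(
            {
                "batch": key[0],
                "time_point": key[1],
                "pearson_r": r,
                "n_overlap": len(pair),
                "n_single_replicate": discordant,
            }
        )
    return pd.DataFrame(rows)
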