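"""Pairwise differential expression across fermentation time points.

For each pair of time points, proteins observed in both replicates of both
groups are compared with a two-sided Student t-test (pooled variance; Welch
available) on log2-centred abundances.  P-values are adjusted per comparison
with the Benjamini-Hochberg step-up procedure, and a protein is called a
differentially expressed protein (DEP) when ``q < fdr`` *and*
``|log2FC| >= min_log2fc`` (defaults 0.05 and 1).

Missing values are never imputed; proteins failing the replicate rule in
either group are excluded from the comparison, and zero-variance proteins
are flagged rather than assigned an arbitrary p-value.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix, SampleMetadata, ValidationError

DEFAULT_FDR = 0.05
DEFAULT_MIN_LOG2FC = 1.0


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are ignored and returned as NaN; the number of tests m is
    the count of finite p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _group_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row count, mean, and sample variance ignoring NaN."""
    n = np.sum(np.isfinite(values), axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=1)
        var = np.nanvar(values, axis=1, ddof=1)
    return n, mean, var


def ttest_arrays(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised row-wise two-sided t-test.

    Returns ``(t, p, df)`` with NaN where a row has fewer than two finite
    values in either group or zero pooled variance.
    """
    na, ma, va = _group_stats(a)
    nb, mb, vb = _group_stats(b)
    valid = (na >= 2) & (nb >= 2)
    t = np.full(a.shape[0], np.nan)
    p = np.full(a.shape[0], np.nan)
    df = np.full(a.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        if equal_var:
            dof = na + nb - 2.0
            sp2 = ((na - 1) * va + (nb - 1) * vb) / dof
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        else:
            se2a, se2b = va / na, vb / nb
            se = np.sqrt(se2a + se2b)
            dof = (se2a + se2b) ** 2 / (
                se2a**2 / (na - 1) + se2b**2 / (nb - 1)
            )
        good = valid & (se > 0)
        t[good] = (ma[good] - mb[good]) / se[good]
        df[good] = dof[good]
        p[good] = 2.0 * stats.t.sf(np.abs(t[good]), dof[good])
    return t, p, df


def pairwise_ttest(
    matrix: AbundanceMatrix,
    metadata: SampleMetadata,
    group_a: tuple[str, str],
    group_b: tuple[str, str],
    fdr: float = DEFAULT_FDR,
    min_log2fc: float = DEFAULT_MIN_LOG2FC,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Differential expression table for one time-point pair.

    ``group_a``/``group_b`` are (batch, time_point) keys.  Returns a frame
    indexed by protein with columns ``log2fc`` (mean A - mean B), ``t``,
    ``df``, ``p``, ``q``, ``dep`` and ``zero_variance``.
    """
    if matrix.state not in ("log2_centered", "row_mean_normalized"):
        raise ValidationError(
            f"differential testing expects log2-scale input, got state {matrix.state!r}"
        )
    sa = metadata.replicate_samples(group_a)
    sb = metadata.replicate_samples(group_b)
    if not sa or not sb:
        raise ValidationError(f"no samples for {group_a} or {group_b}")
    a = matrix.data[sa].to_numpy()
    b = matrix.data[sb].to_numpy()
    na = np.sum(np.isfinite(a), axis=1)
    nb = np.sum(np.isfinite(b), axis=1)
    tested = (na >= 2) & (nb >= 2)
    t, p, df = ttest_arrays(a, b, equal_var=equal_var)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        log2fc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    log2fc = np.where(tested, log2fc, np.nan)
    zero_var = tested & ~np.isfinite(p)
    q = bh_adjust(p)
    dep = (q < fdr) & (np.abs(log2fc) >= min_log2fc)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "dep": np.where(np.isfinite(q), dep, False),
            "zero_variance": zero_var,
        },
        index=matrix.proteins,
    )
    return out.loc[tested]


def comparison_pairs(
    metadata: SampleMetadata, scheme: str = "all"
) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Time-point pairs under one of three comparison schemes.

    ``all``: all-by-all pairs; ``consecutive``: adjacent time points within
    each batch; ``matched-batches``: the i-th time point of each batch
    against the other batch's i-th (truncated to the shorter batch).
    """
    tps = metadata.timepoints()
    if scheme == "all":
        return list(combinations(tps, 2))
    if scheme == "consecutive":
        pairs = []
        by_batch: dict[str, list[tuple[str, str]]] = {}
        for key in tps:
            by_batch.setdefault(key[0], []).append(key)
        for keys in by_batch.values():
            pairs += list(zip(keys[:-1], keys[1:]))
        return pairs
    if scheme == "matched-batches":
        by_batch = {}
        for key in tps:
            by_batch.setdefault(key[0], []).append(key)
        if len(by_batch) != 2:
            raise ValidationError("matched-batches scheme needs exactly two batches")
        (ka, kb) = by_batch.values()
        return list(zip(ka, kb))
    raise ValidationError(f"unknown comparison scheme {scheme!r}")


def dep_count_matrix(
    matrix: AbundanceMatrix,
    metadata: SampleMetadata,
    fdr: float = DEFAULT_FDR,
    min_log2fc: float = DEFAULT_MIN_LOG2FC,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Symmetric time point x time point matrix of DEP counts (zero diagonal)."""
    tps = metadata.timepoints()
    labels = [metadata.timepoint_label(k) for k in tps]
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for ka, kb in combinations(tps, 2):
        table = pairwise_ttest(matrix, metadata, ka, kb, fdr, min_log2fc, equal_var)
        n = int(table["dep"].sum())
        la, lb = metadata.timepoint_label(ka), metadata.timepoint_label(kb)
        counts.loc[la, lb] = n
        counts.loc[lb, la] = n
    return counts
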