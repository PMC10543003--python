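"""Protein-complex and subcellular-compartment co-regulation analysis.

Given an all-by-all protein correlation matrix over the fermentation time
course, protein pairs are split into *interacting* (co-members of at least
one annotated complex) and *non-interacting* (every other defined pair), and
the two correlation distributions are compared with a one-sided Wilcoxon
rank-sum test (interacting > non-interacting).  Per-compartment correlation
distributions are computed analogously, with multi-localised proteins
contributing to every compartment they map to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError
from .qc import CorrelationMatrix


@dataclass
class ComplexCatalog:
    """Complex id -> member protein set; variants are discrete complexes."""

    complexes: dict[str, set[str]]
    names: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            if len(members) < 2:
                raise ValidationError(f"complex {cid} has fewer than 2 members")

    def member_pairs(self) -> set[tuple[str, str]]:
        pairs: set[tuple[str, str]] = set()
        for members in self.complexes.values():
            mem = sorted(members)
            for i in range(len(mem)):
                for j in range(i + 1, len(mem)):
                    pairs.add((mem[i], mem[j]))
        return pairs


@dataclass
class LocalizationMap:
    """Protein -> set of compartments; multi-membership allowed."""

    locations: dict[str, set[str]]

    def __post_init__(self) -> None:
        empty = [p for p, locs in self.locations.items() if not locs]
        if empty:
            raise ValidationError(f"proteins without compartment: {empty[:5]}")

    def compartments(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for protein, locs in self.locations.items():
            for loc in locs:
                out.setdefault(loc, set()).add(protein)
        return out


@dataclass
class PairCorrelationSummary:
    group: str
    r_values: np.ndarray
    statistic: float | None = None
    p_value: float | None = None

    @property
    def count(self) -> int:
        return int(self.r_values.size)

    @property
    def median(self) -> float:
        return float(np.median(self.r_values)) if self.count else float("nan")

    @property
    def mean(self) -> float:
        return float(np.mean(self.r_values)) if self.count else float("nan")


def complex_coverage(catalog: ComplexCatalog, detected: set[str]) -> tuple[pd.DataFrame, dict]:
    """Fraction of each complex's members present in the detected set.

    The summary reports the share of complexes with at least one detected
    member and the mean within-complex detected fraction.
    """
    rows = []
    for cid, members in catalog.complexes.items():
        hit = len(members & detected)
        rows.append(
            {
                "complex_id": cid,
                "n_members": len(members),
                "n_detected": hit,
                "fraction_detected": hit / len(members),
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "n_complexes": len(table),
        "share_with_any_member": float((table["n_detected"] > 0).mean()) if len(table) else 0.0,
        "mean_fraction_detected": float(table["fraction_detected"].mean()) if len(table) else 0.0,
    }
    return table, summary


def pair_correlation_split(
    corr: CorrelationMatrix, catalog: ComplexCatalog
) -> tuple[PairCorrelationSummary, PairCorrelationSummary]:
    """Split all defined protein pairs into interacting vs non-interacting.

    Pairs with undefined correlation are excluded from both groups.  The
    returned interacting summary carries a one-sided Wilcoxon rank-sum
    statistic and p-value for a location shift toward higher correlation.
    """
    ids = list(corr.values.index)
    pos = {p: i for i, p in enumerate(ids)}
    vals = corr.values.to_numpy()
    n = len(ids)
    inter_mask = np.zeros((n, n), dtype=bool)
    for a, b in catalog.member_pairs():
        if a in pos and b in pos:
            inter_mask[pos[a], pos[b]] = True
            inter_mask[pos[b], pos[a]] = True
    iu = np.triu_indices(n, k=1)
    r = vals[iu]
    is_inter = inter_mask[iu]
    defined = np.isfinite(r)
    inter_r = r[defined & is_inter]
    non_r = r[defined & ~is_inter]
    if inter_r.size == 0:
        raise ValidationError("no defined interacting pairs in the correlation matrix")
    if non_r.size == 0:
        raise ValidationError("no defined non-interacting pairs in the correlation matrix")
    stat, p = stats.mannwhitneyu(inter_r, non_r, alternative="greater")
    interacting = PairCorrelationSummary("interacting", inter_r, float(stat), float(p))
    non_interacting = PairCorrelationSummary("non_interacting", non_r)
    return interacting, non_interacting


def compartment_correlation(
    corr: CorrelationMatrix, locmap: LocalizationMap
) -> dict[str, PairCorrelationSummary]:
    """Within-compartment pair correlation distributions.

    Compartments with fewer than two proteins in the correlation matrix are
    skipped with a warning; multi-localised proteins appear in every
    compartment they are annotated to.
    """
    ids = list(corr.values.index)
    pos = {p: i for i, p in enumerate(ids)}
    vals = corr.values.to_numpy()
    out: dict[str, PairCorrelationSummary] = {}
    for compartment, members in sorted(locmap.compartments().items()):
        present = sorted(m for m in members if m in pos)
        if len(present) < 2:
            warnings.warn(f"compartment {compartment!r} has <2 detected proteins; skipped")
            continue
        idx = np.array([pos[m] for m in present])
        sub = vals[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        r = sub[iu]
        r = r[np.isfinite(r)]
        out[compartment] = PairCorrelationSummary(compartment, r)
    return out


def pair_table(
    corr: CorrelationMatrix, catalog: ComplexCatalog | None = None
) -> pd.DataFrame:
    """Long-format (id_a, id_b, r, n, group) table of defined pairs."""
    table = corr.defined_pairs()
    if catalog is not None:
        inter = catalog.member_pairs()
        table["group"] = [
            "interacting" if (min(a, b), max(a, b)) in inter else "non_interacting"
            for a, b in zip(table["id_a"], table["id_b"])
        ]
    return table
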