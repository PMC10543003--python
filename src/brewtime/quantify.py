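"""Spectral-count quantification and normalisation.

Implements the length-corrected ppm abundance metric: proteins are digested
in silico with trypsin (cleave after K/R, suppressed before P, zero missed
cleavages), peptides are filtered to the 7-40 residue detectability window,
and a per-protein correction factor ``1 / (sum of in-range peptide lengths)``
converts residue-weighted PSM counts into a molar-like protein weight.
Weights are scaled to parts per million so every sample column sums to 10^6.

Also houses the downstream matrix transforms: the two-unique-peptide and
both-replicate detection filters, replicate summing, log2 + median centring,
and row-mean normalisation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    AbundanceMatrix,
    ConfigurationError,
    PeptideCountMatrix,
    PSMMatrix,
    SampleMetadata,
    ValidationError,
)

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

PEPTIDE_MIN_LEN = 7
PEPTIDE_MAX_LEN = 40


@dataclass
class PeptideSet:
    """Ordered tryptic peptides of one protein.

    ``in_range`` flags peptides inside the detectability window; the
    concatenation of ``peptides`` always reconstructs the parent sequence.
    """

    protein_id: str
    peptides: list[str]
    in_range: list[bool]

    def in_range_peptides(self) -> list[str]:
        return [p for p, ok in zip(self.peptides, self.in_range) if ok]

    def in_range_lengths(self) -> list[int]:
        return [len(p) for p in self.in_range_peptides()]


@dataclass(frozen=True)
class CorrectionFactor:
    """Per-protein length correction: 1 / (sum of in-range peptide lengths)."""

    protein_id: str
    detectable_length: int

    @property
    def factor(self) -> float:
        return 1.0 / self.detectable_length


class UndefinedFactorError(ValidationError):
    """No in-range peptide: the correction factor is undefined."""


def digest_protein(
    protein_id: str,
    sequence: str,
    min_len: int = PEPTIDE_MIN_LEN,
    max_len: int = PEPTIDE_MAX_LEN,
) -> PeptideSet:
    """In-silico tryptic digest with zero missed cleavages.

    Cleaves C-terminal to every K or R unless the next residue is proline.
    Peptides are returned N-to-C; the in-range flag marks peptides of
    ``min_len``-``max_len`` residues inclusive.
    """
    if not sequence:
        raise ValidationError(f"{protein_id}: empty sequence")
    for i, aa in enumerate(sequence):
        if aa not in STANDARD_RESIDUES:
            raise ValidationError(
                f"{protein_id}: non-standard residue {aa!r} at position {i + 1}"
            )
    peptides: list[str] = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 >= len(sequence) or sequence[i + 1] != "P"):
            peptides.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        peptides.append(sequence[start:])
    flags = [min_len <= len(p) <= max_len for p in peptides]
    return PeptideSet(protein_id=protein_id, peptides=peptides, in_range=flags)


def peptide_filter(
    peptides: PeptideSet, min_len: int = PEPTIDE_MIN_LEN, max_len: int = PEPTIDE_MAX_LEN
) -> PeptideSet:
    """Subset to peptides with ``min_len <= length <= max_len`` (inclusive)."""
    if min_len > max_len:
        raise ConfigurationError(f"min_len {min_len} exceeds max_len {max_len}")
    kept = [p for p in peptides.peptides if min_len <= len(p) <= max_len]
    return PeptideSet(peptides.protein_id, kept, [True] * len(kept))


def correction_factor(peptides: PeptideSet) -> CorrectionFactor:
    """Length correction from the summed in-range peptide lengths."""
    total = sum(peptides.in_range_lengths())
    if total == 0:
        raise UndefinedFactorError(
            f"{peptides.protein_id}: no peptides in the detectability window"
        )
    return CorrectionFactor(peptides.protein_id, total)


def digest_fasta(
    sequences: dict[str, str],
    min_len: int = PEPTIDE_MIN_LEN,
    max_len: int = PEPTIDE_MAX_LEN,
) -> tuple[dict[str, PeptideSet], dict[str, CorrectionFactor]]:
    """Digest every protein; proteins with no in-range peptide are excluded
    from the factor map with a logged warning (they cannot be quantified)."""
    peptide_sets: dict[str, PeptideSet] = {}
    factors: dict[str, CorrectionFactor] = {}
    skipped = []
    for pid, seq in sequences.items():
        ps = digest_protein(pid, seq, min_len, max_len)
        peptide_sets[pid] = ps
        try:
            factors[pid] = correction_factor(ps)
        except UndefinedFactorError:
            skipped.append(pid)
    if skipped:
        logger.warning(
            "%d proteins had no peptide in the %d-%d window and are excluded from ppm: %s%s",
            len(skipped), min_len, max_len, ", ".join(skipped[:5]),
            "..." if len(skipped) > 5 else "",
        )
    return peptide_sets, factors


def psm_to_ppm(
    counts: PeptideCountMatrix, factors: dict[str, CorrectionFactor]
) -> AbundanceMatrix:
    """Convert peptide-level PSM counts to ppm protein abundances.

    Per sample, each protein's weight is ``sum over its peptides of
    PSMs x peptide length x correction factor``; weights are scaled by 10^6
    and divided by the sample total, so every defined column sums to 10^6.
    A sample with zero total weight yields an all-missing column.
    """
    unassigned = sorted(set(counts.assignments) - set(factors))
    if unassigned:
        raise ValidationError(
            f"counted peptides map to proteins without a correction factor: {unassigned[:5]}"
        )
    weighted = counts.data.mul(counts.lengths, axis=0)
    per_protein = weighted.groupby(counts.assignments).sum()
    fac = pd.Series({p: f.factor for p, f in factors.items()})
    per_protein = per_protein.mul(fac.reindex(per_protein.index), axis=0)
    totals = per_protein.sum(axis=0)
    ppm = per_protein.mul(1e6).div(totals, axis=1)
    empty = totals <= 0
    if empty.any():
        warnings.warn(f"samples with zero total weight flagged missing: {list(totals.index[empty])}")
        ppm.loc[:, empty] = np.nan
    return AbundanceMatrix(data=ppm, state="ppm")


# ---------------------------------------------------------------------------
# Detection filters and normalisations
# ---------------------------------------------------------------------------

def detection_filter(
    matrix: AbundanceMatrix,
    metadata: SampleMetadata,
    unique_peptides: pd.Series | PSMMatrix | None = None,
    min_unique_peptides: int = 2,
    strict_replicates: bool = False,
) -> AbundanceMatrix:
    """Apply the detection filters used before differential testing.

    Drops proteins identified by fewer than ``min_unique_peptides`` distinct
    peptides, then masks any value not detected in *both* replicates of its
    time point — single-replicate detections are unreliable for testing.
    Proteins left with no value at all are removed.
    """
    missing_cols = set(matrix.samples) - set(metadata.samples)
    if missing_cols:
        raise ValidationError(f"metadata does not cover samples: {sorted(missing_cols)}")
    data = matrix.data.copy()
    if isinstance(unique_peptides, PSMMatrix):
        unique_peptides = unique_peptides.unique_peptides
    if unique_peptides is not None:
        uniq = unique_peptides.reindex(data.index).fillna(0)
        dropped = int((uniq < min_unique_peptides).sum())
        if dropped:
            logger.info("detection_filter: dropped %d proteins with <%d unique peptides",
                        dropped, min_unique_peptides)
        data = data.loc[uniq >= min_unique_peptides]
    for key in metadata.timepoints():
        reps = [s for s in metadata.replicate_samples(key) if s in data.columns]
        if len(reps) != 2:
            msg = f"time point {key} has {len(reps)} replicates (expected 2)"
            if strict_replicates:
                raise ValidationError(msg)
            warnings.warn(msg + "; both-replicate rule skipped for it")
            continue
        block = data[reps]
        incomplete = block.isna().any(axis=1)
        data.loc[incomplete, reps] = np.nan
    data = data.dropna(how="all")
    return AbundanceMatrix(data=data, state=matrix.state)


def sum_replicates(matrix: AbundanceMatrix, metadata: SampleMetadata) -> AbundanceMatrix:
    """Sum replicate intensities into one column per time point.

    A value observed in only one replicate stands alone (summing is done to
    maximise the number of proteins retained); a value is missing only when
    missing in every replicate.
    """
    cols = {}
    for key in metadata.timepoints():
        reps = [s for s in metadata.replicate_samples(key) if s in matrix.data.columns]
        block = matrix.data[reps]
        summed = block.sum(axis=1, min_count=1)
        cols[metadata.timepoint_label(key)] = summed
    return AbundanceMatrix(data=pd.DataFrame(cols), state="replicate_summed")


def log2_median_center(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2-transform and centre each column on its median.

    Intensities are log-normal, so the log2 values are approximately normal;
    subtracting each sample's median equalises location across samples.
    Zeros are treated as missing; negative values are invalid.
    """
    data = matrix.data
    if (data < 0).any().any():
        raise ValidationError("negative abundance encountered; log2 undefined")
    data = data.where(data > 0)  # zeros -> missing
    logged = np.log2(data)
    centered = logged.sub(logged.median(axis=0, skipna=True), axis=1)
    return AbundanceMatrix(data=centered, state="log2_centered")


def row_mean_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Express each value as log2(value / row mean over non-missing entries).

    All-missing rows are dropped with a warning.  Input is expected on the
    raw intensity scale (e.g. replicate-summed).
    """
    data = matrix.data
    all_missing = data.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} all-missing rows")
        data = data.loc[~all_missing]
    if (data < 0).any().any():
        raise ValidationError("negative abundance encountered")
    data = data.where(data > 0)
    means = data.mean(axis=1, skipna=True)
    ratios = np.log2(data.div(means, axis=0))
    return AbundanceMatrix(data=ratios, state="row_mean_normalized")
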