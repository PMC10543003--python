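"""Core in-memory containers shared by every pipeline stage.

All matrices are thin wrappers around :class:`pandas.DataFrame` with proteins
as rows and samples (or time points) as columns.  Missing values are ``NaN``,
never zero: a zero spectral count is informative, an undetected protein is
not.  Each :class:`AbundanceMatrix` carries a *state* tag recording how far
through the normalisation chain it has travelled, so downstream stages can
refuse inputs at the wrong processing stage instead of silently producing
nonsense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed processing states, in pipeline order.
ABUNDANCE_STATES = (
    "raw",
    "ppm",
    "replicate_summed",
    "log2_centered",
    "row_mean_normalized",
)

PHASES = ("fermentation", "post_crash", "conditioning")


class ValidationError(ValueError):
    """Raised when an input value violates a documented precondition."""


class ConfigurationError(ValueError):
    """Raised when configuration fields are inconsistent or out of range."""


@dataclass
class AbundanceMatrix:
    """Protein x sample abundance matrix with a processing-state tag.

    Parameters
    ----------
    data
        Non-negative abundances (any scale for ``raw``/``ppm``; log2 scale
        for ``log2_centered`` and ``row_mean_normalized``).  ``NaN`` marks a
        missing (undetected) value.
    state
        One of :data:`ABUNDANCE_STATES`.
    """

    data: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in ABUNDANCE_STATES:
            raise ConfigurationError(
                f"unknown abundance state {self.state!r}; expected one of {ABUNDANCE_STATES}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein ids: {dups}")
        self.data = self.data.astype(float)

    @property
    def proteins(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def with_state(self, data: pd.DataFrame, state: str) -> "AbundanceMatrix":
        return AbundanceMatrix(data=data, state=state)

    def n_measurements(self) -> int:
        """Number of non-missing protein abundance measurements."""
        return int(self.data.notna().sum().sum())


@dataclass
class PSMMatrix:
    """Protein x sample matrix of peptide-spectrum-match counts.

    ``unique_peptides`` records, per protein, how many distinct peptides
    contributed at least one PSM anywhere in the experiment; the detection
    filter requires two or more.
    """

    data: pd.DataFrame
    unique_peptides: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValidationError("PSM counts must be non-negative integers")
        self.data = self.data.astype(np.int64)
        if self.unique_peptides is not None:
            self.unique_peptides = self.unique_peptides.reindex(self.data.index)


@dataclass
class PeptideCountMatrix:
    """Peptide-level PSM counts with peptide -> protein assignments.

    Rows are peptide ids; ``assignments`` maps each peptide id to its parent
    protein, ``lengths`` to its length in residues.  This is the native input
    of the length-corrected ppm computation.
    """

    data: pd.DataFrame
    assignments: pd.Series  # peptide id -> protein id
    lengths: pd.Series  # peptide id -> residue count

    def __post_init__(self) -> None:
        missing = self.data.index.difference(self.assignments.index)
        if len(missing):
            raise ValidationError(f"peptides without protein assignment: {list(missing)[:5]}")
        self.assignments = self.assignments.reindex(self.data.index)
        self.lengths = self.lengths.reindex(self.data.index)

    def to_protein_counts(self) -> PSMMatrix:
        """Aggregate to a protein-level PSM matrix with unique-peptide counts."""
        protein_counts = self.data.groupby(self.assignments).sum()
        detected = self.data.sum(axis=1) > 0
        uniq = detected.groupby(self.assignments).sum().astype(int)
        return PSMMatrix(data=protein_counts, unique_peptides=uniq.reindex(protein_counts.index))


@dataclass
class SampleMetadata:
    """Per-sample design information: batch, time point, phase, replicate.

    The table is indexed by sample id and must cover every column of the
    matrices it is used with.  A *time point* is identified by the pair
    ``(batch, time_point)`` — the same nominal hour in two batches is two
    distinct time points.
    """

    table: pd.DataFrame

    REQUIRED = ("batch", "time_point", "phase", "replicate")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ConfigurationError(f"sample metadata missing column {col!r}")
        bad = set(self.table["phase"]) - set(PHASES)
        if bad:
            raise ConfigurationError(f"unknown phases {sorted(bad)}; expected {PHASES}")

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    def timepoints(self) -> list[tuple[str, str]]:
        """Ordered unique (batch, time_point) pairs, in table order."""
        seen: dict[tuple[str, str], None] = {}
        for _, row in self.table.iterrows():
            seen.setdefault((row["batch"], row["time_point"]), None)
        return list(seen)

    def timepoint_label(self, key: tuple[str, str]) -> str:
        return f"{key[0]}:{key[1]}"

    def replicate_samples(self, key: tuple[str, str]) -> list[str]:
        batch, tp = key
        mask = (self.table["batch"] == batch) & (self.table["time_point"] == tp)
        return list(self.table.index[mask])

    def subset(self, samples: list[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[samples])


@dataclass
class GroundTruth:
    """Planted signal of a simulated fermentation time course.

    ``planted_log2`` holds the noise-free log2 abundance of every protein at
    every time point (baseline + trajectory + batch shift + complex factor);
    all ground-truth queries derive from it.
    """

    trajectory_class: dict[str, str]  # protein -> archetype name
    batch_shifted: dict[str, float]  # protein -> log2 offset (shifted batch)
    complexes: dict[str, list[str]]  # complex id -> member proteins
    planted_log2: pd.DataFrame  # proteins x time-point labels

    def true_deps(self, label_a: str, label_b: str, min_log2fc: float = 1.0) -> set[str]:
        """Proteins whose planted log2 difference between two time points
        is at least ``min_log2fc`` in absolute value."""
        diff = (self.planted_log2[label_a] - self.planted_log2[label_b]).abs()
        return set(diff.index[diff >= min_log2fc])

    def class_labels(self, proteins: list[str] | None = None) -> pd.Series:
        prots = proteins if proteins is not None else list(self.planted_log2.index)
        return pd.Series({p: self.trajectory_class.get(p, "background") for p in prots})
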