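"""Synthetic fermentation proteome generator with known ground truth.

Emulates the design of a commercial ale fermentation proteomics study: two
production batches separated by serial repitching, sampled at 17 time points
(7 in the first batch; 7 fermentation + 3 conditioning-tank points in the
repitched batch), two independent replicates per time point, and on the
order of 2,600 detected proteins.  Abundances are log-normal: every value is
``2**(baseline + trajectory effect + batch shift + complex factor +
replicate noise)``, so all planted effects are additive in log2 space.

The generator plants three kinds of structure, each recorded in a
:class:`~brewtime.containers.GroundTruth`:

* **trajectory classes** — archetypal time-course shapes (early peak, late
  rise, flat-then-drop, monotone decline) scaled by an effect size in log2
  units, shared across batches;
* **batch shifts** — a constant log2 offset applied to a protein set in one
  batch only, mimicking repitching-associated abundance changes;
* **complexes** — groups of proteins sharing a latent time-course factor
  with tunable loading, giving co-regulated modules of known strength.

Dropout marks a detected protein as *missing* (NaN, never zero) in exactly
one replicate of a time point, matching the single-replicate detections seen
in real runs.  By default dropout is abundance-independent (MCAR); an
abundance-weighted mode (MNAR) is available since low-abundance proteins
plausibly drop out more often.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    AbundanceMatrix,
    ConfigurationError,
    GroundTruth,
    PeptideCountMatrix,
    SampleMetadata,
)

# ---------------------------------------------------------------------------
# Trajectory archetypes: functions of normalised batch time u in [0, 1].
# Values are in [0, 1]; the planted effect is effect_size * shape(u).
# ---------------------------------------------------------------------------

ARCHETYPES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "early_peak": lambda u: np.exp(-(((u - 0.15) / 0.10) ** 2)),
    "late_rise": lambda u: 1.0 / (1.0 + np.exp(-(u - 0.75) * 18.0)),
    "flat_then_drop": lambda u: 1.0 - 1.0 / (1.0 + np.exp(-(u - 0.8) * 20.0)),
    "monotone_down": lambda u: np.exp(-np.asarray(u, dtype=float) / 0.18),
    "monotone_up": lambda u: np.asarray(u, dtype=float),
    "flat": lambda u: np.zeros_like(np.asarray(u, dtype=float)),
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class TrajectoryClass:
    shape: str
    n_members: int
    effect_size: float  # log2 units


@dataclass(frozen=True)
class BatchShift:
    batch: str
    n_members: int
    offset: float  # log2 units, applied in `batch` only


@dataclass(frozen=True)
class ComplexPlan:
    size: int
    loading: float  # share of the latent factor each member carries, in [0, 1]


def default_time_points() -> list[tuple[str, str, str]]:
    """(batch, time-point label, phase) triples of the emulated design.

    Batch B1: six fermentation samplings plus one 24 h post-crash point.
    Batch B15 (after 14 repitches): seven fermentation/post-crash points and
    three conditioning-tank samplings.  17 time points, 34 samples at two
    replicates each.
    """
    b1 = [("B1", t, "fermentation") for t in ("0h", "6h", "24h", "48h", "72h", "96h")]
    b1.append(("B1", "24PC", "post_crash"))
    b15 = [("B15", t, "fermentation") for t in ("3h", "24h", "48h", "72h", "96h", "120h")]
    b15.append(("B15", "24PC", "post_crash"))
    b15 += [("B15", t, "conditioning") for t in ("C24", "C48", "C72")]
    return b1 + b15


@dataclass
class SimulationConfig:
    """Study-design parameters of the simulated fermentation time course.

    Defaults reproduce the emulated study's regime: 2 batches x 17 time
    points x 2 replicates (34 samples), 2,600 proteins, log-normal
    intensities whose within-time-point replicate Pearson r falls in the
    0.84-0.94 band, and ~14% per-time-point single-replicate dropout.
    """

    n_proteins: int = 2600
    time_points: list[tuple[str, str, str]] = field(default_factory=default_time_points)
    n_replicates: int = 2
    base_log_abundance: tuple[float, float] = (20.0, 2.0)  # mean, sd of log2 baseline
    replicate_noise_sd: float = 0.72  # log2 units; calibrated to the 0.84-0.94 r band
    dropout_rate: float = 0.14
    dropout_mode: str = "mcar"  # or "mnar" (abundance-weighted)
    trajectory_classes: list[TrajectoryClass] = field(
        default_factory=lambda: [
            TrajectoryClass("early_peak", 150, 2.0),
            TrajectoryClass("late_rise", 150, 2.0),
            TrajectoryClass("flat_then_drop", 150, 2.0),
            TrajectoryClass("monotone_down", 150, 2.0),
        ]
    )
    batch_shifts: list[BatchShift] = field(
        default_factory=lambda: [BatchShift("B15", 50, 1.5)]
    )
    complex_plan: list[ComplexPlan] = field(
        default_factory=lambda: [ComplexPlan(5, 0.9)] * 20
    )
    complex_amplitude: float = 1.5  # log2 sd of the shared latent factor
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise ConfigurationError("n_proteins must be positive")
        if self.n_replicates <= 0:
            raise ConfigurationError("n_replicates must be positive")
        if not self.time_points:
            raise ConfigurationError("time_points must be non-empty")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.replicate_noise_sd < 0:
            raise ConfigurationError("replicate_noise_sd must be >= 0")
        if self.dropout_mode not in ("mcar", "mnar"):
            raise ConfigurationError("dropout_mode must be 'mcar' or 'mnar'")
        for tc in self.trajectory_classes:
            if tc.shape not in ARCHETYPES:
                raise ConfigurationError(
                    f"trajectory_classes: unknown archetype {tc.shape!r}"
                )
            if tc.n_members < 0:
                raise ConfigurationError("trajectory_classes: n_members must be >= 0")
        planted = sum(tc.n_members for tc in self.trajectory_classes)
        planted += sum(bs.n_members for bs in self.batch_shifts)
        planted += sum(cp.size for cp in self.complex_plan)
        if planted > self.n_proteins:
            raise ConfigurationError(
                f"planted protein count {planted} exceeds n_proteins {self.n_proteins}"
            )
        for cp in self.complex_plan:
            if not (0.0 <= cp.loading <= 1.0):
                raise ConfigurationError("complex_plan: loading must lie in [0, 1]")
            if cp.size < 2:
                raise ConfigurationError("complex_plan: complex size must be >= 2")


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{str(i).zfill(width)}" for i in range(n)]


def _normalised_batch_time(time_points: list[tuple[str, str, str]]) -> np.ndarray:
    """Position of each time point within its batch, scaled to [0, 1]."""
    batches: dict[str, list[int]] = {}
    for i, (batch, _, _) in enumerate(time_points):
        batches.setdefault(batch, []).append(i)
    u = np.zeros(len(time_points))
    for idxs in batches.values():
        denom = max(len(idxs) - 1, 1)
        for pos, i in enumerate(idxs):
            u[i] = pos / denom
    return u


def simulate_timecourse(
    config: SimulationConfig,
) -> tuple[AbundanceMatrix, SampleMetadata, GroundTruth]:
    """Simulate a replicated fermentation time course.

    Returns the raw (exp-scale, log-normal) abundance matrix with dropout
    applied, the sample metadata, and the planted ground truth.  Identical
    config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    proteins = _protein_ids(config.n_proteins)
    tps = config.time_points
    n_tp = len(tps)
    tp_labels = [f"{b}:{t}" for b, t, _ in tps]
    u = _normalised_batch_time(tps)

    # --- assign planted roles to disjoint protein blocks -------------------
    cursor = 0
    trajectory_class: dict[str, str] = {}
    class_effect = np.zeros((config.n_proteins, n_tp))
    for k, tc in enumerate(config.trajectory_classes):
        members = proteins[cursor : cursor + tc.n_members]
        cursor += tc.n_members
        shape_vals = ARCHETYPES[tc.shape](u)
        for p in members:
            trajectory_class[p] = f"{tc.shape}"
        rows = [proteins.index(p) for p in members]
        class_effect[rows, :] = tc.effect_size * shape_vals

    batch_shifted: dict[str, float] = {}
    shift_effect = np.zeros((config.n_proteins, n_tp))
    for bs in config.batch_shifts:
        members = proteins[cursor : cursor + bs.n_members]
        cursor += bs.n_members
        cols = [j for j, (b, _, _) in enumerate(tps) if b == bs.batch]
        for p in members:
            batch_shifted[p] = bs.offset
            shift_effect[proteins.index(p), cols] = bs.offset

    complexes: dict[str, list[str]] = {}
    complex_effect = np.zeros((config.n_proteins, n_tp))
    for k, cp in enumerate(config.complex_plan):
        members = proteins[cursor : cursor + cp.size]
        cursor += cp.size
        complexes[f"CPX{k + 1:03d}"] = members
        latent = rng.standard_normal(n_tp)
        for p in members:
            own = rng.standard_normal(n_tp)
            mix = cp.loading * latent + math.sqrt(1.0 - cp.loading**2) * own
            complex_effect[proteins.index(p), :] = config.complex_amplitude * mix

    # --- planted (noise-free) log2 abundance per time point ----------------
    mu, sd = config.base_log_abundance
    baseline = rng.normal(mu, sd, size=config.n_proteins)
    planted = baseline[:, None] + class_effect + shift_effect + complex_effect
    planted_df = pd.DataFrame(planted, index=proteins, columns=tp_labels)

    # --- replicate measurements in log2 space ------------------------------
    sample_ids: list[str] = []
    meta_rows = []
    cols = []
    for j, (batch, tp, phase) in enumerate(tps):
        for r in range(1, config.n_replicates + 1):
            sid = f"{batch}_{tp}_R{r}"
            sample_ids.append(sid)
            meta_rows.append(
                {"batch": batch, "time_point": tp, "phase": phase, "replicate": f"R{r}"}
            )
            noise = rng.normal(0.0, config.replicate_noise_sd, size=config.n_proteins)
            cols.append(planted[:, j] + noise)
    log2_values = np.column_stack(cols)

    # --- dropout: missing in exactly one replicate of a time point ---------
    values = np.exp2(log2_values)
    if config.dropout_rate > 0 and config.n_replicates >= 2:
        if config.dropout_mode == "mnar":
            # low-baseline proteins drop out more often; mean rate preserved
            ranks = pd.Series(baseline).rank(pct=True).to_numpy()
            prot_rate = np.clip(2.0 * config.dropout_rate * (1.0 - ranks), 0.0, 0.999)
        else:
            prot_rate = np.full(config.n_proteins, config.dropout_rate)
        for j in range(n_tp):
            hit = rng.random(config.n_proteins) < prot_rate
            which = rng.integers(0, config.n_replicates, size=config.n_proteins)
            for i in np.nonzero(hit)[0]:
                values[i, j * config.n_replicates + which[i]] = np.nan

    matrix = AbundanceMatrix(
        data=pd.DataFrame(values, index=proteins, columns=sample_ids), state="raw"
    )
    metadata = SampleMetadata(pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample")))
    truth = GroundTruth(
        trajectory_class=trajectory_class,
        batch_shifted=batch_shifted,
        complexes=complexes,
        planted_log2=planted_df,
    )
    return matrix, metadata, truth


# ---------------------------------------------------------------------------
# Protein sequences and PSM counts
# ---------------------------------------------------------------------------

def simulate_protein_fasta(
    n_proteins: int,
    rng: np.random.Generator | int = 0,
    length_range: tuple[int, int] = (250, 550),
    kr_freq: float = 0.1,
) -> dict[str, str]:
    """Random protein sequences with controllable tryptic site density.

    ``kr_freq`` is the combined frequency of lysine and arginine; at the
    default 1/10 the geometric spacing of cleavage sites gives a mean tryptic
    peptide length of roughly ten residues, so a healthy fraction of digests
    lands in the 7-40 residue detectability window.  ``kr_freq=0`` yields
    proteins that digest to a single peptide.
    """
    if n_proteins <= 0:
        raise ConfigurationError("n_proteins must be positive")
    if not (0.0 <= kr_freq < 1.0):
        raise ConfigurationError("kr_freq must lie in [0, 1)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    others = [a for a in AMINO_ACIDS if a not in "KR"]
    probs = np.empty(len(AMINO_ACIDS))
    alphabet = list(AMINO_ACIDS)
    for i, a in enumerate(alphabet):
        probs[i] = kr_freq / 2.0 if a in "KR" else (1.0 - kr_freq) / len(others)
    sequences: dict[str, str] = {}
    for pid in _protein_ids(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=probs))
        sequences[pid] = seq
    return sequences


def simulate_psm_counts(
    truth_abundance: AbundanceMatrix,
    peptides: Mapping[str, Sequence[int]],
    depth: int,
    rng: np.random.Generator | int = 0,
) -> PeptideCountMatrix:
    """Draw peptide-level PSM counts from planted abundances.

    For every sample, ``depth`` PSMs are allocated multinomially over all
    detectable (in-range) peptides with probability proportional to
    ``abundance(protein) * peptide length`` — longer peptides and more
    abundant proteins attract more spectra.  Summed to the protein level the
    selection probability is proportional to abundance times detectable
    length, and every column sums exactly to ``depth``.

    Parameters
    ----------
    peptides
        Mapping protein id -> lengths of its detectable peptides.
    """
    if depth <= 0:
        raise ConfigurationError("depth must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    pep_ids: list[str] = []
    pep_protein: list[str] = []
    pep_len: list[int] = []
    for pid in truth_abundance.proteins:
        lens = list(peptides.get(pid, []))
        total = sum(lens)
        if total == 0:
            if truth_abundance.data.loc[pid].fillna(0).sum() > 0:
                warnings.warn(
                    f"protein {pid} has no detectable peptides; excluded from PSM sampling"
                )
            continue
        for i, L in enumerate(lens):
            pep_ids.append(f"{pid}|p{i}")
            pep_protein.append(pid)
            pep_len.append(int(L))

    lengths = np.asarray(pep_len, dtype=float)
    abund = truth_abundance.data.reindex(pep_protein).to_numpy()
    abund = np.nan_to_num(abund, nan=0.0)
    counts = np.zeros((len(pep_ids), truth_abundance.data.shape[1]), dtype=np.int64)
    for j in range(truth_abundance.data.shape[1]):
        w = abund[:, j] * lengths
        total = w.sum()
        if total <= 0:
            continue
        counts[:, j] = rng.multinomial(depth, w / total)
    idx = pd.Index(pep_ids, name="peptide")
    return PeptideCountMatrix(
        data=pd.DataFrame(counts, index=idx, columns=truth_abundance.samples),
        assignments=pd.Series(pep_protein, index=idx),
        lengths=pd.Series(pep_len, index=idx),
    )


def simulate_two_group_dataset(
    n_proteins: int,
    frac_effect: float,
    effect: float,
    sd: float,
    n_per_group: int,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimal two-condition dataset for error-rate studies.

    Returns ``(group_a, group_b, is_effect)`` where the first
    ``round(frac_effect * n_proteins)`` proteins carry a mean log2 shift of
    ``effect`` (random sign) and everything else is null; both groups have
    i.i.d. Gaussian noise with standard deviation ``sd``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_eff = int(round(frac_effect * n_proteins))
    is_effect = np.zeros(n_proteins, dtype=bool)
    is_effect[:n_eff] = True
    signs = rng.choice([-1.0, 1.0], size=n_proteins)
    delta = np.where(is_effect, signs * effect, 0.0)
    a = rng.normal(0.0, sd, size=(n_proteins, n_per_group))
    b = delta[:, None] + rng.normal(0.0, sd, size=(n_proteins, n_per_group))
    return a, b, is_effect
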