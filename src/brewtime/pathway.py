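"""Pathway perturbation scoring (DRPS/DPPS) and entity-removal re-ranking.

A pathway model maps pathways to reactions and each reaction to the set of
measurable entities (proteins/enzymes) that catalyse it.  Scores are
computed on row-mean-normalised log2 abundances:

* **DRPS** (differential reaction perturbation score): for each entity, the
  span ``max - min`` of its values across samples (equivalently the maximum
  absolute pairwise difference); a reaction's DRPS is the largest span over
  its measured entities, 0 when none is measured.
* **DPPS** (differential pathway perturbation score): the root mean square
  of reaction DRPS over *all* reactions of the pathway — unmeasured
  reactions contribute 0 to the sum but stay in the denominator, so sparsely
  covered pathways are not inflated.  ``DPPS = sqrt(sum(DRPS^2) / n_reactions)``.

``leave_out_rerank`` recomputes the ranking with a set of entities masked,
exposing pathways whose score is carried by a few driver enzymes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, ValidationError


@dataclass
class Pathway:
    pathway_id: str
    name: str
    reactions: dict[str, set[str]]  # reaction id -> entity ids

    def __post_init__(self) -> None:
        if not self.reactions:
            raise ValidationError(f"pathway {self.pathway_id} has no reactions")

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def entities(self) -> set[str]:
        out: set[str] = set()
        for ents in self.reactions.values():
            out |= ents
        return out


@dataclass
class PathwayModel:
    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.pathways.values())

    def __len__(self) -> int:
        return len(self.pathways)


def entity_span(values: np.ndarray) -> float:
    """Span (max - min) of one entity's values across samples, NaN-aware.

    Equals the maximum of |difference| over all sample pairs; 0 when fewer
    than two values are observed.
    """
    finite = values[np.isfinite(values)]
    if finite.size < 2:
        return 0.0
    return float(finite.max() - finite.min())


def reaction_drps(
    entities: set[str], matrix: AbundanceMatrix, exclude: set[str] | None = None
) -> float:
    """DRPS: maximum entity span over the reaction's measured entities."""
    exclude = exclude or set()
    best = 0.0
    for ent in entities:
        if ent in exclude or ent not in matrix.data.index:
            continue
        span = entity_span(matrix.data.loc[ent].to_numpy(dtype=float))
        best = max(best, span)
    return best


def pathway_dpps(
    pathway: Pathway, matrix: AbundanceMatrix, exclude: set[str] | None = None
) -> tuple[float, float]:
    """DPPS and measured-entity coverage for one pathway.

    Coverage is the fraction of the pathway's entities present in the
    matrix (after exclusions); the DPPS denominator is the model's total
    reaction count, measured or not.
    """
    exclude = exclude or set()
    sq_sum = 0.0
    for entities in pathway.reactions.values():
        drps = reaction_drps(entities, matrix, exclude)
        sq_sum += drps * drps
    ents = pathway.entities
    measured = {e for e in ents if e in matrix.data.index and e not in exclude}
    coverage = len(measured) / len(ents) if ents else 0.0
    return float(np.sqrt(sq_sum / pathway.n_reactions)), coverage


def rank_pathways(
    model: PathwayModel,
    matrix: AbundanceMatrix,
    top_n: int | None = None,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Pathways ranked by DPPS (descending; ties alphabetical by id)."""
    rows = []
    for pw in model:
        dpps, coverage = pathway_dpps(pw, matrix, exclude)
        rows.append(
            {"pathway_id": pw.pathway_id, "name": pw.name, "dpps": dpps, "coverage": coverage}
        )
    table = pd.DataFrame(rows, columns=["pathway_id", "name", "dpps", "coverage"])
    table = table.sort_values(
        ["dpps", "pathway_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    if top_n is not None:
        table = table.head(top_n)
    return table


def leave_out_rerank(
    model: PathwayModel, matrix: AbundanceMatrix, removed_entities: set[str]
) -> pd.DataFrame:
    """Re-rank pathways with a set of entities masked from the matrix.

    Returns one row per pathway with the DPPS and rank before and after
    removal and the rank shift (positive = pathway fell in the ranking).
    """
    missing = {e for e in removed_entities if e not in matrix.data.index}
    if removed_entities and missing == set(removed_entities):
        raise ValidationError(f"removed entities not present in matrix: {sorted(missing)}")
    before = rank_pathways(model, matrix).set_index("pathway_id")
    after = rank_pathways(model, matrix, exclude=set(removed_entities)).set_index("pathway_id")
    out = pd.DataFrame(
        {
            "name": before["name"],
            "dpps_before": before["dpps"],
            "rank_before": before["rank"],
            "dpps_after": after["dpps"],
            "rank_after": after["rank"],
        }
    )
    out["rank_shift"] = out["rank_after"] - out["rank_before"]
    return out.sort_values("rank_before").reset_index()
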