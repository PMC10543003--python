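"""Readers and writers for the pipeline's plain-text formats.

Matrices travel as TSV with a protein-id first column and sample-id header;
the processing state is recorded in a sidecar JSON (``<name>.meta.json``) so
a written matrix round-trips with its tag.  Protein sequences use FASTA,
term/complex sets GMT or two-column TSV, pathway models JSON, and the
dendrogram exports to Newick for inspection.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cluster import DendrogramModel
from .containers import AbundanceMatrix, PSMMatrix, SampleMetadata, ValidationError
from .coregulation import ComplexCatalog, LocalizationMap
from .pathway import Pathway, PathwayModel

logger = logging.getLogger(__name__)

CONTAMINANT_PREFIXES = ("CON__", "REV__")


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def _check_numeric(table: pd.DataFrame, path: Path) -> pd.DataFrame:
    out = {}
    for col in table.columns:
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna() & table[col].notna() & (table[col].astype(str).str.strip() != "")
        bad &= ~table[col].astype(str).str.lower().isin(["nan"])
        if bad.any():
            row = table.index[bad][0]
            raise ValidationError(
                f"{path}: non-numeric value {table.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        out[col] = converted
    return pd.DataFrame(out, index=table.index)


def read_intensity_table(path: str | Path, dialect: str = "generic") -> AbundanceMatrix:
    """Read a protein x sample intensity matrix.

    ``dialect='generic'`` expects protein ids in the first column and sample
    ids in the header; ``dialect='maxquant'`` parses a proteinGroups-style
    export (``Majority protein IDs`` + ``LFQ intensity <sample>`` columns).
    Contaminant/decoy rows (ids prefixed CON__/REV__) are dropped with a
    logged count; duplicate ids and non-numeric cells are errors.
    """
    path = Path(path)
    if dialect == "maxquant":
        return _read_proteingroups(path)
    if dialect != "generic":
        raise ValidationError(f"unknown dialect {dialect!r}")
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup = table.index[table.index.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate protein ids: {dup}")
    contaminant = table.index.str.startswith(CONTAMINANT_PREFIXES)
    if contaminant.any():
        logger.info("%s: dropped %d contaminant/decoy rows", path, int(contaminant.sum()))
        table = table.loc[~contaminant]
    data = _check_numeric(table, path)
    state = "raw"
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        state = json.loads(sidecar.read_text()).get("state", "raw")
    return AbundanceMatrix(data=data, state=state)


def _read_proteingroups(path: Path) -> AbundanceMatrix:
    """Tolerant MaxQuant proteinGroups parser: keeps LFQ intensity columns."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    id_col = next(
        (c for c in ("Majority protein IDs", "Protein IDs") if c in table.columns), None
    )
    if id_col is None:
        raise ValidationError(f"{path}: no protein id column found")
    lfq_cols = [c for c in table.columns if c.startswith("LFQ intensity ")]
    if not lfq_cols:
        raise ValidationError(f"{path}: no 'LFQ intensity <sample>' columns found")
    ids = table[id_col].str.split(";").str[0]
    # flag rows marked as contaminant/reverse either by column or id prefix
    drop = ids.str.startswith(CONTAMINANT_PREFIXES)
    for flag_col in ("Potential contaminant", "Reverse", "Only identified by site"):
        if flag_col in table.columns:
            drop |= table[flag_col].fillna("") == "+"
    if drop.any():
        logger.info("%s: dropped %d contaminant/decoy rows", path, int(drop.sum()))
    table = table.loc[~drop]
    ids = ids.loc[~drop]
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"{path}: duplicate protein ids: {dup}")
    data = table[lfq_cols].copy()
    data.index = ids
    data.columns = [c[len("LFQ intensity ") :] for c in lfq_cols]
    data = _check_numeric(data, path)
    data = data.where(data > 0)  # MaxQuant writes 0 for undetected
    out = AbundanceMatrix(data=data, state="raw")
    if "Unique peptides" in table.columns:
        uniq = pd.to_numeric(table["Unique peptides"], errors="coerce")
        uniq.index = ids
        out.unique_peptides = uniq  # type: ignore[attr-defined]
    return out


def write_intensity_table(matrix: AbundanceMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.data.to_csv(path, sep="\t", index_label="protein_id", na_rep="NaN")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({"state": matrix.state}, indent=2) + "\n")


def read_metadata(path: str | Path) -> SampleMetadata:
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return SampleMetadata(table)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    metadata.table.to_csv(path, sep="\t", index_label="sample")


def read_psm_table(path: str | Path) -> PSMMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0)
    uniq = None
    if "unique_peptides" in table.columns:
        uniq = table.pop("unique_peptides")
    return PSMMatrix(data=table, unique_peptides=uniq)


def write_psm_table(psm: PSMMatrix, path: str | Path) -> None:
    table = psm.data.copy()
    if psm.unique_peptides is not None:
        table["unique_peptides"] = psm.unique_peptides
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index_label="protein_id")


# ---------------------------------------------------------------------------
# Sequences and annotation catalogs
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: term <tab> description <tab> member1 <tab> member2 ..."""
    out: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"{path}: GMT line with <3 fields: {line[:60]!r}")
        out[fields[0]] = set(filter(None, fields[2:]))
    return out


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for term in sorted(sets):
            members = "\t".join(sorted(sets[term]))
            fh.write(f"{term}\t{description}\t{members}\n")


def read_complex_catalog(path: str | Path) -> ComplexCatalog:
    """Complexes as GMT or two-column TSV (complex_id, member)."""
    path = Path(path)
    first = path.read_text().splitlines()[0] if path.read_text().strip() else ""
    if path.suffix == ".gmt" or len(first.split("\t")) >= 3:
        return ComplexCatalog(read_gmt(path))
    table = pd.read_csv(path, sep="\t", dtype=str)
    cid_col, member_col = table.columns[:2]
    complexes: dict[str, set[str]] = {}
    for _, row in table.iterrows():
        complexes.setdefault(row[cid_col], set()).add(row[member_col])
    return ComplexCatalog(complexes)


def read_localization(path: str | Path) -> LocalizationMap:
    """Two-column TSV (protein, compartment); repeated proteins accumulate."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    pcol, ccol = table.columns[:2]
    locations: dict[str, set[str]] = {}
    for _, row in table.iterrows():
        locations.setdefault(row[pcol], set()).add(row[ccol])
    return LocalizationMap(locations)


def read_pathway_model(path: str | Path) -> PathwayModel:
    """Pathway model from JSON ({id: {name, reactions: {rid: [entities]}}})
    or a flat three-column TSV (pathway_id, reaction_id, entity_id)."""
    path = Path(path)
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
        pathways = {
            pid: Pathway(
                pathway_id=pid,
                name=entry.get("name", pid),
                reactions={rid: set(ents) for rid, ents in entry["reactions"].items()},
            )
            for pid, entry in raw.items()
        }
        return PathwayModel(pathways)
    table = pd.read_csv(path, sep="\t", dtype=str)
    pcol, rcol, ecol = table.columns[:3]
    tree: dict[str, dict[str, set[str]]] = {}
    for _, row in table.iterrows():
        tree.setdefault(row[pcol], {}).setdefault(row[rcol], set())
        if isinstance(row[ecol], str) and row[ecol]:
            tree[row[pcol]][row[rcol]].add(row[ecol])
    return PathwayModel(
        {pid: Pathway(pid, pid, reactions) for pid, reactions in tree.items()}
    )


def write_pathway_model(model: PathwayModel, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    raw = {
        pw.pathway_id: {
            "name": pw.name,
            "reactions": {rid: sorted(ents) for rid, ents in pw.reactions.items()},
        }
        for pw in model
    }
    Path(path).write_text(json.dumps(raw, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Dendrogram export
# ---------------------------------------------------------------------------

def dendrogram_to_newick(tree: DendrogramModel) -> str:
    """Serialise the linkage tree to Newick with merge heights as branch
    lengths (leaf labels are protein ids)."""
    Z, leaves = tree.linkage, tree.leaves
    n = len(leaves)

    def height(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n, 2])

    def render(node: int, parent_h: float) -> str:
        length = parent_h - height(node)
        if node < n:
            return f"{leaves[node]}:{length:.6g}"
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = height(node)
        return f"({render(left, h)},{render(right, h)}):{length:.6g}"

    root = 2 * n - 2
    root_h = height(root)
    left, right = int(Z[root - n, 0]), int(Z[root - n, 1])
    return f"({render(left, root_h)},{render(right, root_h)});"
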