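"""Readers and writers for the on-disk formats the pipeline touches.

All tabular files are tab-delimited UTF-8 with a header line; lines starting
with ``#`` are ignored. FASTA ids are the first whitespace-delimited header
token. Positions are 1-based on disk and in memory.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    ALPHABET,
    NAMESPACES,
    Dataset,
    FeatureMatrix,
    PhosphoSite,
    Protein,
    StructureAnnotation,
    StructureTable,
)

logger = logging.getLogger(__name__)

#: Default STRING-style interaction score cutoff for partner-term features.
DEFAULT_PPI_CUTOFF = 400.0


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> List[Protein]:
    """Read a proteome FASTA.

    Sequences are uppercased; characters outside the 20 standard codes are
    replaced by ``X`` (with a warning). Duplicate ids and empty files are
    errors.
    """
    proteins: List[Protein] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate protein id in FASTA: {pid}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        cleaned = "".join(c if c in ALPHABET else "X" for c in seq)
        if cleaned != seq:
            bad = sorted({c for c in seq if c not in ALPHABET})
            logger.warning(
                "protein %s: replaced non-standard residues %s with X", pid, bad
            )
        proteins.append(Protein(pid, cleaned))
    if not proteins:
        raise ValueError(f"no FASTA records in {path}")
    return proteins


def write_fasta(path, proteins: Iterable[Protein]) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Phosphosites

SITE_COLUMNS = ["protein_id", "position", "residue", "family"]


def read_sites(path, proteome: Optional[Dict[str, Protein]] = None) -> List[PhosphoSite]:
    """Read a phosphosite TSV (protein_id, position, residue, family).

    Duplicate (protein, position, family) rows collapse to one with a warning.
    When a proteome is supplied, every site is validated against it and all
    offending rows are reported together.
    """
    df = _read_tsv(path)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sites file {path} missing columns: {missing}")
    before = len(df)
    df = df.drop_duplicates(subset=["protein_id", "position", "family"])
    if len(df) < before:
        logger.warning(
            "sites file %s: dropped %d duplicate rows", path, before - len(df)
        )
    sites = [
        PhosphoSite(r.protein_id, int(r.position), r.residue, r.family)
        for r in df.itertuples(index=False)
    ]
    if proteome is not None:
        errors = []
        for site in sites:
            prot = proteome.get(site.protein_id)
            if prot is None:
                errors.append(f"{site.protein_id}:{site.position}: unknown protein")
                continue
            try:
                site.validate_against(prot)
            except ValueError as exc:
                errors.append(str(exc))
        if errors:
            raise ValueError(
                f"sites file {path}: {len(errors)} invalid rows:\n"
                + "\n".join(errors)
            )
    return sites


def write_sites(path, sites: Iterable[PhosphoSite]) -> None:
    df = pd.DataFrame(
        [(s.protein_id, s.position, s.residue, s.family) for s in sites],
        columns=SITE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotations

def read_annotations(
    path,
    namespace: str,
    protein_ids: Optional[Iterable[str]] = None,
    ppi_score_cutoff: float = DEFAULT_PPI_CUTOFF,
) -> FeatureMatrix:
    """Read a long-format annotation TSV into a binary incidence matrix.

    The standard dialect has columns (protein_id, term_id). For the
    ``string_ppi`` namespace a 3-column dialect (protein_a, protein_b, score)
    is also accepted: pairs with score >= ``ppi_score_cutoff`` become binary
    partner-presence terms ``partner:<id>`` on both interactors.
    """
    if namespace not in NAMESPACES:
        raise ValueError(
            f"unknown namespace {namespace!r}; expected one of {NAMESPACES}"
        )
    df = _read_tsv(path)
    cols = list(df.columns)
    if {"protein_a", "protein_b", "score"}.issubset(cols):
        if namespace != "string_ppi":
            raise ValueError(
                f"interaction dialect is only valid for string_ppi, not {namespace}"
            )
        pairs: List[Tuple[str, str]] = []
        for r in df.itertuples(index=False):
            if float(r.score) >= ppi_score_cutoff:
                pairs.append((r.protein_a, f"partner:{r.protein_b}"))
                pairs.append((r.protein_b, f"partner:{r.protein_a}"))
    else:
        if not {"protein_id", "term_id"}.issubset(cols):
            raise ValueError(
                f"annotation file {path} must have columns protein_id, term_id"
            )
        if df["term_id"].isna().any() or (df["term_id"].str.len() == 0).any():
            raise ValueError(f"annotation file {path} contains empty term ids")
        pairs = list(zip(df["protein_id"], df["term_id"]))
    return FeatureMatrix.from_pairs(namespace, pairs, protein_ids=protein_ids)


def write_annotations(path, matrix: FeatureMatrix) -> None:
    df = pd.DataFrame(list(matrix.pairs()), columns=["protein_id", "term_id"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Structure

STRUCTURE_COLUMNS = ["protein_id", "position", "ss_label", "acc_score"]


def read_structure(path) -> StructureTable:
    df = _read_tsv(path)
    missing = [c for c in STRUCTURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"structure file {path} missing columns: {missing}")
    table = StructureTable()
    for r in df.itertuples(index=False):
        table.add(r.protein_id, int(r.position), r.ss_label, int(r.acc_score))
    return table


def write_structure(path, table: StructureTable) -> None:
    df = pd.DataFrame(
        [(r.protein_id, r.position, r.ss_label, r.acc_score) for r in table.records()],
        columns=STRUCTURE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Predictions

@dataclass(frozen=True)
class PredictionRecord:
    """One predicted phosphosite from a proteome scan."""

    protein_id: str
    position: int
    residue: str
    family: str
    decision_value: float
    protein_score: float


PREDICTION_COLUMNS = [
    "protein_id",
    "position",
    "residue",
    "family",
    "decision_value",
    "protein_score",
]


def write_predictions(path, records: Sequence[PredictionRecord]) -> None:
    """Write the predicted-site TSV (header always present, >=6 sig digits)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.protein_id}\t{r.position}\t{r.residue}\t{r.family}\t"
                f"{r.decision_value:.6g}\t{r.protein_score:.6g}\n"
            )


def read_predictions(path) -> List[PredictionRecord]:
    df = _read_tsv(path)
    return [
        PredictionRecord(
            r.protein_id,
            int(r.position),
            r.residue,
            r.family,
            float(r.decision_value),
            float(r.protein_score),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Dataset directories

def write_dataset(directory, dataset: Dataset) -> None:
    """Write a Dataset as the standard file layout under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_fasta(d / "proteome.fasta", dataset.proteome.values())
    write_sites(d / "sites.tsv", dataset.sites)
    for ns, mat in dataset.matrices.items():
        write_annotations(d / f"annotations_{ns}.tsv", mat)
    if dataset.structure is not None:
        write_structure(d / "structure.tsv", dataset.structure)


def read_dataset(directory) -> Dataset:
    """Load a Dataset from the layout written by :func:`write_dataset`."""
    d = Path(directory)
    proteins = read_fasta(d / "proteome.fasta")
    proteome = {p.id: p for p in proteins}
    sites = read_sites(d / "sites.tsv", proteome)
    matrices: Dict[str, FeatureMatrix] = {}
    for path in sorted(d.glob("annotations_*.tsv")):
        ns = path.stem[len("annotations_"):]
        matrices[ns] = read_annotations(path, ns, protein_ids=list(proteome))
    structure = None
    if (d / "structure.tsv").exists():
        structure = read_structure(d / "structure.tsv")
    ds = Dataset(proteome=proteome, sites=sites, matrices=matrices, structure=structure)
    ds.validate()
    return ds
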