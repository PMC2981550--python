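"""Core domain types shared across the pipeline.

Positions are 1-based everywhere — in files and in memory — matching the
convention used by phosphorylation-site databases. Sequences use the 20
standard one-letter amino-acid codes plus ``X`` for unknown residues.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

#: Canonical residue ordering used for one-hot encoding.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ORDER)
ALPHABET = AA_SET | {"X"}

#: Annotation namespaces understood by the pipeline.
NAMESPACES = ("kegg", "go_bp", "go_cc", "go_mf", "pfam", "interpro", "string_ppi")

PHOSPHO_RESIDUES = frozenset("STY")


@dataclass(frozen=True)
class Protein:
    """A protein sequence with a whitespace-free identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid protein id: {self.id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for protein {self.id}")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id}: characters outside alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"position {position} out of range 1..{len(self.sequence)} "
                f"for protein {self.id}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class PhosphoSite:
    """An experimentally supported phosphorylation site.

    ``position`` is 1-based; ``residue`` is the phospho-acceptor (S, T or Y);
    ``family`` names the kinase family the site is attributed to.
    """

    protein_id: str
    position: int
    residue: str
    family: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"residue must be one of S/T/Y, got {self.residue!r}")
        if not self.family:
            raise ValueError("empty kinase family label")

    def validate_against(self, protein: Protein) -> None:
        if self.position > len(protein):
            raise ValueError(
                f"site {self.protein_id}:{self.position} beyond sequence "
                f"length {len(protein)}"
            )
        actual = protein.residue(self.position)
        if actual != self.residue:
            raise ValueError(
                f"site {self.protein_id}:{self.position} residue mismatch: "
                f"annotated {self.residue}, sequence has {actual}"
            )


@dataclass(frozen=True)
class StructureAnnotation:
    """Per-residue secondary structure (H/E/C) and solvent accessibility (0-9)."""

    protein_id: str
    position: int
    ss_label: str
    acc_score: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.ss_label not in ("H", "E", "C"):
            raise ValueError(f"ss_label must be H/E/C, got {self.ss_label!r}")
        if not 0 <= self.acc_score <= 9:
            raise ValueError(f"acc_score must be 0..9, got {self.acc_score}")


class StructureTable:
    """Lookup table of per-residue structure annotations.

    At most one record per (protein, position); missing positions are allowed
    and treated as unknown by the feature encoders.
    """

    def __init__(self, records: Iterable[StructureAnnotation] = ()) -> None:
        self._data: Dict[str, Dict[int, Tuple[str, int]]] = {}
        for rec in records:
            self.add(rec.protein_id, rec.position, rec.ss_label, rec.acc_score)

    def add(self, protein_id: str, position: int, ss_label: str, acc_score: int) -> None:
        per = self._data.setdefault(protein_id, {})
        if position in per:
            raise ValueError(
                f"duplicate structure record for {protein_id}:{position}"
            )
        per[position] = (ss_label, int(acc_score))

    def add_protein(self, protein_id: str, ss_labels: str, acc_scores: Iterable[int]) -> None:
        """Bulk-add a full-coverage annotation for one protein (positions 1..L)."""
        acc = list(acc_scores)
        if len(ss_labels) != len(acc):
            raise ValueError("ss_labels and acc_scores length mismatch")
        per = self._data.setdefault(protein_id, {})
        for i, (s, a) in enumerate(zip(ss_labels, acc), start=1):
            per[i] = (s, int(a))

    def get(self, protein_id: str, position: int) -> Optional[Tuple[str, int]]:
        per = self._data.get(protein_id)
        if per is None:
            return None
        return per.get(position)

    def records(self) -> Iterator[StructureAnnotation]:
        for pid in sorted(self._data):
            for pos in sorted(self._data[pid]):
                ss, acc = self._data[pid][pos]
                yield StructureAnnotation(pid, pos, ss, acc)

    def __len__(self) -> int:
        return sum(len(v) for v in self._data.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureTable):
            return NotImplemented
        return self._data == other._data


@dataclass
class FeatureMatrix:
    """Binary protein x term incidence for one annotation namespace."""

    namespace: str
    protein_ids: List[str]
    term_ids: List[str]
    incidence: np.ndarray  # shape (n_proteins, n_terms), values 0/1

    def __post_init__(self) -> None:
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError(f"duplicate protein ids in {self.namespace} matrix")
        if len(set(self.term_ids)) != len(self.term_ids):
            raise ValueError(f"duplicate term ids in {self.namespace} matrix")
        self.incidence = np.asarray(self.incidence, dtype=np.uint8)
        if self.incidence.shape != (len(self.protein_ids), len(self.term_ids)):
            raise ValueError(
                f"{self.namespace} incidence shape {self.incidence.shape} does not "
                f"match ({len(self.protein_ids)}, {len(self.term_ids)})"
            )
        if self.incidence.size and self.incidence.max() > 1:
            raise ValueError("incidence values must be 0 or 1")
        self._prow = {p: i for i, p in enumerate(self.protein_ids)}
        self._tcol = {t: j for j, t in enumerate(self.term_ids)}

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)

    def protein_row(self, protein_id: str) -> int:
        return self._prow[protein_id]

    def term_col(self, term_id: str) -> int:
        return self._tcol[term_id]

    def has_term(self, protein_id: str, term_id: str) -> int:
        """Incidence value; proteins absent from the matrix count as 0."""
        i = self._prow.get(protein_id)
        if i is None:
            return 0
        return int(self.incidence[i, self._tcol[term_id]])

    def align(self, protein_ids: Iterable[str]) -> "FeatureMatrix":
        """Re-index rows onto ``protein_ids``; unknown proteins get all-zero rows."""
        ids = list(protein_ids)
        out = np.zeros((len(ids), self.n_terms), dtype=np.uint8)
        for i, pid in enumerate(ids):
            j = self._prow.get(pid)
            if j is not None:
                out[i] = self.incidence[j]
        return FeatureMatrix(self.namespace, ids, list(self.term_ids), out)

    def pairs(self) -> Iterator[Tuple[str, str]]:
        """Yield (protein_id, term_id) for every 1 entry, row-major."""
        rows, cols = np.nonzero(self.incidence)
        for r, c in zip(rows.tolist(), cols.tolist()):
            yield self.protein_ids[r], self.term_ids[c]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.namespace == other.namespace
            and self.protein_ids == other.protein_ids
            and self.term_ids == other.term_ids
            and np.array_equal(self.incidence, other.incidence)
        )

    @classmethod
    def from_pairs(
        cls,
        namespace: str,
        pairs: Iterable[Tuple[str, str]],
        protein_ids: Optional[Iterable[str]] = None,
    ) -> "FeatureMatrix":
        """Build a binary matrix from (protein, term) pairs.

        Duplicate pairs collapse to a single 1. If ``protein_ids`` is given the
        rows are aligned to it (extra proteins get all-zero rows); otherwise
        rows follow first appearance order.
        """
        pair_list = list(pairs)
        terms: List[str] = []
        tseen = set()
        for _, t in pair_list:
            if t not in tseen:
                tseen.add(t)
                terms.append(t)
        if protein_ids is None:
            prots: List[str] = []
            pseen = set()
            for p, _ in pair_list:
                if p not in pseen:
                    pseen.add(p)
                    prots.append(p)
        else:
            prots = list(protein_ids)
        prow = {p: i for i, p in enumerate(prots)}
        tcol = {t: j for j, t in enumerate(terms)}
        inc = np.zeros((len(prots), len(terms)), dtype=np.uint8)
        for p, t in pair_list:
            i = prow.get(p)
            if i is not None:
                inc[i, tcol[t]] = 1
        return cls(namespace, prots, terms, inc)


@dataclass
class Dataset:
    """A proteome, its known phosphosites, annotation matrices and structure."""

    proteome: Dict[str, Protein]
    sites: List[PhosphoSite]
    matrices: Dict[str, FeatureMatrix] = field(default_factory=dict)
    structure: Optional[StructureTable] = None

    def validate(self) -> None:
        """Referential integrity: sites resolve, matrices align to the proteome."""
        errors: List[str] = []
        for site in self.sites:
            prot = self.proteome.get(site.protein_id)
            if prot is None:
                errors.append(f"site references unknown protein {site.protein_id}")
                continue
            try:
                site.validate_against(prot)
            except ValueError as exc:
                errors.append(str(exc))
        for ns, mat in self.matrices.items():
            extra = set(mat.protein_ids) - set(self.proteome)
            if extra:
                errors.append(
                    f"matrix {ns} references unknown proteins: {sorted(extra)[:5]}"
                )
        if errors:
            raise ValueError("dataset validation failed:\n" + "\n".join(errors))

    def families(self) -> List[str]:
        return sorted({s.family for s in self.sites})

    def family_sites(self, family: str) -> List[PhosphoSite]:
        return [s for s in self.sites if s.family == family]

    def substrate_ids(self, family: str) -> List[str]:
        """Substrate protein ids for a family, in proteome order."""
        wanted = {s.protein_id for s in self.family_sites(family)}
        return [pid for pid in self.proteome if pid in wanted]

    def known_positions(self) -> set:
        """All (protein_id, position) pairs that are known sites, any family."""
        return {(s.protein_id, s.position) for s in self.sites}
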