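"""Peptide windows and their binary encodings.

A candidate site is represented by the 9-mer window covering the central
residue and the -4..+4 flanking positions (half-window h=4 by default),
padded with ``X`` where the window overruns a terminus. Each window residue
contributes a 20-bit one-hot block (order ACDEFGHIKLMNPQRSTVWY; ``X`` and
padding encode as all zeros), a coil flag (1 for coil, 0 for helix/strand)
and a 7-bit solvent-accessibility one-hot (bins 0..6; scores above 6 clamp
to 6). For h=4 the full sequence+structure vector has 180 + 9 + 63 = 252
bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .datatypes import AA_ORDER, Protein, StructureTable

logger = logging.getLogger(__name__)

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Accessibility scores are binned to 0..6 (higher observed scores clamp).
N_ACC_BINS = 7


@dataclass(frozen=True)
class PeptideWindow:
    """A (2h+1)-mer peptide centered on a 1-based protein position."""

    protein_id: str
    position: int
    peptide: str

    @property
    def center(self) -> str:
        return self.peptide[len(self.peptide) // 2]

    @property
    def half_window(self) -> int:
        return len(self.peptide) // 2


@dataclass(frozen=True)
class SiteVector:
    """Binary feature vector for one site, with named block layout."""

    values: np.ndarray
    layout: Dict[str, slice]

    def block(self, name: str) -> np.ndarray:
        return self.values[self.layout[name]]


def extract_window(protein: Protein, position: int, h: int = 4) -> PeptideWindow:
    """Extract the 2h+1 window around a 1-based position, X-padded at termini."""
    if not 1 <= position <= len(protein):
        raise IndexError(
            f"position {position} out of range 1..{len(protein)} for {protein.id}"
        )
    seq = protein.sequence
    chars = []
    for off in range(-h, h + 1):
        idx = position - 1 + off
        chars.append(seq[idx] if 0 <= idx < len(seq) else "X")
    return PeptideWindow(protein.id, position, "".join(chars))


def onehot_encode(window: Union[PeptideWindow, str]) -> np.ndarray:
    """One-hot encode a peptide: 20 bits per residue, ``X`` -> all zeros."""
    peptide = window.peptide if isinstance(window, PeptideWindow) else window
    out = np.zeros(20 * len(peptide), dtype=np.float64)
    for i, aa in enumerate(peptide):
        if aa == "X":
            continue
        j = AA_INDEX.get(aa)
        if j is None:
            raise ValueError(f"unknown residue {aa!r} in peptide {peptide}")
        out[20 * i + j] = 1.0
    return out


def encode_structure(
    window: PeptideWindow, structure: Optional[StructureTable]
) -> Tuple[np.ndarray, np.ndarray]:
    """Coil flags and accessibility one-hots for a window's residues.

    Coil flag is 1 iff the secondary-structure label is C (helix and strand
    are 0). Accessibility sets the bit at index min(score, 6). Positions that
    are padded, or that have no structure record, contribute zeros.
    """
    h = window.half_window
    width = 2 * h + 1
    coil = np.zeros(width, dtype=np.float64)
    acc = np.zeros(N_ACC_BINS * width, dtype=np.float64)
    missing = 0
    for i, off in enumerate(range(-h, h + 1)):
        if window.peptide[i] == "X":
            continue
        rec = None if structure is None else structure.get(
            window.protein_id, window.position + off
        )
        if rec is None:
            missing += 1
            continue
        ss_label, acc_score = rec
        if ss_label == "C":
            coil[i] = 1.0
        acc[N_ACC_BINS * i + min(acc_score, N_ACC_BINS - 1)] = 1.0
    if missing:
        logger.warning(
            "window %s:%d: %d residues without structure records (encoded as zeros)",
            window.protein_id,
            window.position,
            missing,
        )
    return coil, acc


def site_vector(
    window: PeptideWindow, structure: Optional[StructureTable]
) -> SiteVector:
    """Full sequence+structure vector (252 bits for h=4)."""
    seq = onehot_encode(window)
    coil, acc = encode_structure(window, structure)
    values = np.concatenate([seq, coil, acc])
    layout = {
        "sequence": slice(0, len(seq)),
        "coil": slice(len(seq), len(seq) + len(coil)),
        "accessibility": slice(len(seq) + len(coil), len(values)),
    }
    return SiteVector(values, layout)


def sequence_struct_length(h: int = 4) -> int:
    """Length of the sequence+structure block: 20(2h+1) + (2h+1) + 7(2h+1)."""
    return (20 + 1 + N_ACC_BINS) * (2 * h + 1)


def pairwise_identity(a: Union[PeptideWindow, str], b: Union[PeptideWindow, str]) -> float:
    """Fraction of positions with equal residues; ``X`` matches nothing."""
    sa = a.peptide if isinstance(a, PeptideWindow) else a
    sb = b.peptide if isinstance(b, PeptideWindow) else b
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "X")
    return matches / len(sa)


def greedy_homology_filter(
    windows: Sequence[Union[PeptideWindow, str]], threshold: float = 0.7
) -> List[Union[PeptideWindow, str]]:
    """Scan in input order, keeping a window iff its identity to every
    previously kept window is <= threshold (strictly "over" is discarded)."""
    kept: List[Union[PeptideWindow, str]] = []
    kept_strs: List[str] = []
    for w in windows:
        s = w.peptide if isinstance(w, PeptideWindow) else w
        if all(pairwise_identity(s, k) <= threshold for k in kept_strs):
            kept.append(w)
            kept_strs.append(s)
    return kept
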