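"""Annotated proteins, arginine-centered peptide windows, and dataset
construction.

The modelling unit is an odd-length peptide window centered on an arginine,
X-padded at the protein termini so every window is symmetric about its
central residue. Positive windows are experimentally verified methylation
sites; all remaining arginines start as *unlabeled* and become
pseudo-negatives only after similarity filtering against the positive set,
mirroring the CD-HIT / CD-HIT-2d workflow at a 40% identity cut-off.
Because every window has the same length, identity is computed as ungapped
positional identity, with the padding symbol X matching nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Set, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .scales import AMINO_ACIDS, NONSTANDARD

logger = logging.getLogger(__name__)

MIN_PROTEIN_LENGTH = 30

POSITIVE = "positive"
UNLABELED = "unlabeled"
NEGATIVE = "negative"
_LABELS = (POSITIVE, UNLABELED, NEGATIVE)

_SEQUENCE_LETTERS = frozenset(AMINO_ACIDS) | {"X"} | NONSTANDARD


@dataclass(frozen=True)
class AnnotatedProtein:
    """A protein sequence plus its verified methylated arginine positions.

    Positions are 1-based. Every annotated position must index an 'R' and the
    sequence must be at least 30 residues long (shorter fragments are
    excluded upstream).
    """

    id: str
    sequence: str
    methylated_positions: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _SEQUENCE_LETTERS
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid sequence letters {sorted(bad)}"
            )
        if len(self.sequence) < MIN_PROTEIN_LENGTH:
            raise ValueError(
                f"protein {self.id!r}: sequence shorter than "
                f"{MIN_PROTEIN_LENGTH} aa"
            )
        for pos in self.methylated_positions:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"position {pos} of {self.id} is out of range"
                )
            if self.sequence[pos - 1] != "R":
                raise ValueError(f"position {pos} of {self.id} is not R")

    @property
    def arginine_positions(self) -> List[int]:
        """All 1-based positions of 'R' in the sequence."""
        return [i + 1 for i, aa in enumerate(self.sequence) if aa == "R"]


@dataclass(frozen=True)
class PeptideWindow:
    """An odd-length, arginine-centered peptide over the 21-letter alphabet.

    ``center_position`` is the 1-based position of the central R on the
    source protein. X occurs only as contiguous terminal padding.
    """

    peptide: str
    label: str
    protein_id: str
    center_position: int

    def __post_init__(self) -> None:
        if len(self.peptide) % 2 == 0:
            raise ValueError("window length must be odd")
        if self.label not in _LABELS:
            raise ValueError(f"invalid label {self.label!r}")
        mid = len(self.peptide) // 2
        if self.peptide[mid] != "R":
            raise ValueError(
                f"window center must be 'R', got {self.peptide[mid]!r}"
            )
        core = self.peptide.strip("X")
        if "X" in core:
            raise ValueError("X allowed only as terminal padding")

    def __len__(self) -> int:
        return len(self.peptide)


@dataclass
class WindowDataset:
    """An ordered collection of equal-length peptide windows."""

    window_length: int
    windows: List[PeptideWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        for w in self.windows:
            if len(w) != self.window_length:
                raise ValueError(
                    f"window {w.peptide!r} has length {len(w)}, "
                    f"expected {self.window_length}"
                )

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[PeptideWindow]:
        return iter(self.windows)

    def __getitem__(self, i: int) -> PeptideWindow:
        return self.windows[i]

    @property
    def peptides(self) -> List[str]:
        return [w.peptide for w in self.windows]

    def relabeled(self, label: str) -> "WindowDataset":
        return WindowDataset(
            self.window_length,
            [replace(w, label=label) for w in self.windows],
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame(
            {
                "peptide": [w.peptide for w in self.windows],
                "label": [w.label for w in self.windows],
                "protein_id": [w.protein_id for w in self.windows],
                "center_position": [w.center_position for w in self.windows],
                "window_length": self.window_length,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "WindowDataset":
        df = pd.read_csv(path, sep="\t", dtype={"peptide": str})
        if df.empty:
            raise ValueError(f"empty window table: {path}")
        lengths = df["window_length"].unique()
        if len(lengths) != 1:
            raise ValueError("mixed window lengths in table")
        windows = [
            PeptideWindow(r.peptide, r.label, r.protein_id, int(r.center_position))
            for r in df.itertuples()
        ]
        return cls(int(lengths[0]), windows)


def load_annotated_proteins(
    fasta_path: Union[str, Path], sites_path: Union[str, Path]
) -> List[AnnotatedProtein]:
    """Read a FASTA file plus a TSV site table into annotated proteins.

    The site table has a header with columns ``protein_id`` and ``position``
    (1-based). A site pointing at a non-arginine residue, or at a protein id
    absent from the FASTA, is a hard error. Proteins shorter than 30 aa are
    dropped with a warning. Records without any annotated site are retained
    (with an empty annotation set) so the same reader serves prediction-time
    input.
    """
    records = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    sites = pd.read_csv(sites_path, sep="\t", dtype={"protein_id": str})
    if not {"protein_id", "position"} <= set(sites.columns):
        raise ValueError(
            "site table must have columns 'protein_id' and 'position'"
        )
    by_protein: Dict[str, Set[int]] = {}
    for row in sites.itertuples():
        pid, pos = row.protein_id, int(row.position)
        if pid not in records:
            raise ValueError(f"site table references unknown protein {pid!r}")
        seq = records[pid]
        if not 1 <= pos <= len(seq):
            raise ValueError(f"position {pos} of {pid} is out of range")
        if seq[pos - 1] != "R":
            raise ValueError(f"position {pos} of {pid} is not R")
        by_protein.setdefault(pid, set()).add(pos)

    proteins: List[AnnotatedProtein] = []
    for pid, seq in records.items():
        if len(seq) < MIN_PROTEIN_LENGTH:
            logger.warning(
                "dropping %s: length %d < %d aa", pid, len(seq),
                MIN_PROTEIN_LENGTH,
            )
            continue
        proteins.append(
            AnnotatedProtein(pid, seq, frozenset(by_protein.get(pid, ())))
        )
    return proteins


def load_proteins_fasta(fasta_path: Union[str, Path]) -> List[AnnotatedProtein]:
    """Read prediction-time input: FASTA alone, no site annotations.

    Records shorter than 30 aa are dropped with a warning, as at training
    time.
    """
    proteins: List[AnnotatedProtein] = []
    n_records = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_records += 1
        seq = str(rec.seq).upper()
        if len(seq) < MIN_PROTEIN_LENGTH:
            logger.warning(
                "dropping %s: length %d < %d aa", rec.id, len(seq),
                MIN_PROTEIN_LENGTH,
            )
            continue
        proteins.append(AnnotatedProtein(rec.id, seq))
    if n_records == 0:
        raise ValueError(f"empty FASTA: {fasta_path}")
    return proteins


def extract_windows(
    protein: AnnotatedProtein, window_length: int
) -> List[PeptideWindow]:
    """One window per arginine: positive if annotated, else unlabeled.

    Termini are X-padded to keep the arginine central. Windows that would
    include a nonstandard residue (B, Z, U, O) are dropped with a warning.
    """
    if window_length % 2 == 0 or window_length < 7:
        raise ValueError("window_length must be odd and >= 7")
    half = window_length // 2
    seq = protein.sequence
    out: List[PeptideWindow] = []
    for pos in protein.arginine_positions:
        start, stop = pos - 1 - half, pos + half  # 0-based [start, stop)
        left_pad = max(0, -start)
        right_pad = max(0, stop - len(seq))
        core = seq[max(0, start):min(len(seq), stop)]
        peptide = "X" * left_pad + core + "X" * right_pad
        if set(peptide) & NONSTANDARD:
            logger.warning(
                "dropping window at %s:%d: nonstandard residue", protein.id,
                pos,
            )
            continue
        label = POSITIVE if pos in protein.methylated_positions else UNLABELED
        out.append(PeptideWindow(peptide, label, protein.id, pos))
    return out


def extract_all_windows(
    proteins: Iterable[AnnotatedProtein], window_length: int
) -> Tuple[WindowDataset, WindowDataset]:
    """Windows for a protein collection, split into (positive, unlabeled)."""
    pos: List[PeptideWindow] = []
    unl: List[PeptideWindow] = []
    for protein in proteins:
        for w in extract_windows(protein, window_length):
            (pos if w.label == POSITIVE else unl).append(w)
    return WindowDataset(window_length, pos), WindowDataset(window_length, unl)


def window_identity(
    a: Union[str, PeptideWindow], b: Union[str, PeptideWindow]
) -> float:
    """Ungapped fractional identity between two equal-length peptides.

    X matches nothing, including another X, so terminal padding never
    creates similarity.
    """
    pa = a.peptide if isinstance(a, PeptideWindow) else a
    pb = b.peptide if isinstance(b, PeptideWindow) else b
    if len(pa) != len(pb):
        raise ValueError("peptides must have equal length")
    matches = sum(
        1 for x, y in zip(pa, pb) if x == y and x != "X"
    )
    return matches / len(pa)


def reduce_redundancy(
    windows: WindowDataset, threshold: float = 0.4
) -> WindowDataset:
    """Greedy redundancy reduction in input order.

    A window is retained iff its identity to every previously retained
    window is below ``threshold``; the result is a subset of the input in
    which no retained pair reaches the threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if len(windows) == 0:
        raise ValueError("empty input")
    kept: List[PeptideWindow] = []
    for w in windows:
        if all(window_identity(w, k) < threshold for k in kept):
            kept.append(w)
    return WindowDataset(windows.window_length, kept)


def derive_negatives(
    unlabeled: WindowDataset,
    positives: WindowDataset,
    threshold: float = 0.4,
) -> WindowDataset:
    """Pseudo-negatives: unlabeled windows dissimilar to every positive.

    An unlabeled window survives iff its identity to each positive window is
    strictly below ``threshold``; survivors are relabeled negative.
    """
    if unlabeled.window_length != positives.window_length:
        raise ValueError("window lengths must match")
    kept = [
        w
        for w in unlabeled
        if all(window_identity(w, p) < threshold for p in positives)
    ]
    return WindowDataset(unlabeled.window_length, kept).relabeled(NEGATIVE)


def split_dataset(
    positives: WindowDataset,
    negatives: WindowDataset,
    seed: int,
) -> Tuple[WindowDataset, WindowDataset, WindowDataset, WindowDataset]:
    """Random 4:1 train/test split of positives, with an equal-size negative
    test set drawn from the negatives.

    Returns ``(train_pos, test_pos, train_neg, test_neg)``. The test share is
    ``round(N/5)`` of the positives; the negative test set has exactly the
    same size, and the remaining negatives form the negative training pool.
    """
    n_test = int(round(len(positives) / 5))
    if len(negatives) < n_test:
        raise ValueError(
            f"need at least {n_test} negatives for the test set, "
            f"have {len(negatives)}"
        )
    rng = np.random.default_rng(seed)
    L = positives.window_length
    pos_idx = rng.permutation(len(positives))
    neg_idx = rng.permutation(len(negatives))
    test_pos = [positives[i] for i in sorted(pos_idx[:n_test])]
    train_pos = [positives[i] for i in sorted(pos_idx[n_test:])]
    test_neg = [negatives[i] for i in sorted(neg_idx[:n_test])]
    train_neg = [negatives[i] for i in sorted(neg_idx[n_test:])]
    return (
        WindowDataset(L, train_pos),
        WindowDataset(L, test_pos),
        WindowDataset(L, train_neg),
        WindowDataset(L, test_neg),
    )


def make_negative_subsets(
    train_neg: WindowDataset,
    n_positive_train: int,
    k: int = 5,
    seed: int = 0,
) -> List[WindowDataset]:
    """Class-balancing under-sampling: k negative subsets of size equal to
    the positive training set, each sampled without replacement.
    """
    if len(train_neg) < n_positive_train:
        raise ValueError(
            f"need {n_positive_train} negatives per subset, "
            f"have {len(train_neg)}"
        )
    if len(train_neg) == n_positive_train:
        logger.info(
            "negative pool equals subset size; the %d subsets are identical",
            k,
        )
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(k):
        idx = rng.choice(len(train_neg), size=n_positive_train, replace=False)
        subsets.append(
            WindowDataset(
                train_neg.window_length,
                [train_neg[i] for i in sorted(idx)],
            )
        )
    return subsets
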