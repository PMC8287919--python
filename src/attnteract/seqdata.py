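"""Sequence and label I/O, one-hot encoding and dataset splitting.

DNA sequences are held as plain strings over ``{A, C, G, T, N}`` and
encoded as 4 x L binary matrices with the fixed channel order A, C, G, T
(every position-weight matrix in the package uses the same order).
Unknown bases (``N``) encode as an all-zero column, which leaves
convolution outputs untouched by positions with no sequence information.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import numpy as np
import pandas as pd
from Bio import SeqIO

ALPHABET = "ACGT"
VALID_BASES = frozenset("ACGTN")
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "Sequence", "LabeledDataset", "read_fasta", "write_fasta",
    "one_hot_encode", "one_hot_decode", "encode_batch", "reverse_complement",
    "read_label_table", "write_label_table", "read_bed_intervals",
    "split_dataset", "equalize_length",
]


@dataclasses.dataclass(frozen=True)
class Sequence:
    """One DNA sequence; ``bases`` is an uppercase string over A/C/G/T/N."""

    id: str
    bases: str

    def __post_init__(self):
        bad = set(self.bases) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclasses.dataclass
class LabeledDataset:
    """Sequences with binary or multi-label targets and split assignments.

    ``labels`` has shape (n,) for a binary task or (n, C) for a C-task
    multi-label problem.  ``split`` holds one tag per example out of
    {"train", "val", "test"} ("" before :func:`split_dataset` runs).
    """

    sequences: list[Sequence]
    labels: np.ndarray
    split: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences disagree in length")
        if self.split is None:
            self.split = np.array([""] * len(self.sequences), dtype=object)

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    @property
    def n_tasks(self) -> int:
        return 1 if self.labels.ndim == 1 else self.labels.shape[1]

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return LabeledDataset([self.sequences[i] for i in idx],
                              self.labels[idx], self.split[idx].copy())

    def split_subset(self, tag: str) -> "LabeledDataset":
        return self.subset(self.split == tag)


def read_fasta(path) -> list[Sequence]:
    """Read a FASTA file into a list of :class:`Sequence` (order preserved).

    Bases are uppercased on load; characters outside A/C/G/T/N raise a
    ``ValueError`` naming the record and character.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found (empty or malformed file)")
    out = []
    for rec in records:
        bases = str(rec.seq).upper()
        bad = set(bases) - VALID_BASES
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains invalid character(s) {sorted(bad)}")
        out.append(Sequence(rec.id, bases))
    return out


def write_fasta(sequences: Iterable[Sequence], path) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n{seq.bases}\n")


def one_hot_encode(seq: Sequence | str) -> np.ndarray:
    """Encode as a 4 x L {0,1} matrix; N columns are all-zero."""
    bases = seq.bases if isinstance(seq, Sequence) else seq
    mat = np.zeros((4, len(bases)), dtype=np.float64)
    idx = np.frombuffer(bases.encode(), dtype=np.uint8)
    for base, channel in BASE_INDEX.items():
        mat[channel, idx == ord(base)] = 1.0
    return mat


def one_hot_decode(mat: np.ndarray) -> str:
    mat = np.asarray(mat)
    if mat.shape[0] != 4:
        raise ValueError("expected a 4 x L matrix")
    empty = mat.sum(axis=0) == 0
    chars = np.array(list(ALPHABET))[mat.argmax(axis=0)]
    chars[empty] = "N"
    return "".join(chars)


def encode_batch(seqs: TypingSequence[Sequence], length: int | None = None) -> np.ndarray:
    """Stack one-hot encodings into (N, 4, L), length-equalizing if needed."""
    if length is None:
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("sequences differ in length; pass an explicit length")
        length = lengths.pop()
    if not seqs:
        return np.zeros((0, 4, length))
    return np.stack([one_hot_encode(equalize_length(s, length)) for s in seqs])


def reverse_complement(bases: str) -> str:
    return bases.translate(COMPLEMENT)[::-1]


def equalize_length(seq: Sequence, length: int) -> Sequence:
    """Center-crop or symmetrically N-pad to exactly ``length`` bp.

    Attention requires a constant pooled length d across a batch, hence a
    constant input L; padding with N keeps the extra columns all-zero
    after encoding.
    """
    bases = seq.bases
    if len(bases) == length:
        return seq
    if len(bases) > length:
        start = (len(bases) - length) // 2
        return Sequence(seq.id, bases[start:start + length])
    pad = length - len(bases)
    left = pad // 2
    return Sequence(seq.id, "N" * left + bases + "N" * (pad - left))


def read_label_table(path) -> pd.DataFrame:
    """Read a headered TSV with an ``id`` column and one column per task."""
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise ValueError(f"{path}: label table must have an 'id' column")
    return df.set_index("id")


def write_label_table(ids: TypingSequence[str], labels: np.ndarray, path,
                      task_names: TypingSequence[str] | None = None) -> None:
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[:, None]
    if task_names is None:
        task_names = [f"task{i}" for i in range(labels.shape[1])] \
            if labels.shape[1] > 1 else ["label"]
    df = pd.DataFrame(labels.astype(int), columns=list(task_names))
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def read_bed_intervals(bed_path, genome_fasta) -> list[Sequence]:
    """Extract sequences for BED6 intervals (0-based half-open).

    Minus-strand intervals are reverse-complemented before use.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), sequence_always_upper=True)
    out = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{bed_path}:{lineno}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 else "+"
            bases = str(genome[chrom][start:end])
            if strand == "-":
                bases = reverse_complement(bases)
            out.append(Sequence(name, bases))
    return out


def split_dataset(ds: LabeledDataset,
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0) -> LabeledDataset:
    """Assign train/val/test tags by a seeded shuffle.

    Fractions follow the 80/10/10 convention by default and must sum to 1.
    Returns ``ds`` with its ``split`` array filled in (in place).
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must be >= 0 and sum to 1, got {fractions}")
    n = len(ds)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    tags = np.empty(n, dtype=object)
    tags[order[:n_train]] = "train"
    tags[order[n_train:n_train + n_val]] = "val"
    tags[order[n_train + n_val:]] = "test"
    ds.split = tags
    return ds
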