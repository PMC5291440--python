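"""FASTA input/output and one-hot encoding of TSS-anchored sequence windows.

Sequences are fixed-length DNA windows anchored at a transcription start
site (TSS).  Coordinates are 1-based and inclusive; the TSS-relative
coordinate of 1-based position ``p`` is ``p - tss_index`` (so position 201
in a 251-nt window with ``tss_index=201`` is 0).

One-hot encoding uses column order A, T, G, C.  ``N`` encodes as the
all-zero row, so an ambiguous base contributes nothing to any filter
dot product.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import DataError

ALPHABET = "ATGC"
VALID_BASES = frozenset("ATGCN")

PROMOTER = 1
NONPROMOTER = 0

_LABEL_NAMES = {PROMOTER: "promoter", NONPROMOTER: "nonpromoter"}
_LABEL_VALUES = {
    "promoter": PROMOTER,
    "nonpromoter": NONPROMOTER,
    "non-promoter": NONPROMOTER,
}

_BASE_TO_COL = {b: i for i, b in enumerate(ALPHABET)}


@dataclass(frozen=True)
class SequenceRecord:
    """A fixed-length DNA window with optional label and TSS anchoring.

    Parameters
    ----------
    id
        Record identifier (FASTA header word).
    sequence
        Uppercase DNA over ``{A, C, G, T, N}``.
    label
        Optional binary class: 1 = promoter, 0 = non-promoter.
    tss_index
        Optional 1-based position of the TSS within the window
        (201 for 251-nt eukaryotic windows spanning -200..+50,
        61 for 81-nt bacterial windows spanning -60..+20).
    """

    id: str
    sequence: str
    label: int | None = None
    tss_index: int | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) == 0:
            raise DataError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise DataError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(alphabet is A, C, G, T, N)"
            )
        if self.label is not None and self.label not in (PROMOTER, NONPROMOTER):
            raise DataError(f"record {self.id!r}: label must be 0 or 1")
        if self.tss_index is not None and not (1 <= self.tss_index <= len(seq)):
            raise DataError(
                f"record {self.id!r}: tss_index {self.tss_index} outside 1..{len(seq)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_label(self, label: int | None) -> "SequenceRecord":
        return replace(self, label=label)

    def tss_relative(self, position: int) -> int:
        """TSS-relative coordinate of a 1-based window position."""
        if self.tss_index is None:
            raise DataError(f"record {self.id!r}: no tss_index set")
        return position - self.tss_index


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; order is preserved; labels are left unset
    (labels come from which file a record was read from, or a manifest —
    never from headers).  An empty file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    with open(path) as handle:
        first = None
        for line in handle:
            if line.strip():
                first = line
                break
        if first is None:
            return []
        if not first.lstrip().startswith(">"):
            raise DataError(
                f"{path}: not FASTA — first non-blank line does not start "
                f"with '>': {first.strip()[:40]!r}"
            )
    for entry in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=entry.id, sequence=str(entry.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped multi-record FASTA."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def read_label_manifest(path: str | Path) -> dict[str, int]:
    """Read a two-column (id, label) manifest; labels are 'promoter'/'nonpromoter'."""
    labels: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            rec_id, name = parts
            if name.lower() not in _LABEL_VALUES:
                raise DataError(
                    f"{path}:{lineno}: unknown label {name!r} "
                    "(expected 'promoter' or 'nonpromoter')"
                )
            labels[rec_id] = _LABEL_VALUES[name.lower()]
    return labels


def write_label_manifest(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("# record_id\tlabel\n")
        for rec in records:
            if rec.label is None:
                raise DataError(f"record {rec.id!r} has no label to write")
            handle.write(f"{rec.id}\t{_LABEL_NAMES[rec.label]}\n")


def apply_labels(records: Sequence[SequenceRecord], labels: dict[str, int]) -> list[SequenceRecord]:
    """Attach manifest labels to records; every record must be covered."""
    out = []
    for rec in records:
        if rec.id not in labels:
            raise DataError(f"record {rec.id!r} missing from label manifest")
        out.append(rec.with_label(labels[rec.id]))
    return out


def encode_one_hot(record: SequenceRecord | str) -> np.ndarray:
    """Encode a sequence as an n x 4 one-hot matrix, columns A, T, G, C.

    A -> (1,0,0,0), T -> (0,1,0,0), G -> (0,0,1,0), C -> (0,0,0,1);
    N -> (0,0,0,0).
    """
    seq = record.sequence if isinstance(record, SequenceRecord) else record.upper()
    n = len(seq)
    mat = np.zeros((n, 4), dtype=np.float64)
    for i, base in enumerate(seq):
        if base == "N":
            continue
        try:
            mat[i, _BASE_TO_COL[base]] = 1.0
        except KeyError:
            raise DataError(f"invalid base {base!r} at position {i + 1}") from None
    return mat


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`encode_one_hot`; all-zero rows decode to ``N``."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise DataError(f"one-hot matrix must be n x 4, got shape {matrix.shape}")
    if not np.isin(matrix, (0.0, 1.0)).all():
        raise DataError("one-hot matrix entries must be 0 or 1")
    sums = matrix.sum(axis=1)
    bad = np.nonzero(~np.isin(sums, (0.0, 1.0)))[0]
    if bad.size:
        raise DataError(f"one-hot row {bad[0] + 1} sums to {sums[bad[0]]:g}, expected 0 or 1")
    out = []
    for row in matrix:
        if row.sum() == 0:
            out.append("N")
        else:
            out.append(ALPHABET[int(np.argmax(row))])
    return "".join(out)


def encode_batch(records: Sequence[SequenceRecord]) -> np.ndarray:
    """Stack equal-length records into a (batch, length, 4) array."""
    if not records:
        raise DataError("cannot encode an empty batch")
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise DataError(f"records have mixed lengths {sorted(lengths)}")
    return np.stack([encode_one_hot(r) for r in records])
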