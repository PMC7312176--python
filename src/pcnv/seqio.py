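"""Readers and writers: FASTA in; vector tables, PHYLIP matrices, labels.

FASTA parsing goes through Biopython's ``SeqIO``; gzip-compressed input is
detected by the ``.gz`` extension or the gzip magic bytes.  Numeric output
uses ``repr``-round-trip formatting so a written vector table reads back
bit-exactly.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np
from Bio import SeqIO

from .core import PCNVector, SequenceRecord

__all__ = [
    "Dataset",
    "read_fasta",
    "read_labels",
    "write_fasta",
    "write_labels",
    "write_vectors",
    "read_vectors",
    "write_distmat",
]

PathLike = Union[str, Path]

_GZIP_MAGIC = b"\x1f\x8b"


@dataclass
class Dataset:
    """An ordered collection of sequence records plus optional class labels."""

    records: list[SequenceRecord]
    labels: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate record ids: {sorted(dupes)}")
        if self.labels is not None:
            missing = set(self.labels) - set(ids)
            if missing:
                raise ValueError(
                    f"labels refer to ids absent from the records: {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def _open_text(path: PathLike) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if path.suffix == ".gz" or magic == _GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def read_fasta(source: Union[PathLike, IO[str]], strict: bool = False) -> Dataset:
    """Parse a (possibly gzipped) multi-FASTA file into a Dataset.

    The record id is the first whitespace-delimited token of the header.
    ``strict=True`` rejects any character outside {A, C, G, T}.
    """
    if hasattr(source, "read"):
        handle: IO[str] = source  # type: ignore[assignment]
        name = getattr(source, "name", "<stream>")
        close = False
    else:
        handle = _open_text(source)
        name = str(source)
        close = True
    try:
        records = []
        seen: set[str] = set()
        dupes: list[str] = []
        for rec in SeqIO.parse(handle, "fasta"):
            if not rec.seq:
                raise ValueError(f"{name}: record {rec.id!r} has an empty sequence")
            if rec.id in seen:
                dupes.append(rec.id)
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, str(rec.seq), strict=strict))
        if dupes:
            raise ValueError(f"{name}: duplicate record ids: {sorted(set(dupes))}")
        if not records:
            raise ValueError(f"{name}: no FASTA records found")
        return Dataset(records)
    finally:
        if close:
            handle.close()


def write_fasta(dataset: Dataset, path: PathLike, width: int = 70) -> None:
    with open(path, "wt", encoding="ascii") as fh:
        for rec in dataset.records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_labels(path: PathLike) -> dict[str, str]:
    """Parse a two-column (tab or comma) id→label table.

    A first line whose second field is non-numeric and whose id never
    reappears is still treated as data — only an exact ``id,label`` /
    ``id<TAB>label`` header is skipped.
    """
    labels: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            sep = "\t" if "\t" in line else ","
            fields = [f.strip() for f in line.split(sep)]
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(fields)}"
                )
            rid, label = fields
            if lineno == 1 and (rid.lower(), label.lower()) == ("id", "label"):
                continue
            if rid in labels:
                raise ValueError(f"{path}: line {lineno}: duplicate id {rid!r}")
            labels[rid] = label
    if not labels:
        raise ValueError(f"{path}: no label rows found")
    return labels


def write_labels(labels: dict[str, str], path: PathLike) -> None:
    with open(path, "wt", encoding="ascii") as fh:
        for rid, label in labels.items():
            fh.write(f"{rid}\t{label}\n")


def write_vectors(vectors: Iterable[PCNVector], path: PathLike, sep: str = "\t") -> None:
    """Write PCNVectors as a delimited table: id, N, then the 18 components.

    Floats are written with ``repr`` so reading the table back reproduces
    the values bit-exactly.
    """
    from .core import COMPONENT_NAMES

    vectors = list(vectors)
    if not vectors:
        raise ValueError("no vectors to write")
    with open(path, "wt", encoding="ascii") as fh:
        fh.write(sep.join(("id", "N") + COMPONENT_NAMES) + "\n")
        for v in vectors:
            row = [v.source_id, str(v.source_length)]
            row += [repr(c) for c in v.components]
            fh.write(sep.join(row) + "\n")


def read_vectors(path: PathLike, sep: str = "\t") -> list[PCNVector]:
    """Read a table written by :func:`write_vectors`."""
    from .core import COMPONENT_NAMES

    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        if tuple(header) != ("id", "N") + COMPONENT_NAMES:
            raise ValueError(f"{path}: unexpected vector-table header: {header}")
        out = []
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(sep)
            if len(fields) != 20:
                raise ValueError(f"{path}: expected 20 columns, got {len(fields)}")
            out.append(
                PCNVector(
                    components=tuple(float(x) for x in fields[2:]),
                    source_id=fields[0],
                    source_length=int(fields[1]),
                )
            )
    if not out:
        raise ValueError(f"{path}: no vector rows found")
    return out


def write_distmat(
    labels: list[str],
    d: np.ndarray,
    path: PathLike,
    strict_phylip: bool = False,
) -> None:
    """Write a PHYLIP square distance matrix.

    By default labels are written in full (relaxed dialect).  With
    ``strict_phylip`` labels are padded/truncated to the classic 10
    characters.
    """
    d = np.asarray(d, dtype=np.float64)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError(f"matrix shape {d.shape} does not match {n} labels")
    with open(path, "wt", encoding="ascii") as fh:
        fh.write(f"{n}\n")
        for i, label in enumerate(labels):
            name = f"{label[:10]:<10}" if strict_phylip else label
            row = "  ".join(repr(float(x)) for x in d[i])
            fh.write(f"{name}  {row}\n")
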