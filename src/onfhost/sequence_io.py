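"""FASTA ingestion, normalization, and sequence perturbation.

One FASTA file is one genome (a complete genome or a multi-contig draft
assembly project). Contigs are kept separate so that k-mer counting never
creates artificial junction words. All letters outside {A, C, G, T} are
normalized to N at read time; N positions are later excluded from counting.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO


class InputFormatError(ValueError):
    """Raised when a sequence file cannot be parsed into a usable record."""


_VALID = set("ACGTN")
# anything not ACGT (after uppercasing) becomes N
_NORMALIZE = str.maketrans(
    {c: ("N" if c not in "ACGT" else c) for c in map(chr, range(256))}
)


def normalize_sequence(seq: str) -> str:
    """Uppercase and map every non-ACGT character (IUPAC codes etc.) to N."""
    return seq.upper().translate(_NORMALIZE)


@dataclass
class SequenceRecord:
    """A genome (or genome project): an id plus an ordered list of contigs."""

    id: str
    contigs: list[str]
    headers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise InputFormatError(f"record {self.id!r} has no contigs")
        for c in self.contigs:
            if not c:
                raise InputFormatError(f"record {self.id!r} has a zero-length contig")
            if not set(c) <= _VALID:
                bad = sorted(set(c) - _VALID)
                raise InputFormatError(
                    f"record {self.id!r} contains invalid characters {bad}; "
                    "run normalize_sequence first"
                )
        if not self.headers:
            self.headers = [f"{self.id}_contig{i}" for i in range(len(self.contigs))]

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_genome(path: str | Path, id: str | None = None) -> SequenceRecord:
    """Read one FASTA file (optionally gzipped) into a SequenceRecord.

    Parameters
    ----------
    path
        FASTA file; multi-record files become multi-contig records.
    id
        Record identifier; defaults to the file stem (without .fa/.gz).

    Raises
    ------
    InputFormatError
        If the file is empty, not FASTA, or contains a zero-length record.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    stem = path.name
    for suffix in (".gz", ".fasta", ".fa", ".fna"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    record_id = id if id is not None else stem

    contigs: list[str] = []
    headers: list[str] = []
    with _open_text(path) as handle:
        first = handle.read(1)
        if first != ">":
            raise InputFormatError(f"not a FASTA file (no '>' header): {path}")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            seq = normalize_sequence(str(rec.seq))
            if not seq:
                raise InputFormatError(f"zero-length record {rec.id!r} in {path}")
            contigs.append(seq)
            headers.append(rec.description)
    if not contigs:
        raise InputFormatError(f"no FASTA records in {path}")
    return SequenceRecord(id=record_id, contigs=contigs, headers=headers)


def write_genome(record: SequenceRecord, path: str | Path, width: int = 70) -> None:
    """Write a SequenceRecord as plain multi-record FASTA."""
    path = Path(path)
    with open(path, "wt") as fh:
        for header, contig in zip(record.headers, record.contigs):
            fh.write(f">{header}\n")
            for i in range(0, len(contig), width):
                fh.write(contig[i : i + width] + "\n")


def subsample_fragment(
    record: SequenceRecord, length: int, seed: int
) -> SequenceRecord:
    """Extract one random contiguous fragment of the given length.

    The fragment never spans contig boundaries. The source contig is chosen
    with probability proportional to its number of valid start positions, so
    every window across the whole project is equally likely.
    """
    if length < 1:
        raise ValueError(f"fragment length must be >= 1, got {length}")
    windows = np.array([max(0, len(c) - length + 1) for c in record.contigs])
    total = int(windows.sum())
    if total == 0:
        raise ValueError(
            f"no contig of {record.id!r} is >= {length} nt "
            f"(longest is {max(len(c) for c in record.contigs)} nt)"
        )
    rng = np.random.default_rng(seed)
    flat = int(rng.integers(total))  # uniform over all windows
    ci = int(np.searchsorted(np.cumsum(windows), flat, side="right"))
    start = flat - int(np.concatenate([[0], np.cumsum(windows)])[ci])
    fragment = record.contigs[ci][start : start + length]
    return SequenceRecord(
        id=f"{record.id}|frag{length}",
        contigs=[fragment],
        headers=[f"{record.headers[ci]} fragment:{start}-{start + length}"],
    )


_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def mutate(record: SequenceRecord, rate: float, seed: int) -> SequenceRecord:
    """Apply i.i.d. substitution errors at the given per-position rate.

    Each non-N position is substituted with probability ``rate``; a
    substituted base becomes one of the three other bases uniformly.
    N positions are untouched. Deterministic for a fixed seed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"substitution rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    new_contigs = []
    for contig in record.contigs:
        arr = np.frombuffer(contig.encode("ascii"), dtype=np.uint8).copy()
        codes = _BASE_CODE[arr]
        hit = (rng.random(arr.size) < rate) & (codes != 255)
        # code + 1 + U{0,1,2} mod 4 is uniform over the three other bases
        shift = rng.integers(1, 4, size=arr.size).astype(np.uint8)
        new_codes = (codes[hit] + shift[hit]) % 4
        arr[hit] = _CODE_BASE[new_codes]
        new_contigs.append(arr.tobytes().decode("ascii"))
    return SequenceRecord(
        id=record.id, contigs=new_contigs, headers=list(record.headers)
    )
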