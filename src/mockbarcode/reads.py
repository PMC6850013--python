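"""Lightweight read containers with FASTQ round-trip support."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Read", "ReadSet"]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """A single read: identifier, sequence and per-base Phred quality values."""

    id: str
    seq: str
    qual: list[int]
    #: set by the trimmer so re-trimming is a no-op; not serialized to FASTQ
    trimmed: bool = False

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def source_bin(self) -> str | None:
        """Ground-truth label embedded in the read id (``...|bin=<id>``)."""
        for part in self.id.split("|"):
            if part.startswith("bin="):
                return part[4:]
        return None


@dataclass
class ReadSet:
    """An ordered collection of reads plus provenance metadata."""

    reads: list[Read] = field(default_factory=list)
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __getitem__(self, i: int) -> Read:
        return self.reads[i]

    def write_fastq(self, path: str | Path) -> Path:
        """Write the set as Phred+33 FASTQ; returns the path written."""
        path = Path(path)
        records = (
            SeqRecord(
                Seq(r.seq),
                id=r.id,
                description="",
                letter_annotations={"phred_quality": list(r.qual)},
            )
            for r in self.reads
        )
        try:
            with open(path, "w") as handle:
                SeqIO.write(records, handle, "fastq")
        except OSError as exc:
            raise OSError(f"failed to write FASTQ {path}: {exc}") from exc
        return path

    @classmethod
    def from_fastq(cls, path: str | Path, name: str = "") -> "ReadSet":
        path = Path(path)
        try:
            records = list(SeqIO.parse(str(path), "fastq"))
        except OSError as exc:
            raise OSError(f"failed to read FASTQ {path}: {exc}") from exc
        reads = [
            Read(rec.id, str(rec.seq).upper(),
                 list(rec.letter_annotations["phred_quality"]))
            for rec in records
        ]
        return cls(reads=reads, name=name or path.stem)
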