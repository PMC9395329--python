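"""Sequence containers and file I/O.

Reads and genomes travel as plain Python objects; FASTA/FASTQ round-trips go
through Biopython so the files interoperate with standard tooling. Synthetic
reads carry their provenance (true source genome) in the FASTQ description as
``src=<label>`` so downstream recovery tests can audit every pipeline stage.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PHRED_OFFSET = 33


@dataclass(frozen=True)
class Read:
    """A single shotgun read with phred+33 qualities and optional provenance."""

    id: str
    seq: str
    qual: str
    source: str | None = None  # true origin when simulated: sgb id, "host", "junk_*"

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def quals(self) -> list[int]:
        return [ord(c) - PHRED_OFFSET for c in self.qual]

    def trimmed(self, start: int, end: int) -> "Read":
        return replace(self, seq=self.seq[start:end], qual=self.qual[start:end])


@dataclass
class ReadSet:
    """A sample's reads, ordered."""

    sample_id: str
    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __getitem__(self, i):
        return self.reads[i]

    def subset(self, indices: Iterable[int]) -> "ReadSet":
        return ReadSet(self.sample_id, [self.reads[i] for i in indices])

    def source_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.reads:
            key = r.source if r.source is not None else "unknown"
            counts[key] = counts.get(key, 0) + 1
        return counts


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(
            Seq(r.seq),
            id=r.id,
            description=f"src={r.source}" if r.source is not None else "",
        )
        rec.letter_annotations["phred_quality"] = r.quals
        records.append(rec)
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path: str | Path, sample_id: str | None = None) -> ReadSet:
    sample_id = sample_id or Path(path).name.split(".")[0]
    reads = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            source = None
            for token in rec.description.split():
                if token.startswith("src="):
                    source = token[4:]
            qual = "".join(
                chr(q + PHRED_OFFSET) for q in rec.letter_annotations["phred_quality"]
            )
            reads.append(Read(rec.id, str(rec.seq), qual, source))
    return ReadSet(sample_id, reads)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
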