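"""Read QC, host-read removal, and fixed-depth subsampling.

The QC stage drops adapter-bearing reads, trims low-quality read edges
inward, and drops reads that end up short or low-quality overall; the host
screen removes reads whose k-mer content matches the host (dog) genome,
either with the built-in k-mer screen or from an externally produced SAM of
reads-vs-host alignments; subsampling fixes the analysis depth (10 million
reads by default) so samples are comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._kmers import canonical_kmers, seq_to_codes
from .io import Read, ReadSet

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    min_mean_quality: float = 20.0
    edge_quality_threshold: int = 20
    min_length_after_trim: int = 50
    adapter_sequences: list[str] = field(default_factory=list)
    subsample_depth: int = 10_000_000  # study default: 10 million reads
    host_kmer_length: int = 31
    host_match_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_mean_quality < 0 or self.edge_quality_threshold < 0:
            raise ValueError("quality thresholds must be non-negative")
        if self.subsample_depth <= 0:
            raise ValueError("subsample_depth must be positive")


@dataclass
class Disposition:
    """Per-read QC outcome: kept (possibly trimmed) or why it was dropped."""

    read_id: str
    outcome: str  # kept | adapter | low_quality | too_short
    trimmed_to: int | None = None


def _trim_edges(quals: list[int], threshold: int) -> tuple[int, int]:
    """Half-open [start, end) of the read after inward edge trimming.

    Scans from each end and stops at the first base whose quality reaches the
    threshold; may return an empty interval.
    """
    start, end = 0, len(quals)
    while start < end and quals[start] < threshold:
        start += 1
    while end > start and quals[end - 1] < threshold:
        end -= 1
    return start, end


def quality_filter(reads: ReadSet, qc: QCConfig) -> tuple[ReadSet, list[Disposition]]:
    """Adapter removal, edge trimming, and quality/length filtering.

    Order of survivors is preserved; the returned dispositions cover every
    input read so counts are conserved. The operation is idempotent: a second
    pass leaves its own output unchanged.
    """
    kept: list[Read] = []
    log: list[Disposition] = []
    for read in reads:
        if len(read.seq) != len(read.qual):  # defensive; Read enforces on build
            raise ValueError(f"malformed record {read.id!r}: seq/qual length mismatch")
        if any(adapter in read.seq for adapter in qc.adapter_sequences):
            log.append(Disposition(read.id, "adapter"))
            continue
        quals = read.quals
        start, end = _trim_edges(quals, qc.edge_quality_threshold)
        if end - start < qc.min_length_after_trim:
            log.append(Disposition(read.id, "too_short"))
            continue
        trimmed = quals[start:end]
        if sum(trimmed) / len(trimmed) < qc.min_mean_quality:
            log.append(Disposition(read.id, "low_quality"))
            continue
        kept.append(read.trimmed(start, end))
        log.append(Disposition(read.id, "kept", trimmed_to=end - start))
    return ReadSet(reads.sample_id, kept), log


class HostKmerScreen:
    """Strand-canonical k-mer set of the host genome, reusable across samples."""

    def __init__(self, host_genome: str, k: int = 31):
        self.k = k
        kmers, valid = canonical_kmers(seq_to_codes(host_genome), k)
        self._kmers = np.unique(kmers[valid])

    def match_fraction(self, read_seq: str) -> float:
        kmers, valid = canonical_kmers(seq_to_codes(read_seq), self.k)
        kmers = kmers[valid]
        if len(kmers) == 0:
            return 0.0
        if len(self._kmers) == 0:
            return 0.0
        idx = np.searchsorted(self._kmers, kmers)
        idx[idx == len(self._kmers)] = 0
        return float(np.mean(self._kmers[idx] == kmers))


def host_screen(
    reads: ReadSet,
    host_genome: str | None = None,
    qc: QCConfig | None = None,
    sam_path: str | Path | None = None,
    screen: HostKmerScreen | None = None,
) -> ReadSet:
    """Remove reads matching the host genome.

    Built-in mode drops a read when at least ``host_match_fraction`` of its
    canonical k-mers occur in the host genome's k-mer set. External mode
    (``sam_path``) drops every read with an aligned record in a
    reads-vs-host SAM produced by a full aligner.
    """
    if sam_path is not None:
        import pysam

        aligned: set[str] = set()
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
            for rec in sam:
                if not rec.is_unmapped:
                    aligned.add(rec.query_name)
        survivors = [r for r in reads if r.id not in aligned]
        return ReadSet(reads.sample_id, survivors)
    if host_genome is None and screen is None:
        raise ValueError("provide a host genome or a reads-vs-host SAM")
    qc = qc or QCConfig()
    screen = screen or HostKmerScreen(host_genome, qc.host_kmer_length)
    survivors = [
        r for r in reads if screen.match_fraction(r.seq) < qc.host_match_fraction
    ]
    return ReadSet(reads.sample_id, survivors)


def subsample_reads(reads: ReadSet, depth: int, seed: int = 0) -> ReadSet:
    """Uniform without-replacement subsample to a fixed depth.

    Keeps all reads (with a warning) when the sample is already below depth;
    survivors keep their original order.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if len(reads) <= depth:
        if len(reads) < depth:
            msg = (
                f"{reads.sample_id}: only {len(reads)} reads available "
                f"(requested depth {depth}); keeping all"
            )
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
        return ReadSet(reads.sample_id, list(reads.reads))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=depth, replace=False))
    return reads.subset(idx.tolist())
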