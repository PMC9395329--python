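"""Relative-abundance estimation from unique best-hit read mapping.

The estimator follows four steps:

1. **Unique best mapping** — each read is scored against every position of
   every SGB representative on both strands (ungapped, full containment,
   unit mismatch penalty). A read counts only when its best score is achieved
   at exactly one (SGB, position, strand); ties make it ambiguous and reads
   over the mismatch budget are unmapped.
2. **Window counts** — unique reads are tallied into the fixed-width genome
   windows by their leftmost base.
3. **Dense mean cover** — per SGB, window counts become per-base densities
   (count x read length / window length) and the cover is a two-sided
   trimmed mean of the sorted densities (default 25% per side), i.e. the
   coverage of the densely covered core of the genome, normalized by genome
   size through the per-base scale.
4. **Relative abundance** — an SGB "exists" in a sample when its cover is
   positive, enough unique reads support it, and its coverage is not
   concentrated in a tiny fraction of windows; abundances are covers divided
   by the summed covers of existing SGBs, then capped at 1e-4.

The built-in mapper is seed-and-extend with non-overlapping exact k-mer
seeds and a per-read mismatch budget of (#seeds - 1): by pigeonhole, every
alignment within budget contains a clean seed, so the mapper returns exactly
the assignments of an exhaustive all-position scan. A SAM of reads-vs-catalog
alignments from an external aligner is accepted as an alternative input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._kmers import encode_kmers, revcomp_codes, seq_to_codes
from .catalog import SGBCatalog, WindowIndex
from .io import ReadSet

DEFAULT_CAP = 1e-4


@dataclass
class ReadMapping:
    read_id: str
    status: str  # unique | ambiguous | unmapped
    sgb_id: str | None = None
    position: int | None = None  # 0-based leftmost base
    strand: str | None = None  # + | -
    mismatches: int | None = None
    window: int | None = None


@dataclass
class MappingResult:
    mappings: list[ReadMapping] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.mappings)

    def __iter__(self):
        return iter(self.mappings)

    def status_counts(self) -> dict[str, int]:
        out = {"unique": 0, "ambiguous": 0, "unmapped": 0}
        for m in self.mappings:
            out[m.status] += 1
        return out


@dataclass
class CoverProfile:
    """Per-SGB per-window unique-read counts for one sample."""

    sample_id: str
    window_counts: dict[str, np.ndarray]
    unique_reads: dict[str, int]

    @property
    def n_unique_reads(self) -> int:
        return sum(self.unique_reads.values())


@dataclass
class AbundanceVector:
    sample_id: str
    raw_cover: pd.Series
    exists: pd.Series
    relative: pd.Series
    cap_level: float = DEFAULT_CAP
    cap_mode: str | None = None  # None (uncapped) | floor | zero


class CatalogIndex:
    """Seed index of the catalog: every k-mer position of every SGB genome."""

    def __init__(self, catalog: SGBCatalog, seed_length: int = 31):
        self.seed_length = seed_length
        self.sgb_ids = catalog.sgb_ids
        self.genomes = {
            r.sgb_id: np.frombuffer(r.sequence.encode(), dtype=np.uint8)
            for r in catalog
        }
        self._codes = {g: seq_to_codes(catalog[g].sequence) for g in self.sgb_ids}
        index: dict[int, list[tuple[int, int]]] = {}
        for gi, g in enumerate(self.sgb_ids):
            kmers, valid = encode_kmers(self._codes[g], seed_length)
            for pos in np.flatnonzero(valid):
                index.setdefault(int(kmers[pos]), []).append((gi, int(pos)))
        self._index = index

    def seed_hits(self, kmer: int) -> list[tuple[int, int]]:
        return self._index.get(kmer, [])


_COMP_ASCII = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCATGCA"):
    _COMP_ASCII[_a] = _b


def _revcomp_bytes(arr: np.ndarray) -> np.ndarray:
    return _COMP_ASCII[arr[::-1]]


def mismatch_budget(read_length: int, seed_length: int) -> int:
    """Maximum mismatches at which an alignment is still accepted.

    Set to (number of disjoint seed windows - 1) so every acceptable
    alignment is guaranteed to contain an error-free seed.
    """
    return max(read_length // seed_length - 1, 0)


def unique_best_map(
    reads: ReadSet,
    index: CatalogIndex,
    window_index: WindowIndex,
) -> MappingResult:
    """Assign each read to its unique best location, or call it ambiguous/unmapped.

    Equivalent to exhaustively scoring the read at every position of every
    genome on both strands with a unit mismatch penalty and accepting only a
    unique best within the mismatch budget.
    """
    k = index.seed_length
    genomes = [index.genomes[g] for g in index.sgb_ids]
    out: list[ReadMapping] = []
    for read in reads:
        L = len(read.seq)
        n_seeds = L // k
        budget = mismatch_budget(L, k)
        if n_seeds == 0:
            out.append(ReadMapping(read.id, "unmapped"))
            continue
        fwd = np.frombuffer(read.seq.encode(), dtype=np.uint8)
        rev = _revcomp_bytes(fwd)
        candidates: set[tuple[int, int, str]] = set()
        for strand, arr in (("+", fwd), ("-", rev)):
            codes = seq_to_codes(bytes(arr))
            kmers, valid = encode_kmers(codes, k)
            for s in range(n_seeds):
                off = s * k
                if not valid[off]:
                    continue
                for gi, pos in index.seed_hits(int(kmers[off])):
                    start = pos - off
                    if start >= 0 and start + L <= len(genomes[gi]):
                        candidates.add((gi, start, strand))
        best_mm = budget + 1
        best: list[tuple[int, int, str]] = []
        for gi, start, strand in sorted(candidates):
            arr = fwd if strand == "+" else rev
            mm = int(np.count_nonzero(genomes[gi][start : start + L] != arr))
            if mm < best_mm:
                best_mm, best = mm, [(gi, start, strand)]
            elif mm == best_mm:
                best.append((gi, start, strand))
        if best_mm > budget or not best:
            out.append(ReadMapping(read.id, "unmapped"))
        elif len(best) > 1:
            out.append(ReadMapping(read.id, "ambiguous"))
        else:
            gi, start, strand = best[0]
            sgb = index.sgb_ids[gi]
            out.append(
                ReadMapping(
                    read.id,
                    "unique",
                    sgb_id=sgb,
                    position=start,
                    strand=strand,
                    mismatches=best_mm,
                    window=window_index.window_of(sgb, start),
                )
            )
    return MappingResult(out)


def unique_best_map_from_sam(
    sam_path: str | Path,
    catalog: SGBCatalog,
    window_index: WindowIndex,
) -> MappingResult:
    """Unique-best assignment from an external aligner's reads-vs-catalog SAM.

    The best alignment score per read is taken from the AS tag when present
    (falling back to -NM, then to MAPQ); a read is unique iff exactly one
    record attains the best score.
    """
    import pysam

    known = set(catalog.sgb_ids)
    per_read: dict[str, list[tuple[float, str, int]]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.query_name not in per_read:
                per_read[rec.query_name] = []
                order.append(rec.query_name)
            if rec.is_unmapped:
                continue
            if rec.reference_name not in known:
                raise ValueError(f"SAM references unknown contig {rec.reference_name!r}")
            if rec.has_tag("AS"):
                score = float(rec.get_tag("AS"))
            elif rec.has_tag("NM"):
                score = -float(rec.get_tag("NM"))
            else:
                score = float(rec.mapping_quality)
            per_read[rec.query_name].append(
                (score, rec.reference_name, rec.reference_start)
            )
    out = []
    for rid in order:
        hits = per_read[rid]
        if not hits:
            out.append(ReadMapping(rid, "unmapped"))
            continue
        top = max(s for s, _, _ in hits)
        best = [(g, p) for s, g, p in hits if s == top]
        if len(best) > 1:
            out.append(ReadMapping(rid, "ambiguous"))
        else:
            g, p = best[0]
            out.append(
                ReadMapping(
                    rid, "unique", sgb_id=g, position=p, strand=None,
                    window=window_index.window_of(g, p),
                )
            )
    return MappingResult(out)


def count_windows(
    result: MappingResult, index: WindowIndex, sample_id: str = "sample"
) -> CoverProfile:
    """Tally unique reads into genome windows; ambiguous/unmapped count nowhere."""
    counts = {g: np.zeros(len(w), dtype=np.int64) for g, w in index.windows.items()}
    uniq = {g: 0 for g in index.windows}
    for m in result:
        if m.status == "unique":
            counts[m.sgb_id][m.window] += 1
            uniq[m.sgb_id] += 1
    return CoverProfile(sample_id, counts, uniq)


def dense_mean_cover(
    profile: CoverProfile,
    index: WindowIndex,
    read_length_bp: int,
    trim_fraction: float = 0.25,
) -> pd.Series:
    """Per-SGB dense mean cover: trimmed mean of per-window per-base density.

    Window counts convert to densities count x read_length / window_length;
    the lowest and highest ``trim_fraction`` of windows are discarded and the
    remaining central windows averaged. ``trim_fraction=0`` is the plain mean
    density. Genome-size normalization is inherent: densities are per-base.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    covers = {}
    for g, counts in profile.window_counts.items():
        if len(counts) == 0:
            raise ValueError(f"{g}: empty window vector")
        if counts.sum() == 0:
            covers[g] = 0.0
            continue
        density = counts * read_length_bp / index.window_lengths(g)
        density = np.sort(density)
        t = int(np.floor(trim_fraction * len(density)))
        central = density[t : len(density) - t]
        covers[g] = float(central.mean())
    return pd.Series(covers)


@dataclass
class ExistenceConfig:
    """When is an SGB concluded to exist in a sample?"""

    min_reads: int = 10
    min_nonzero_window_fraction: float = 0.05


def estimate_relative_abundance(
    covers: pd.Series,
    profile: CoverProfile,
    existence: ExistenceConfig | None = None,
    sample_id: str | None = None,
) -> AbundanceVector:
    """Normalize covers over the SGBs concluded to exist in the sample.

    p_g = c_g / sum of covers of existing SGBs; non-existing SGBs get 0.
    """
    existence = existence or ExistenceConfig()
    sample_id = sample_id or profile.sample_id
    exists = {}
    for g in covers.index:
        counts = profile.window_counts[g]
        nnz_frac = float(np.count_nonzero(counts)) / len(counts)
        exists[g] = (
            covers[g] > 0
            and profile.unique_reads[g] >= existence.min_reads
            and nnz_frac >= existence.min_nonzero_window_fraction
        )
    exists = pd.Series(exists)
    total = covers[exists].sum()
    if total == 0:
        warnings.warn(f"{sample_id}: no SGB passes the existence criterion", stacklevel=2)
        rel = pd.Series(0.0, index=covers.index)
    else:
        rel = covers.where(exists, 0.0) / total
    return AbundanceVector(sample_id, covers, exists, rel)


def apply_detection_cap(
    v: AbundanceVector, cap: float = DEFAULT_CAP, mode: str = "floor"
) -> AbundanceVector:
    """Cap relative abundances at the detection level.

    ``floor`` raises every entry below the cap (zeros included) to the cap —
    the vector no longer sums to 1, which is recorded in the cap state and is
    intended for log-scale downstream use. ``zero`` zeroes entries below the
    cap and renormalizes the survivors to sum 1.
    """
    if not 0 < cap < 1:
        raise ValueError("cap must lie in (0, 1)")
    rel = v.relative.copy()
    if mode == "floor":
        rel[rel < cap] = cap
    elif mode == "zero":
        rel[rel < cap] = 0.0
        total = rel.sum()
        if total > 0:
            rel = rel / total
    else:
        raise ValueError(f"unknown cap mode {mode!r}")
    return AbundanceVector(v.sample_id, v.raw_cover, v.exists, rel, cap, mode)


def estimate_sample(
    reads: ReadSet,
    catalog: SGBCatalog,
    window_index: WindowIndex,
    catalog_index: CatalogIndex | None = None,
    read_length_bp: int | None = None,
    trim_fraction: float = 0.25,
    existence: ExistenceConfig | None = None,
    sam_path: str | Path | None = None,
) -> tuple[AbundanceVector, MappingResult, CoverProfile]:
    """Convenience wrapper: map -> count -> cover -> relative abundance (uncapped)."""
    if sam_path is not None:
        result = unique_best_map_from_sam(sam_path, catalog, window_index)
    else:
        catalog_index = catalog_index or CatalogIndex(catalog)
        result = unique_best_map(reads, catalog_index, window_index)
    if read_length_bp is None:
        read_length_bp = int(round(np.mean([len(r) for r in reads]))) if len(reads) else 0
    profile = count_windows(result, window_index, reads.sample_id)
    covers = dense_mean_cover(profile, window_index, read_length_bp, trim_fraction)
    vec = estimate_relative_abundance(covers, profile, existence)
    return vec, result, profile


def abundance_table(vectors: list[AbundanceVector]) -> pd.DataFrame:
    """Stack per-sample relative abundances into a samples x SGBs table."""
    return pd.DataFrame({v.sample_id: v.relative for v in vectors}).T
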