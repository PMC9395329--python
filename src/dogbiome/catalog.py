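"""Reference catalog of species-level genome bins (SGBs).

An SGB is a species-granularity cluster of assembled genomes represented by a
single assembly; abundance estimation runs against these representatives.
Two pieces of study logic live here:

* the inclusion rule — an SGB enters the analysis catalog iff it is the only
  SGB of its genus or is supported by at least 5 assemblies (guarding against
  artificially split near-identical bins);
* the fixed-width window tiling of each representative genome, over which
  unique-read coverage is later counted.

Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_fasta, write_fasta

TAXONOMY_COLUMNS = [
    "sgb_id",
    "species",
    "genus",
    "family",
    "phylum",
    "n_assemblies",
    "butyrate_flag",
    "acetate_flag",
]


@dataclass
class SGBRecord:
    """One species-level genome bin: representative sequence plus taxonomy."""

    sgb_id: str
    species: str
    genus: str
    family: str
    phylum: str
    n_assemblies: int
    sequence: str
    butyrate_flag: bool = False
    acetate_flag: bool = False

    @property
    def genome_length_bp(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if self.n_assemblies < 1:
            raise ValueError(f"{self.sgb_id}: n_assemblies must be >= 1")


@dataclass
class SGBCatalog:
    records: list[SGBRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, sgb_id: str) -> SGBRecord:
        for rec in self.records:
            if rec.sgb_id == sgb_id:
                return rec
        raise KeyError(sgb_id)

    @property
    def sgb_ids(self) -> list[str]:
        return [rec.sgb_id for rec in self.records]

    def taxonomy_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sgb_id": r.sgb_id,
                "species": r.species,
                "genus": r.genus,
                "family": r.family,
                "phylum": r.phylum,
                "n_assemblies": r.n_assemblies,
                "butyrate_flag": int(r.butyrate_flag),
                "acetate_flag": int(r.acetate_flag),
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=TAXONOMY_COLUMNS)

    def butyrate_producers(self) -> list[str]:
        return [r.species for r in self.records if r.butyrate_flag]

    def acetate_producers(self) -> list[str]:
        return [r.species for r in self.records if r.acetate_flag]

    # ---- persistence -----------------------------------------------------

    def to_files(self, fasta_path: str | Path, taxonomy_path: str | Path) -> None:
        write_fasta({r.sgb_id: r.sequence for r in self.records}, fasta_path)
        self.taxonomy_frame().to_csv(taxonomy_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, fasta_path: str | Path, taxonomy_path: str | Path) -> "SGBCatalog":
        seqs = read_fasta(fasta_path)
        tax = pd.read_csv(taxonomy_path, sep="\t", dtype={"sgb_id": str})
        records = []
        for row in tax.itertuples(index=False):
            if row.sgb_id not in seqs:
                raise ValueError(f"taxonomy row {row.sgb_id} missing from FASTA")
            records.append(
                SGBRecord(
                    sgb_id=row.sgb_id,
                    species=row.species,
                    genus=row.genus,
                    family=row.family,
                    phylum=row.phylum,
                    n_assemblies=int(row.n_assemblies),
                    sequence=seqs[row.sgb_id],
                    butyrate_flag=bool(row.butyrate_flag),
                    acetate_flag=bool(row.acetate_flag),
                )
            )
        return cls(records)


def filter_sgbs(records: list[SGBRecord] | SGBCatalog, min_assemblies: int = 5) -> tuple[SGBCatalog, SGBCatalog]:
    """Apply the catalog inclusion rule.

    An SGB is kept iff it is the sole SGB of its genus, or it is supported by
    at least ``min_assemblies`` assemblies. Returns (kept, dropped) catalogs.
    """
    if isinstance(records, SGBCatalog):
        records = records.records
    genus_counts: dict[str, int] = {}
    for rec in records:
        if not rec.genus or (isinstance(rec.genus, float) and np.isnan(rec.genus)):
            raise ValueError(f"{rec.sgb_id}: missing genus label")
        genus_counts[rec.genus] = genus_counts.get(rec.genus, 0) + 1
    kept, dropped = [], []
    for rec in records:
        if genus_counts[rec.genus] == 1 or rec.n_assemblies >= min_assemblies:
            kept.append(rec)
        else:
            dropped.append(rec)
    return SGBCatalog(kept), SGBCatalog(dropped)


@dataclass
class WindowIndex:
    """Fixed-width tiling of each SGB genome into half-open windows.

    Every window has length ``window_length_bp`` except possibly the terminal
    one, which covers the genome remainder.
    """

    window_length_bp: int
    windows: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def n_windows(self, sgb_id: str) -> int:
        return len(self.windows[sgb_id])

    def window_lengths(self, sgb_id: str) -> np.ndarray:
        return np.array([end - start for start, end in self.windows[sgb_id]])

    def window_of(self, sgb_id: str, position: int) -> int:
        """Window ordinal containing a 0-based genome position."""
        n = len(self.windows[sgb_id])
        ordinal = position // self.window_length_bp
        if not 0 <= ordinal < n:
            raise ValueError(f"position {position} outside {sgb_id}")
        return ordinal


def build_window_index(catalog: SGBCatalog, window_length_bp: int = 1000) -> WindowIndex:
    """Tile every catalog genome into windows of ``window_length_bp``."""
    if window_length_bp <= 0:
        raise ValueError("window_length_bp must be positive")
    import warnings

    windows: dict[str, list[tuple[int, int]]] = {}
    for rec in catalog:
        length = rec.genome_length_bp
        if length < window_length_bp:
            warnings.warn(
                f"{rec.sgb_id}: genome ({length} bp) shorter than one window "
                f"({window_length_bp} bp); using a single window",
                stacklevel=2,
            )
        starts = list(range(0, length, window_length_bp))
        windows[rec.sgb_id] = [(s, min(s + window_length_bp, length)) for s in starts]
    return WindowIndex(window_length_bp, windows)
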