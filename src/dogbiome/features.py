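"""Microbiome features derived from the relative-abundance table.

Per sample: richness (species detected at or above the cap), Shannon
diversity in nats, summed abundance of butyrate- and acetate-producing
species (literature-curated lists; 24 butyrate producers in the reference
study), the Firmicutes/Bacteroidetes ratio, taxon aggregates at phylum /
family / genus rank, and Bray-Curtis beta diversity with classical PCoA.

The assembled feature table mirrors the study's layout: a 13-column summary
block (richness, Shannon, the two producer sums, F/B ratio, and eight
configurable taxon aggregates) followed by all species abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .abundance import DEFAULT_CAP

logger = logging.getLogger(__name__)

SUMMARY_CORE = ["richness", "shannon", "butyrate_producers", "acetate_producers", "fb_ratio"]
_BACTEROIDETES_SPELLINGS = ("Bacteroidetes", "Bacteroides")


def compute_alpha_diversity(abundances: pd.Series, cap: float = DEFAULT_CAP) -> tuple[int, float]:
    """Richness S and Shannon diversity H (nats) of one sample.

    Detection is defined against the raw (pre-floor) abundances: a species is
    present when its abundance is at least the cap. H is computed on the
    detected species renormalized to sum 1; S=0 yields H=0 by convention.
    """
    detected = abundances[abundances >= cap]
    s = int(len(detected))
    if s == 0:
        return 0, 0.0
    q = detected.to_numpy(dtype=float)
    q = q / q.sum()
    h = float(-(q * np.log(q)).sum())
    return s, h


def aggregate_taxa(table: pd.DataFrame, taxonomy: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Sum species abundances into rank-level aggregates (samples x labels)."""
    tax = taxonomy.set_index("sgb_id")
    missing = [g for g in table.columns if g not in tax.index]
    if missing:
        raise ValueError(f"SGBs missing from taxonomy: {missing[:5]}")
    labels = tax.loc[list(table.columns), rank]
    bad = labels[labels.isna() | (labels == "")]
    if len(bad):
        raise ValueError(f"missing {rank} label for SGB {bad.index[0]!r}")
    return table.T.groupby(labels).sum().T


def scfa_producer_sum(abundances: pd.Series, producers: list[str], taxonomy: pd.DataFrame) -> float:
    """Summed abundance of a producer species list (e.g. butyrate producers)."""
    species_to_sgb = taxonomy.set_index("species")["sgb_id"]
    unknown = [s for s in producers if s not in species_to_sgb.index]
    if unknown:
        raise ValueError(f"producer species absent from catalog: {unknown[:5]}")
    sgbs = species_to_sgb.loc[producers]
    return float(abundances.loc[sgbs].sum())


def fb_ratio(abundances: pd.Series, taxonomy: pd.DataFrame) -> float:
    """Firmicutes / Bacteroidetes summed-abundance ratio.

    The Bacteroidetes phylum label is taken verbatim from the taxonomy table
    (either the "Bacteroidetes" or the "Bacteroides" spelling). A zero
    denominator yields NaN (missing), not infinity.
    """
    phyla = aggregate_taxa(abundances.to_frame().T, taxonomy, "phylum").iloc[0]
    firm = float(phyla.get("Firmicutes", 0.0))
    bact = 0.0
    for label in _BACTEROIDETES_SPELLINGS:
        if label in phyla.index:
            bact = float(phyla[label])
            break
    if bact == 0:
        logger.info("zero Bacteroidetes abundance; F/B ratio reported as missing")
        return float("nan")
    return firm / bact


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, samples x samples."""
    d = squareform(pdist(table.to_numpy(dtype=float), metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # all-zero sample pairs
    return pd.DataFrame(d, index=table.index, columns=table.index)


def beta_diversity_pcoa(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical PCoA of Bray-Curtis dissimilarities.

    Double-centers -BC^2/2, eigendecomposes, and returns sample coordinates
    on the positive-eigenvalue axes (scaled by sqrt of eigenvalue) plus the
    full eigenvalue spectrum in decreasing order; negative eigenvalues are
    reported but carry no axis.
    """
    if len(table) < 3:
        raise ValueError("PCoA needs at least 3 samples")
    d = bray_curtis_matrix(table).to_numpy()
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > 1e-12
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=table.index, columns=cols), eigvals


@dataclass
class FeatureManifest:
    """Names the 13-column summary block of the feature table.

    Aggregate entries use the form ``rank:label`` (e.g. ``phylum:Firmicutes``);
    the default pads the five core features with phylum then family
    aggregates, in sorted label order, up to eight aggregates.
    """

    columns: list[str] = field(default_factory=list)

    @classmethod
    def default(cls, taxonomy: pd.DataFrame, n_aggregates: int = 8) -> "FeatureManifest":
        aggs: list[str] = []
        for rank in ("phylum", "family"):
            for label in sorted(taxonomy[rank].unique()):
                entry = f"{rank}:{label}"
                if entry not in aggs:
                    aggs.append(entry)
                if len(aggs) == n_aggregates:
                    return cls(SUMMARY_CORE + aggs)
        return cls(SUMMARY_CORE + aggs)


def assemble_feature_table(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    butyrate_producers: list[str] | None = None,
    acetate_producers: list[str] | None = None,
    manifest: FeatureManifest | None = None,
    cap: float = DEFAULT_CAP,
    cap_species: bool = True,
) -> pd.DataFrame:
    """Build the per-sample feature table: summary block + species columns.

    ``table`` holds raw (pre-cap) relative abundances, samples x SGBs.
    Richness/diversity are computed against the raw abundances; species
    columns are floor-capped at ``cap`` when ``cap_species`` (the default),
    matching the study's capped abundances entering association/prediction.
    Column order is deterministic: manifest order, then species in catalog
    order.
    """
    if butyrate_producers is None:
        butyrate_producers = taxonomy.loc[taxonomy["butyrate_flag"] == 1, "species"].tolist()
    if acetate_producers is None:
        acetate_producers = taxonomy.loc[taxonomy["acetate_flag"] == 1, "species"].tolist()
    manifest = manifest or FeatureManifest.default(taxonomy)

    aggregates: dict[str, pd.DataFrame] = {}
    rows = {}
    for name in manifest.columns:
        if name in SUMMARY_CORE:
            continue
        if ":" not in name:
            raise ValueError(f"manifest names uncomputed feature {name!r}")
        rank, label = name.split(":", 1)
        if rank not in ("phylum", "family", "genus"):
            raise ValueError(f"manifest names uncomputed feature {name!r}")
        if rank not in aggregates:
            aggregates[rank] = aggregate_taxa(table, taxonomy, rank)
        if label not in aggregates[rank].columns:
            raise ValueError(f"manifest aggregate {name!r} absent from taxonomy")

    for sample in table.index:
        v = table.loc[sample]
        s, h = compute_alpha_diversity(v, cap)
        row = {
            "richness": s,
            "shannon": h,
            "butyrate_producers": scfa_producer_sum(v, butyrate_producers, taxonomy),
            "acetate_producers": scfa_producer_sum(v, acetate_producers, taxonomy),
            "fb_ratio": fb_ratio(v, taxonomy),
        }
        for name in manifest.columns:
            if name in SUMMARY_CORE:
                continue
            rank, label = name.split(":", 1)
            row[name] = float(aggregates[rank].loc[sample, label])
        rows[sample] = row

    summary = pd.DataFrame.from_dict(rows, orient="index")[manifest.columns]
    species = table.copy()
    if cap_species:
        species = species.clip(lower=cap)
    species.columns = [f"species:{c}" for c in species.columns]
    return pd.concat([summary, species], axis=1)
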