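"""Synthetic community, read-set, and cohort generator.

Every downstream stage of the pipeline is validated against data produced
here, where the ground truth is known: reference genomes with taxonomy,
per-sample true relative-abundance profiles, shotgun reads carrying their
true origin as provenance, and a dog-cohort metadata table (demographics plus
eight behavior/performance scores on 1-5 scales) with optional planted
species-to-trait effects.

The generator emulates a working-dog stool shotgun-sequencing study: reads
are drawn from toy bacterial genomes in proportion to abundance x genome
length (so per-base coverage tracks abundance), contaminated with host-genome
reads and with junk reads (adapter-bearing or low-quality), and behavior
scores come from latent Gaussians discretized into five quintile bins so a
planted effect is expressible as a latent shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kmers import codes_to_seq
from .io import Read, ReadSet
from .catalog import SGBCatalog, SGBRecord

# Illumina TruSeq-style adapter; a fixed 33-mer so junk detection is exactly testable.
ADAPTER_33MER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

DEFAULT_TRAITS = (
    "obedience",
    "obedience_specificity",
    "motivation",
    "aggression",
    "cowardice",
    "sociability",
    "stress_level",
    "job_performance",
)

PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Fusobacteria", "Actinobacteria")

_GOOD_QUAL = 37
_JUNK_QUAL = 2


@dataclass
class CommunityConfig:
    """Parameters of the simulated community and sequencing run.

    Defaults describe the reference study condition used throughout the test
    suite: 30 species-level genome bins of 50 kb, 200,000 reads of 100 bp per
    sample at 0.5% base error, 10% host contamination and 5% junk reads, with
    true abundances drawn from a symmetric Dirichlet(0.5) (a realistic
    rank-abundance curve with rare taxa below the 1e-4 detection cap).
    """

    n_sgbs: int = 30
    genome_length_bp: int = 50_000
    n_reads: int = 200_000
    read_length_bp: int = 100
    base_error_rate: float = 0.005
    host_fraction: float = 0.1
    junk_fraction: float = 0.05
    abundance_prior: float | np.ndarray = 0.5
    host_genome_length_bp: int = 50_000
    n_butyrate: int = 24
    n_acetate: int = 12
    adapter: str = ADAPTER_33MER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.host_fraction + self.junk_fraction >= 1:
            raise ValueError("host_fraction + junk_fraction must be < 1")
        if not (0 <= self.host_fraction < 1 and 0 <= self.junk_fraction < 1):
            raise ValueError("fractions must lie in [0, 1)")
        for name in ("n_sgbs", "genome_length_bp", "n_reads", "read_length_bp",
                     "host_genome_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        alpha = np.asarray(self.abundance_prior, dtype=float)
        if np.any(alpha <= 0):
            raise ValueError("Dirichlet concentration parameters must be positive")

    def alpha_vector(self) -> np.ndarray:
        alpha = np.asarray(self.abundance_prior, dtype=float)
        if alpha.ndim == 0:
            return np.full(self.n_sgbs, float(alpha))
        if len(alpha) != self.n_sgbs:
            raise ValueError("abundance_prior length must equal n_sgbs")
        return alpha


@dataclass
class TruthProfile:
    """Ground-truth relative abundances of one sample over the catalog SGBs."""

    sample_id: str
    abundances: pd.Series  # indexed by sgb_id, sums to 1
    host_fraction: float
    seed: int

    def __post_init__(self) -> None:
        vals = self.abundances.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError("abundances must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {vals.sum():.12f})")


@dataclass
class EffectSpec:
    """A planted microbiome-behavior effect.

    Dogs whose ``trait_name`` score is at or above ``threshold`` ("high"
    group) have the listed SGBs' log-abundances shifted by
    ``effect_size`` latent standard deviations (sign per ``direction``)
    before renormalization.
    """

    trait_name: str
    affected_sgbs: list[str]
    effect_size: float
    direction: list[int] | int = 1
    threshold: int = 3

    def directions(self) -> list[int]:
        if isinstance(self.direction, int):
            return [self.direction] * len(self.affected_sgbs)
        if len(self.direction) != len(self.affected_sgbs):
            raise ValueError("direction list must match affected_sgbs")
        return list(self.direction)


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return codes_to_seq(rng.integers(0, 4, size=length, dtype=np.uint8))


def generate_reference_catalog(config: CommunityConfig) -> tuple[SGBCatalog, str]:
    """Random SGB catalog with taxonomy plus a distinct host genome.

    Phyla are drawn with Firmicutes/Bacteroidetes dominant (the dominant
    phyla in canine stool); the first two SGBs are pinned to those phyla so
    both always exist. Every species gets its own genus by default, so the
    whole catalog passes the inclusion rule unless the caller edits
    ``n_assemblies``/genus labels to exercise it.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sgbs
    phylum_weights = np.array([0.40, 0.30, 0.15, 0.10, 0.05])
    phyla = list(rng.choice(PHYLA, size=n, p=phylum_weights))
    if n >= 1:
        phyla[0] = "Firmicutes"
    if n >= 2:
        phyla[1] = "Bacteroidetes"
    n_but = min(config.n_butyrate, n)
    n_ace = min(config.n_acetate, n)
    butyrate_ids = set(rng.choice(n, size=n_but, replace=False).tolist())
    acetate_ids = set(rng.choice(n, size=n_ace, replace=False).tolist())
    records = []
    for i in range(n):
        phylum = phyla[i]
        family = f"{phylum}_fam{(i % 2) + 1}"
        records.append(
            SGBRecord(
                sgb_id=f"SGB_{i + 1:04d}",
                species=f"{phylum[:4]}_species_{i + 1:04d}",
                genus=f"Genus_{i + 1:04d}",
                family=family,
                phylum=phylum,
                n_assemblies=int(rng.integers(1, 31)),
                sequence=_random_genome(rng, config.genome_length_bp),
                butyrate_flag=i in butyrate_ids,
                acetate_flag=i in acetate_ids,
            )
        )
    host = _random_genome(rng, config.host_genome_length_bp)
    assert all(host != r.sequence for r in records)
    return SGBCatalog(records), host


def draw_truth_profile(
    config: CommunityConfig, sgb_ids: list[str], sample_id: str, seed: int
) -> TruthProfile:
    """Sample a true abundance profile from the configured Dirichlet prior."""
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(config.alpha_vector())
    return TruthProfile(sample_id, pd.Series(p, index=sgb_ids), config.host_fraction, seed)


def simulate_sample_reads(
    catalog: SGBCatalog,
    host_genome: str,
    truth: TruthProfile,
    config: CommunityConfig,
) -> ReadSet:
    """Draw one sample's shotgun reads from a known truth profile.

    Each read is, independently: a host read with probability
    ``host_fraction``; a junk read with probability ``junk_fraction`` (half
    adapter-bearing, half uniformly low-quality); otherwise a community read
    from an SGB chosen with probability proportional to abundance x genome
    length, at a uniform position and strand, with bases flipped independently
    at ``base_error_rate``. Provenance (true origin) is recorded per read.
    """
    ids = catalog.sgb_ids
    if list(truth.abundances.index) != ids:
        raise ValueError("truth profile is not defined over the catalog's SGBs")
    rng = np.random.default_rng(truth.seed)
    n, L = config.n_reads, config.read_length_bp
    err = config.base_error_rate

    u = rng.random(n)
    is_host = u < config.host_fraction
    is_junk = (~is_host) & (u < config.host_fraction + config.junk_fraction)
    is_comm = ~(is_host | is_junk)

    lengths = np.array([catalog[g].genome_length_bp for g in ids], dtype=float)
    weights = truth.abundances.to_numpy() * lengths
    total = weights.sum()
    probs = weights / total if total > 0 else None

    genome_codes = {
        g: np.frombuffer(catalog[g].sequence.encode(), dtype=np.uint8) for g in ids
    }
    host_codes = np.frombuffer(host_genome.encode(), dtype=np.uint8)

    source = np.empty(n, dtype=object)
    seq_bytes: list[bytes | None] = [None] * n
    qual = np.empty(n, dtype=object)
    good_qual = chr(_GOOD_QUAL + 33) * L
    junk_qual = chr(_JUNK_QUAL + 33) * L

    def _extract(codes: np.ndarray, idx: np.ndarray, label_fn) -> None:
        m = len(idx)
        if m == 0:
            return
        starts = rng.integers(0, len(codes) - L + 1, size=m)
        mat = codes[starts[:, None] + np.arange(L)]
        rc = rng.random(m) < 0.5
        # reverse-complement in ASCII space via a lookup table
        comp = np.zeros(256, dtype=np.uint8)
        for a, b in zip(b"ACGT", b"TGCA"):
            comp[a] = b
        mat[rc] = comp[mat[rc][:, ::-1]]
        if err > 0:
            flip = rng.random((m, L)) < err
            code_of = np.zeros(256, dtype=np.uint8)
            for k, b in enumerate(b"ACGT"):
                code_of[b] = k
            shift = rng.integers(1, 4, size=int(flip.sum()))
            codes2 = code_of[mat]
            codes2[flip] = (codes2[flip] + shift) % 4
            mat = np.frombuffer(b"ACGT", dtype=np.uint8)[codes2]
        for row, i in enumerate(idx):
            seq_bytes[i] = mat[row].tobytes()
            qual[i] = good_qual
            source[i] = label_fn(row)

    comm_idx = np.flatnonzero(is_comm)
    if len(comm_idx) > 0:
        if probs is None:
            raise ValueError("all-zero truth profile with community reads requested")
        choice = rng.choice(len(ids), size=len(comm_idx), p=probs)
        for g_i in np.unique(choice):
            sel = comm_idx[choice == g_i]
            _extract(genome_codes[ids[g_i]], sel, lambda _row, g=ids[g_i]: g)

    _extract(host_codes, np.flatnonzero(is_host), lambda _row: "host")

    junk_idx = np.flatnonzero(is_junk)
    if len(junk_idx) > 0:
        kind = rng.random(len(junk_idx)) < 0.5
        base = rng.integers(0, 4, size=(len(junk_idx), L), dtype=np.uint8)
        mat = np.frombuffer(b"ACGT", dtype=np.uint8)[base]
        adapter_bytes = config.adapter.encode()
        for row, i in enumerate(junk_idx):
            if kind[row]:
                pos = int(rng.integers(0, L - len(adapter_bytes) + 1))
                s = bytearray(mat[row].tobytes())
                s[pos : pos + len(adapter_bytes)] = adapter_bytes
                seq_bytes[i] = bytes(s)
                qual[i] = good_qual
                source[i] = "junk_adapter"
            else:
                seq_bytes[i] = mat[row].tobytes()
                qual[i] = junk_qual
                source[i] = "junk_lowq"

    reads = [
        Read(
            id=f"{truth.sample_id}:r{i:07d}",
            seq=seq_bytes[i].decode("ascii"),
            qual=qual[i],
            source=source[i],
        )
        for i in range(n)
    ]
    return ReadSet(truth.sample_id, reads)


# --------------------------------------------------------------------------
# Cohort generation


@dataclass
class CohortConfig:
    """Demographic marginals of the simulated working-dog cohort.

    Category frequencies follow the published demographics of an Israeli
    working-dog program (Malinois-dominant breeds, tracking/breeding-dominant
    jobs, ~12% puppies, ~11% sterilized, ~10% recurrent GI issues).
    """

    puppy_fraction: float = 0.118
    female_fraction: float = 0.534
    sterilized_fraction: float = 0.113
    gi_issue_fraction: float = 0.103
    special_diet_fraction: float = 0.067
    breeds: tuple = (
        ("Malinois", 0.435),
        ("Belgian/Dutch Shepherd", 0.185),
        ("GSD", 0.129),
        ("Corgi", 0.097),
        ("Labrador", 0.064),
        ("Other", 0.090),
    )
    jobs: tuple = (
        ("tracking", 0.295),
        ("breeding", 0.188),
        ("scent_detection", 0.147),
        ("bite_work", 0.131),
        ("SAR", 0.123),
        ("failed", 0.116),
    )
    latent_sigma: float = 1.0  # SD of per-dog log-abundance noise around the community mean


def generate_cohort(
    n_dogs: int,
    sgb_ids: list[str] | SGBCatalog,
    trait_definitions: tuple[str, ...] = DEFAULT_TRAITS,
    effects: list[EffectSpec] | tuple = (),
    seed: int = 0,
    config: CommunityConfig | None = None,
    cohort: CohortConfig | None = None,
) -> tuple[pd.DataFrame, list[TruthProfile]]:
    """Simulate cohort metadata and per-dog true abundance profiles.

    Behavior scores discretize latent standard Gaussians into five quintile
    bins (1-5). Each dog's true log-abundance is the community mean profile
    (one Dirichlet draw per cohort) plus N(0, latent_sigma) per-SGB noise;
    an :class:`EffectSpec` shifts the affected SGBs by ``effect_size`` latent
    SDs in dogs whose trait score reaches its threshold, before softmax
    renormalization. With no effects, abundances are independent of all
    metadata by construction.
    """
    if n_dogs < 10:
        raise ValueError("n_dogs must be >= 10")
    if isinstance(sgb_ids, SGBCatalog):
        sgb_ids = sgb_ids.sgb_ids
    config = config or CommunityConfig(n_sgbs=len(sgb_ids))
    if config.n_sgbs != len(sgb_ids):
        raise ValueError("config.n_sgbs must match the number of SGB ids")
    cohort = cohort or CohortConfig()
    for spec in effects:
        if spec.trait_name not in trait_definitions:
            raise ValueError(f"unknown trait {spec.trait_name!r}")
        for g in spec.affected_sgbs:
            if g not in sgb_ids:
                raise ValueError(f"effect on absent SGB {g!r}")

    rng = np.random.default_rng(seed)
    dog_ids = [f"dog_{i + 1:04d}" for i in range(n_dogs)]

    is_puppy = rng.random(n_dogs) < cohort.puppy_fraction
    age = np.where(
        is_puppy,
        rng.uniform(0.5, 1.0, size=n_dogs),
        np.clip(rng.lognormal(math.log(3.5), 0.55, size=n_dogs), 1.0, 12.0),
    ).round(1)
    meta = pd.DataFrame(
        {
            "dog_id": dog_ids,
            "age": age,
            "sex": np.where(rng.random(n_dogs) < cohort.female_fraction, "F", "M"),
            "breed": rng.choice(
                [b for b, _ in cohort.breeds],
                size=n_dogs,
                p=_norm([p for _, p in cohort.breeds]),
            ),
            "job": rng.choice(
                [j for j, _ in cohort.jobs],
                size=n_dogs,
                p=_norm([p for _, p in cohort.jobs]),
            ),
            "sterilized": rng.random(n_dogs) < cohort.sterilized_fraction,
            "bcs": np.clip(np.round(rng.normal(5.0, 0.6, size=n_dogs) * 2) / 2, 1, 9),
            "gi_issues": rng.random(n_dogs) < cohort.gi_issue_fraction,
            "special_diet": rng.random(n_dogs) < cohort.special_diet_fraction,
        }
    ).set_index("dog_id")

    # 1-5 behavior scores: latent N(0,1) cut at quintiles
    from scipy.stats import norm as _normdist

    cuts = _normdist.ppf([0.2, 0.4, 0.6, 0.8])
    for trait in trait_definitions:
        z = rng.standard_normal(n_dogs)
        meta[trait] = (np.searchsorted(cuts, z) + 1).astype(int)

    # truths
    sigma = cohort.latent_sigma
    community_mean = rng.dirichlet(config.alpha_vector())
    log_mean = np.log(community_mean + 1e-300)
    truths: list[TruthProfile] = []
    col = {g: k for k, g in enumerate(sgb_ids)}
    for i, dog in enumerate(dog_ids):
        logp = log_mean + sigma * rng.standard_normal(len(sgb_ids))
        for spec in effects:
            if meta.loc[dog, spec.trait_name] >= spec.threshold:
                for g, d in zip(spec.affected_sgbs, spec.directions()):
                    logp[col[g]] += d * spec.effect_size * sigma
        p = np.exp(logp - logp.max())
        p /= p.sum()
        truths.append(
            TruthProfile(
                sample_id=dog,
                abundances=pd.Series(p, index=list(sgb_ids)),
                host_fraction=config.host_fraction,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return meta, truths


def _norm(p: list[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    return arr / arr.sum()


def truth_table(truths: list[TruthProfile]) -> pd.DataFrame:
    """Stack per-dog truth profiles into a samples x SGBs abundance table."""
    return pd.DataFrame({t.sample_id: t.abundances for t in truths}).T
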