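"""End-to-end orchestration: one config, one seed, one output directory.

A run executes simulate (optional) -> QC -> host screen -> subsample ->
abundance -> features -> association scans -> trait prediction, writing every
intermediate table as TSV plus a manifest recording the full configuration,
the seed, and a checksum of every artifact. Re-running an identical config
and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import abundance as ab
from . import association as assoc
from . import features as feat
from . import prediction as pred
from . import read_processing as rp
from . import synthetic as syn
from .catalog import SGBCatalog, build_window_index
from .io import read_fasta, read_fastq, write_fasta, write_fastq

logger = logging.getLogger(__name__)

DEFAULT_CATEGORICAL_PHENOTYPES = list(syn.DEFAULT_TRAITS) + [
    "sex", "sterilized", "gi_issues", "special_diet", "breed", "job",
]
DEFAULT_NUMERIC_PHENOTYPES = ["age", "bcs"]


@dataclass
class RunConfig:
    seed: int = 0
    synthetic: dict | None = None  # n_dogs, effects, CommunityConfig overrides
    inputs: dict | None = None  # reads_dir, catalog_fasta, taxonomy_tsv, host_fasta, metadata_tsv
    qc: dict = field(default_factory=dict)
    subsample_depth: int | None = None
    window_length_bp: int = 1000
    trim_fraction: float = 0.25
    cap: float = ab.DEFAULT_CAP
    cap_mode: str = "floor"
    existence: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)  # method, level, phenotypes
    prediction: dict = field(default_factory=dict)  # k, traits, grouping
    write_reads: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if cfg.inputs:
            for key, value in cfg.inputs.items():
                if key != "reads_dir" and value and not Path(value).exists():
                    raise FileNotFoundError(f"inputs.{key}: {value} does not exist")
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = "sample_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def run_full_analysis(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline; returns the output directory.

    Stage errors abort the run naming the stage; association/prediction are
    skipped with a warning when no metadata is available.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc_cfg = rp.QCConfig(**config.qc) if config.qc else rp.QCConfig(
        adapter_sequences=[syn.ADAPTER_33MER]
    )
    if "adapter_sequences" not in config.qc:
        qc_cfg.adapter_sequences = [syn.ADAPTER_33MER]
    depth = config.subsample_depth or qc_cfg.subsample_depth

    # ---- stage: inputs / simulate ---------------------------------------
    metadata = None
    truths = None
    if config.synthetic is not None:
        params = dict(config.synthetic)
        n_dogs = params.pop("n_dogs", 20)
        effect_specs = [
            syn.EffectSpec(
                trait_name=e["trait"],
                affected_sgbs=list(e["sgbs"]),
                effect_size=float(e.get("effect_size", 0.0)),
                direction=e.get("direction", 1),
                threshold=int(e.get("threshold", 3)),
            )
            for e in params.pop("effects", [])
        ]
        comm = syn.CommunityConfig(seed=config.seed, **params)
        catalog, host_genome = syn.generate_reference_catalog(comm)
        metadata, truths = syn.generate_cohort(
            n_dogs, catalog, effects=effect_specs, seed=config.seed, config=comm
        )
        read_sets = (
            syn.simulate_sample_reads(catalog, host_genome, t, comm) for t in truths
        )
        read_length = comm.read_length_bp
        catalog.to_files(out / "catalog.fasta", out / "taxonomy.tsv")
        write_fasta({"host": host_genome}, out / "host.fasta")
        metadata.to_csv(out / "metadata.tsv", sep="\t", index_label="dog_id")
        _write_tsv(syn.truth_table(truths), out / "truth_profiles.tsv")
    elif config.inputs is not None:
        inp = config.inputs
        catalog = SGBCatalog.from_files(inp["catalog_fasta"], inp["taxonomy_tsv"])
        host_genome = next(iter(read_fasta(inp["host_fasta"]).values())) if inp.get("host_fasta") else None
        fastqs = sorted(Path(inp["reads_dir"]).glob("*.fastq*"))
        if not fastqs:
            raise RuntimeError("stage inputs: no FASTQ files in reads_dir")
        read_sets = (read_fastq(p) for p in fastqs)
        read_length = None
        if inp.get("metadata_tsv"):
            metadata = pd.read_csv(inp["metadata_tsv"], sep="\t", index_col=0)
    else:
        raise RuntimeError("stage inputs: config needs either 'synthetic' or 'inputs'")

    # ---- stages: qc -> host screen -> subsample -> abundance ------------
    window_index = build_window_index(catalog, config.window_length_bp)
    catalog_index = ab.CatalogIndex(catalog)
    screen = (
        rp.HostKmerScreen(host_genome, qc_cfg.host_kmer_length)
        if host_genome is not None
        else None
    )
    existence = ab.ExistenceConfig(**config.existence)
    vectors, capped_vectors, qc_rows = [], [], []
    for reads in read_sets:
        if config.write_reads:
            write_fastq(reads, out / f"reads_{reads.sample_id}.fastq")
        filtered, dispositions = rp.quality_filter(reads, qc_cfg)
        if screen is not None:
            screened = rp.host_screen(filtered, qc=qc_cfg, screen=screen)
        else:
            screened = filtered
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # shortfall below depth is routine here
            final = rp.subsample_reads(screened, depth, seed=config.seed)
        vec, mapping, _profile = ab.estimate_sample(
            final, catalog, window_index, catalog_index,
            read_length_bp=read_length, trim_fraction=config.trim_fraction,
            existence=existence,
        )
        vectors.append(vec)
        capped_vectors.append(ab.apply_detection_cap(vec, config.cap, config.cap_mode))
        status = mapping.status_counts()
        qc_rows.append(
            {
                "sample_id": reads.sample_id,
                "n_input": len(reads),
                "n_after_qc": len(filtered),
                "n_after_host_screen": len(screened),
                "n_analyzed": len(final),
                **{f"n_{k}": v for k, v in status.items()},
            }
        )
    pd.DataFrame(qc_rows).set_index("sample_id").to_csv(
        out / "read_accounting.tsv", sep="\t"
    )
    raw_table = ab.abundance_table(vectors)
    capped_table = ab.abundance_table(capped_vectors)
    _write_tsv(raw_table, out / "abundance_raw.tsv")
    _write_tsv(capped_table, out / "abundance_capped.tsv")

    # ---- stage: features ------------------------------------------------
    taxonomy = catalog.taxonomy_frame()
    feature_table = feat.assemble_feature_table(raw_table, taxonomy, cap=config.cap)
    _write_tsv(feature_table, out / "features.tsv")
    if len(feature_table) >= 3:
        coords, eigvals = feat.beta_diversity_pcoa(raw_table)
        _write_tsv(coords, out / "pcoa_coordinates.tsv")
        pd.Series(eigvals, name="eigenvalue").to_csv(
            out / "pcoa_eigenvalues.tsv", sep="\t", index_label="axis"
        )

    # ---- stages: association + prediction -------------------------------
    if metadata is None:
        warnings.warn("no metadata: association and prediction stages skipped")
        logger.warning("no metadata: association and prediction stages skipped")
    else:
        method = config.association.get("method", "bh_fdr")
        level = config.association.get("level", 0.15)
        cat_phens = config.association.get(
            "phenotypes",
            [p for p in DEFAULT_CATEGORICAL_PHENOTYPES if p in metadata.columns],
        )
        num_phens = config.association.get(
            "numeric_phenotypes",
            [p for p in DEFAULT_NUMERIC_PHENOTYPES if p in metadata.columns],
        )
        all_records = []
        for phen in cat_phens:
            recs = assoc.rank_test_scan(feature_table, metadata, phen)
            if recs:
                all_records.extend(assoc.adjust_pvalues(recs, method, level))
        for phen in num_phens:
            recs = assoc.pearson_scan(feature_table, metadata, phen)
            if recs:
                all_records.extend(assoc.adjust_pvalues(recs, method, level))
        assoc.records_frame(all_records).to_csv(
            out / "associations.tsv", sep="\t", index=False, float_format="%.10g"
        )

        k = config.prediction.get("k", 3)
        traits = config.prediction.get(
            "traits",
            [t for t in syn.DEFAULT_TRAITS if t in metadata.columns]
            + (["gi_issues"] if "gi_issues" in metadata.columns else []),
        )
        grouping = config.prediction.get("grouping", "median")
        reports = []
        for trait in traits:
            try:
                report = pred.predict_trait(
                    feature_table, metadata, trait, k=k, seed=config.seed, rule=grouping
                )
            except ValueError as exc:
                logger.warning("prediction for %s skipped: %s", trait, exc)
                continue
            row = report.summary()
            row["threshold"] = report.rule.threshold if report.rule else None
            reports.append(row)
        pd.DataFrame(reports).to_csv(
            out / "predictions.tsv", sep="\t", index=False, float_format="%.10g"
        )

    # ---- manifest --------------------------------------------------------
    artifacts = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
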