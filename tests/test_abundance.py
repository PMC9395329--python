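"""Unique-best mapping, dense mean cover, and relative-abundance estimation."""

import numpy as np
import pandas as pd
import pytest

import dogbiome as db
from dogbiome.abundance import CoverProfile, mismatch_budget
from dogbiome.catalog import SGBRecord
from dogbiome.io import Read, ReadSet
from dogbiome._kmers import codes_to_seq


def _catalog(seqs: dict[str, str]) -> db.SGBCatalog:
    return db.SGBCatalog(
        [
            SGBRecord(g, f"sp_{g}", f"gen_{g}", "fam", "Firmicutes", 1, s)
            for g, s in seqs.items()
        ]
    )


def _reads(seqs: list[str]) -> ReadSet:
    return ReadSet("s", [Read(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)])


def _random_instance(rng, n_genomes=3, max_len=2000, n_reads=50, read_len=60):
    """A small mapping instance with true, erroneous, shared, and junk reads."""
    genomes = {}
    for gi in range(n_genomes):
        length = int(rng.integers(500, max_len + 1))
        genomes[f"G{gi}"] = codes_to_seq(rng.integers(0, 4, size=length, dtype=np.uint8))
    # plant a shared segment so some reads are genuinely ambiguous
    ids = list(genomes)
    seg = genomes[ids[0]][50 : 50 + 150]
    genomes[ids[1]] = genomes[ids[1]][:200] + seg + genomes[ids[1]][350:]
    comp = str.maketrans("ACGT", "TGCA")
    reads = []
    for i in range(n_reads):
        kind = rng.random()
        g = ids[int(rng.integers(0, n_genomes))]
        if kind < 0.7:  # genuine read, possibly with errors
            pos = int(rng.integers(0, len(genomes[g]) - read_len + 1))
            seq = list(genomes[g][pos : pos + read_len])
            for _ in range(int(rng.integers(0, 4))):
                j = int(rng.integers(0, read_len))
                seq[j] = "ACGT"[int(rng.integers(0, 4))]
            seq = "".join(seq)
            if rng.random() < 0.5:
                seq = seq.translate(comp)[::-1]
        elif kind < 0.85:  # read from the shared segment
            pos = int(rng.integers(0, len(seg) - read_len + 1))
            seq = seg[pos : pos + read_len]
        else:  # junk
            seq = codes_to_seq(rng.integers(0, 4, size=read_len, dtype=np.uint8))
        reads.append(seq)
    return genomes, reads


def map_with_package(genomes, read_seqs, window=500):
    catalog = _catalog(genomes)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wi = db.build_window_index(catalog, window)
    index = db.CatalogIndex(catalog)
    return db.unique_best_map(_reads(read_seqs), index, wi)


class TestUniqueBestMap:
    def test_matches_exhaustive_oracle_on_random_instances(self, oracle):
        rng = np.random.default_rng(123)
        for _ in range(30):
            genomes, read_seqs = _random_instance(rng)
            result = map_with_package(genomes, read_seqs)
            for seq, m in zip(read_seqs, result):
                status, sgb, pos, strand = oracle(seq, genomes)
                assert m.status == status, seq
                if status == "unique":
                    assert (m.sgb_id, m.position, m.strand) == (sgb, pos, strand)

    def test_verbatim_unique_read_assigned_to_its_position(self):
        rng = np.random.default_rng(0)
        g = codes_to_seq(rng.integers(0, 4, size=1000, dtype=np.uint8))
        result = map_with_package({"A": g}, [g[200:280]])
        m = result.mappings[0]
        assert (m.status, m.sgb_id, m.position, m.strand, m.mismatches) == (
            "unique", "A", 200, "+", 0,
        )

    def test_read_present_in_two_sgbs_is_ambiguous(self):
        rng = np.random.default_rng(1)
        g1 = codes_to_seq(rng.integers(0, 4, size=600, dtype=np.uint8))
        g2 = codes_to_seq(rng.integers(0, 4, size=600, dtype=np.uint8))
        shared = g1[100:180]
        g2 = g2[:300] + shared + g2[380:]
        result = map_with_package({"A": g1, "B": g2}, [shared])
        assert result.mappings[0].status == "ambiguous"

    def test_unrelated_read_is_unmapped(self):
        rng = np.random.default_rng(2)
        g = codes_to_seq(rng.integers(0, 4, size=1000, dtype=np.uint8))
        junk = codes_to_seq(rng.integers(0, 4, size=80, dtype=np.uint8))
        result = map_with_package({"A": g}, [junk])
        assert result.mappings[0].status == "unmapped"

    def test_status_conservation(self, small_sample, catalog_host):
        _, reads = small_sample
        catalog, _ = catalog_host
        wi = db.build_window_index(catalog, 1000)
        result = db.unique_best_map(reads, db.CatalogIndex(catalog), wi)
        counts = result.status_counts()
        assert sum(counts.values()) == len(reads)

    def test_mismatch_budget_formula(self):
        assert mismatch_budget(100, 31) == 2
        assert mismatch_budget(62, 31) == 1
        assert mismatch_budget(30, 31) == 0

    def test_window_ordinal_from_leftmost_base(self):
        rng = np.random.default_rng(3)
        g = codes_to_seq(rng.integers(0, 4, size=2000, dtype=np.uint8))
        result = map_with_package({"A": g}, [g[990:1070]], window=500)
        assert result.mappings[0].window == 1  # leftmost base 990 lies in [500, 1000)


class TestSamIngestion:
    def test_unique_and_ambiguous_from_alignment_scores(self, tmp_path):
        catalog = _catalog({"A": "A" * 600, "B": "C" * 600})
        wi = db.build_window_index(catalog, 500)
        sam = tmp_path / "aln.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:A\tLN:600\n@SQ\tSN:B\tLN:600\n"
            "r1\t0\tA\t11\t60\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII\tAS:i:20\n"
            "r2\t0\tA\t1\t60\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII\tAS:i:20\n"
            "r2\t256\tB\t1\t0\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII\tAS:i:20\n"
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII\n"
        )
        result = db.unique_best_map_from_sam(sam, catalog, wi)
        by_id = {m.read_id: m for m in result}
        assert by_id["r1"].status == "unique"
        assert by_id["r1"].position == 10  # SAM POS is 1-based
        assert by_id["r2"].status == "ambiguous"
        assert by_id["r3"].status == "unmapped"

    def test_unknown_contig_is_an_error(self, tmp_path):
        catalog = _catalog({"A": "A" * 600})
        wi = db.build_window_index(catalog, 500)
        sam = tmp_path / "aln.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:X\tLN:600\n"
            "r1\t0\tX\t11\t60\t10M\t*\t0\t0\tAAAAAAAAAA\tIIIIIIIIII\n"
        )
        with pytest.raises(ValueError, match="unknown contig"):
            db.unique_best_map_from_sam(sam, catalog, wi)


def _profile(counts, sgb="A", window=1000, genome_len=None):
    counts = np.asarray(counts)
    genome_len = genome_len or window * len(counts)
    cat = _catalog({sgb: "A" * genome_len})
    wi = db.build_window_index(cat, window)
    prof = CoverProfile("s", {sgb: counts}, {sgb: int(counts.sum())})
    return prof, wi


class TestDenseMeanCover:
    @pytest.mark.parametrize("trim", [0.0, 0.1, 0.25, 0.4])
    def test_uniform_counts_give_constant_cover(self, trim):
        prof, wi = _profile([5] * 10)
        cover = db.dense_mean_cover(prof, wi, read_length_bp=100, trim_fraction=trim)
        assert cover["A"] == pytest.approx(0.5)

    def test_worked_eight_window_example(self):
        # counts (0,0,0,0,10,10,10,10), trim 0.25 -> central densities (0,0,1,1) -> 0.5
        prof, wi = _profile([0, 0, 0, 0, 10, 10, 10, 10])
        cover = db.dense_mean_cover(prof, wi, read_length_bp=100, trim_fraction=0.25)
        assert cover["A"] == pytest.approx(0.5)

    def test_zero_trim_equals_plain_mean_density(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            counts = rng.integers(0, 50, size=int(rng.integers(1, 40)))
            if counts.sum() == 0:
                counts[0] = 1
            prof, wi = _profile(counts)
            cover = db.dense_mean_cover(prof, wi, read_length_bp=100, trim_fraction=0.0)
            assert cover["A"] == pytest.approx((counts * 100 / 1000).mean())

    def test_all_zero_counts_give_zero_cover(self):
        prof, wi = _profile([0, 0, 0, 0])
        cover = db.dense_mean_cover(prof, wi, read_length_bp=100)
        assert cover["A"] == 0.0

    def test_terminal_short_window_uses_its_own_length(self):
        prof, wi = _profile([5, 5], genome_len=1500)  # windows 1000 and 500 bp
        cover = db.dense_mean_cover(prof, wi, read_length_bp=100, trim_fraction=0.0)
        assert cover["A"] == pytest.approx((0.5 + 1.0) / 2)

    def test_empty_window_vector_is_an_error(self):
        prof = CoverProfile("s", {"A": np.array([], dtype=int)}, {"A": 0})
        wi = db.WindowIndex(1000, {"A": []})
        with pytest.raises(ValueError, match="empty"):
            db.dense_mean_cover(prof, wi, read_length_bp=100)

    def test_invalid_trim_rejected(self):
        prof, wi = _profile([1, 2])
        with pytest.raises(ValueError):
            db.dense_mean_cover(prof, wi, read_length_bp=100, trim_fraction=0.5)


def _vector(covers: dict, reads: dict, nnz: dict, n_windows=20):
    prof = CoverProfile(
        "s",
        {g: np.concatenate([np.ones(nnz[g], dtype=int), np.zeros(n_windows - nnz[g], dtype=int)])
         for g in covers},
        reads,
    )
    return db.estimate_relative_abundance(pd.Series(covers), prof)


class TestRelativeAbundance:
    def test_equal_covers_split_evenly(self):
        v = _vector({"A": 2.0, "B": 2.0}, {"A": 50, "B": 50}, {"A": 10, "B": 10})
        assert v.relative.tolist() == [0.5, 0.5]

    def test_nonexistent_sgb_excluded_from_normalization(self):
        v = _vector(
            {"A": 3.0, "B": 1.0, "C": 0.0},
            {"A": 50, "B": 50, "C": 0},
            {"A": 10, "B": 10, "C": 0},
        )
        assert v.relative.tolist() == [0.75, 0.25, 0.0]
        assert not v.exists["C"]

    def test_existence_needs_min_reads_and_window_spread(self):
        # plenty of cover but too few reads
        v = _vector({"A": 1.0, "B": 1.0}, {"A": 50, "B": 5}, {"A": 10, "B": 10})
        assert not v.exists["B"]
        # enough reads but concentrated in <5% of windows (0 of 20 nonzero would be
        # degenerate; use a 40-window genome with 1 nonzero = 2.5%)
        prof = CoverProfile(
            "s",
            {"A": np.concatenate([np.full(1, 40), np.zeros(39, dtype=int)])},
            {"A": 40},
        )
        with pytest.warns(UserWarning):
            v2 = db.estimate_relative_abundance(pd.Series({"A": 1.0}), prof)
        assert not v2.exists["A"]

    def test_relative_invariant_to_cover_rescaling(self):
        base = {"A": 3.0, "B": 1.5, "C": 0.5}
        reads = {g: 100 for g in base}
        nnz = {g: 15 for g in base}
        v1 = _vector(base, reads, nnz)
        v2 = _vector({g: 7.3 * c for g, c in base.items()}, reads, nnz)
        assert np.allclose(v1.relative, v2.relative)

    def test_no_existing_sgb_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning, match="existence"):
            v = _vector({"A": 0.0}, {"A": 0}, {"A": 0})
        assert v.relative.sum() == 0.0

    def test_recovery_from_deep_simulation(self, small_config, catalog_host):
        catalog, host = catalog_host
        truth = db.draw_truth_profile(small_config, catalog.sgb_ids, "s", seed=31)
        reads = db.simulate_sample_reads(catalog, host, truth, small_config)
        reads = db.host_screen(reads, host_genome=host)
        wi = db.build_window_index(catalog, 1000)
        vec, _, _ = db.estimate_sample(reads, catalog, wi)
        n = len(reads)
        for g in catalog.sgb_ids:
            p = truth.abundances[g]
            if p >= 1e-3:
                sd = np.sqrt(p * (1 - p) / n)
                assert abs(vec.relative[g] - p) <= 3 * sd + 0.02 * p + 1e-9

    def test_mean_estimate_converges_over_replicates(self, catalog_host):
        catalog, host = catalog_host
        cfg = db.CommunityConfig(
            n_sgbs=len(catalog), genome_length_bp=4000, n_reads=6000,
            host_fraction=0.0, junk_fraction=0.0, host_genome_length_bp=4000, seed=3,
        )
        truth = db.draw_truth_profile(cfg, catalog.sgb_ids, "s", seed=17)
        wi = db.build_window_index(catalog, 1000)
        ests = []
        for seed in range(5):
            t = db.TruthProfile("s", truth.abundances, 0.0, seed=100 + seed)
            reads = db.simulate_sample_reads(catalog, host, t, cfg)
            vec, _, _ = db.estimate_sample(reads, catalog, wi)
            ests.append(vec.relative)
        mean_est = pd.concat(ests, axis=1).mean(axis=1)
        for g in catalog.sgb_ids:
            # at this depth only species above ~1% clear the existence rule
            if truth.abundances[g] >= 0.01:
                assert mean_est[g] == pytest.approx(truth.abundances[g], rel=0.15)


class TestDetectionCap:
    def _vec(self, rel):
        s = pd.Series(rel)
        return db.AbundanceVector("s", s, s > 0, s)

    def test_floor_mode_raises_small_entries(self):
        v = db.apply_detection_cap(self._vec({"A": 5e-5, "B": 0.99995}), 1e-4, "floor")
        assert v.relative["A"] == pytest.approx(1e-4)
        assert v.cap_mode == "floor"
        assert v.relative.min() >= 1e-4

    def test_zero_mode_renormalizes_survivors(self):
        v = db.apply_detection_cap(
            self._vec({"A": 5e-5, "B": 0.7, "C": 0.29995}), 1e-4, "zero"
        )
        assert v.relative["A"] == 0.0
        assert v.relative.sum() == pytest.approx(1.0)
        assert v.relative["B"] == pytest.approx(0.7 / 0.99995)

    def test_no_op_when_all_entries_above_cap(self):
        rel = {"A": 0.4, "B": 0.6}
        for mode in ("floor", "zero"):
            v = db.apply_detection_cap(self._vec(rel), 1e-4, mode)
            assert v.relative.tolist() == [0.4, 0.6]

    def test_invalid_cap_rejected(self):
        with pytest.raises(ValueError):
            db.apply_detection_cap(self._vec({"A": 1.0}), 0.0)
        with pytest.raises(ValueError, match="cap mode"):
            db.apply_detection_cap(self._vec({"A": 1.0}), 1e-4, "clip")
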