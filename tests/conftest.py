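import numpy as np
import pytest

import dogbiome as db


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale community: 6 SGBs x 4 kb, 4000 reads of 100 bp."""
    return db.CommunityConfig(
        n_sgbs=6,
        genome_length_bp=4000,
        n_reads=4000,
        read_length_bp=100,
        base_error_rate=0.005,
        host_fraction=0.1,
        junk_fraction=0.1,
        host_genome_length_bp=4000,
        n_butyrate=4,
        n_acetate=2,
        seed=3,
    )


@pytest.fixture(scope="session")
def catalog_host(small_config):
    return db.generate_reference_catalog(small_config)


@pytest.fixture(scope="session")
def small_sample(small_config, catalog_host):
    catalog, host = catalog_host
    truth = db.draw_truth_profile(small_config, catalog.sgb_ids, "s1", seed=11)
    reads = db.simulate_sample_reads(catalog, host, truth, small_config)
    return truth, reads


def brute_force_map(read_seq, genomes, seed_length=31):
    """Exhaustive all-position, both-strand ungapped scoring oracle.

    Scores every full-containment placement of the read (forward and reverse
    complement) in every genome by mismatch count and applies the same
    acceptance contract as the mapper: a read is unique iff exactly one
    placement attains the minimum mismatch count within the budget
    (#disjoint seed windows - 1).
    """
    L = len(read_seq)
    n_seeds = L // seed_length
    if n_seeds == 0:
        return ("unmapped", None, None, None)
    budget = n_seeds - 1
    comp = str.maketrans("ACGT", "TGCA")
    rc = read_seq.translate(comp)[::-1]
    arrs = {
        "+": np.frombuffer(read_seq.encode(), dtype=np.uint8),
        "-": np.frombuffer(rc.encode(), dtype=np.uint8),
    }
    best_mm, best = budget + 1, []
    for name, seq in genomes.items():
        g = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(g) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(g, L)
        for strand, arr in arrs.items():
            mm = (windows != arr).sum(axis=1)
            m = int(mm.min())
            if m < best_mm:
                best_mm = m
                best = [(name, int(p), strand) for p in np.flatnonzero(mm == m)]
            elif m == best_mm:
                best.extend((name, int(p), strand) for p in np.flatnonzero(mm == m))
    if best_mm > budget or not best:
        return ("unmapped", None, None, None)
    if len(best) > 1:
        return ("ambiguous", None, None, None)
    name, pos, strand = best[0]
    return ("unique", name, pos, strand)


@pytest.fixture(scope="session")
def oracle():
    return brute_force_map
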