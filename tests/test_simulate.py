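import json

import numpy as np
import pytest

from infrapopgen.exceptions import ConfigurationError
from infrapopgen.io import (
    Alignment,
    build_species_datasets,
    metadata_from_frame,
    read_alignment,
    read_loads,
    read_metadata,
)
from infrapopgen.simulate import (
    SimulationConfig,
    SpeciesConfig,
    paperlike_config,
    simulate_species,
    simulate_system,
    write_fixture,
)
from infrapopgen.stats import (
    compute_diversity_stats,
    nucleotide_diversity,
    r2_statistic,
    segregating_sites,
    tajimas_d,
)


def _species(**kw):
    base = dict(name="x", median_load=10.0, n_birds=4, mites_per_bird=3,
                founders=2, theta=0.01, L=200)
    base.update(kw)
    return SpeciesConfig(**base)


class TestSimulateSpecies:
    def test_single_founder_makes_birds_clonal(self, rng):
        ids, seqs, meta = simulate_species(_species(founders=1, theta=0.05), rng)
        by_bird = {}
        for m, s in zip(meta, seqs):
            by_bird.setdefault(m.bird_id, set()).add(s)
        assert all(len(v) == 1 for v in by_bird.values())

    def test_zero_theta_is_monomorphic(self, rng):
        ids, seqs, _ = simulate_species(_species(theta=0.0), rng)
        al = Alignment(ids, seqs)
        assert segregating_sites(al)[0] == 0
        assert nucleotide_diversity(al) == 0.0
        # downstream undefined paths propagate as NaN, not zero
        D, p = tajimas_d(al)
        assert np.isnan(D) and np.isnan(r2_statistic(al))

    def test_expected_pi_equals_theta_with_distinct_founders(self):
        # equilibrium, f = m: the sample is an unstructured coalescent sample
        rng = np.random.default_rng(101)
        cfg = _species(founders=3, mites_per_bird=3, theta=0.01, L=507)
        pis = []
        for _ in range(200):
            ids, seqs, _ = simulate_species(cfg, rng)
            pis.append(nucleotide_diversity(Alignment(ids, seqs)))
        se = np.std(pis) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - cfg.theta) < 3 * se

    def test_sharing_probability_increases_as_founders_decrease(self):
        rng = np.random.default_rng(55)

        def sharing_rate(f):
            # fraction of within-bird mite pairs with identical haplotypes
            from itertools import combinations
            hits = total = 0
            for _ in range(200):
                ids, seqs, meta = simulate_species(
                    _species(founders=f, theta=0.05, n_birds=2), rng
                )
                by_bird = {}
                for m, s in zip(meta, seqs):
                    by_bird.setdefault(m.bird_id, []).append(s)
                for v in by_bird.values():
                    for a, b in combinations(v, 2):
                        total += 1
                        hits += a == b
            return hits / total

        r1, r2, r3 = sharing_rate(1), sharing_rate(2), sharing_rate(3)
        assert r1 == 1.0
        assert r1 > r2 > r3

    def test_too_many_mutations_raises(self, rng):
        with pytest.raises(ConfigurationError, match="increase L"):
            for _ in range(20):
                simulate_species(_species(theta=5.0, L=10), rng)

    def test_mode_validation(self):
        with pytest.raises(ConfigurationError):
            _species(mode="expansion", growth=1.0)
        with pytest.raises(ConfigurationError):
            _species(mode="bogus")


class TestSimulateSystem:
    def test_default_preset_bookkeeping(self, paperlike_system):
        cfg = paperlike_config()
        assert len(cfg.species) == 17
        expected = sum(c.n_birds * c.mites_per_bird for c in cfg.species)
        assert paperlike_system.alignment.n == expected
        assert len(paperlike_system.loads) == 17

    def test_truth_theta_increases_with_load(self):
        cfg = paperlike_config()
        loads = [c.median_load for c in cfg.species]
        thetas = [c.theta for c in cfg.species]
        assert all(t2 > t1 for t1, t2 in zip(thetas, thetas[1:]))
        assert all(m2 > m1 for m1, m2 in zip(loads, loads[1:]))

    def test_load_diversity_correlation_positive(self):
        # generator contract: beta > 0 couples load and realized diversity
        from scipy.stats import spearmanr
        hits = 0
        for run in range(20):
            sysm = simulate_system(paperlike_config(), seed=500 + run)
            loads = dict(zip(sysm.loads["species"], sysm.loads["median_load"]))
            ds = build_species_datasets(
                sysm.alignment, metadata_from_frame(sysm.metadata), loads
            )
            pis = [nucleotide_diversity(d.alignment) for d in ds]
            ms = [d.median_load for d in ds]
            hits += spearmanr(ms, pis).statistic > 0
        assert hits >= 19

    def test_expansion_species_have_lower_r2(self):
        diffs = []
        rng_seed = 900
        for k in range(25):
            pair = []
            for mode in ("expansion", "equilibrium"):
                cfg = SimulationConfig([_species(mode=mode, theta=0.01,
                                                 n_birds=8, L=507)])
                sysm = simulate_system(cfg, seed=rng_seed + k)
                pair.append(r2_statistic(sysm.alignment))
            if not np.isnan(pair).any():
                diffs.append(pair[0] - pair[1])
        assert np.mean(diffs) < 0

    def test_deterministic_given_seed(self):
        a = simulate_system(paperlike_config(), seed=3)
        b = simulate_system(paperlike_config(), seed=3)
        assert a.alignment.seqs == b.alignment.seqs
        assert a.metadata.equals(b.metadata)


class TestWriteFixture:
    def test_round_trip_through_io(self, tmp_path, paperlike_system):
        paths = write_fixture(paperlike_system, tmp_path)
        al = read_alignment(paths["alignment"])
        assert al.ids == paperlike_system.alignment.ids
        assert al.seqs == paperlike_system.alignment.seqs
        meta = read_metadata(paths["metadata"])
        assert len(meta) == al.n
        loads = read_loads(paths["loads"])
        assert len(loads) == 17
        truth = json.loads(paths["truth"].read_text())
        assert set(truth) == set(loads)

    def test_same_seed_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fixture(simulate_system(paperlike_config(), seed=8), d1)
        write_fixture(simulate_system(paperlike_config(), seed=8), d2)
        for name in ("alignment.fasta", "metadata.tsv", "loads.tsv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
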