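"""Synthetic host–symbiont mtDNA datasets with vertical-transmission structure.

The generator emulates the sampling design the analysis assumes: several
symbiont (mite) species, each sampled as a handful of mites from each of
several host (bird) individuals. Within a bird, the m sampled mites
descend from at most f founder lineages (mites assigned to founders
uniformly at random; within-bird coalescence is treated as instantaneous,
capturing the kin structure that vertical transmission produces). The
founder lineages across birds then follow a neutral constant-size
coalescent whose scaled mutation rate θ(M) = θ0·M^β per site increases
with the species' median infrapopulation size M — the census-size →
effective-size link the analysis is designed to detect. Expansion-mode
species compress all ancestral branch lengths by a factor g > 1, the
simplest mechanism producing star-like genealogies, an excess of
singletons and low R₂.

Mutations are dropped per branch as Poisson(length · θ/2 · L) at distinct
uniform positions (quasi-infinite sites on L positions; collisions are
redrawn, back-mutation is not modelled).

Defaults are illustrative: the paper-like preset spans median loads over
one order of magnitude with per-site diversity of order 0.002–0.02, the
magnitude typical of within-species arthropod COI data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import Alignment, SampleMetadata, write_alignment

__all__ = [
    "SpeciesConfig",
    "SimulationConfig",
    "SimulatedSystem",
    "simulate_species",
    "simulate_system",
    "write_fixture",
    "paperlike_config",
]

BASES = "ACGT"


@dataclass
class SpeciesConfig:
    """Parameters for one simulated symbiont species."""

    name: str
    median_load: float  # M: median mites per host individual
    n_birds: int = 8
    mites_per_bird: int = 5
    founders: int = 2  # f: founding lineages per bird (f=1 -> clonal birds)
    theta: float = 0.005  # per-site scaled mutation rate of the species pool
    mode: str = "equilibrium"  # or "expansion"
    growth: float = 20.0  # g: ancestral coalescence-rate multiplier (expansion)
    expansion_time: float = 0.05  # epoch of the sudden expansion, coalescent units
    L: int = 507

    def __post_init__(self) -> None:
        if min(self.n_birds, self.mites_per_bird, self.founders, self.L) < 1:
            raise ConfigurationError(f"{self.name}: counts must be >= 1")
        if self.median_load <= 0:
            raise ConfigurationError(f"{self.name}: median load must be positive")
        if self.theta < 0:
            raise ConfigurationError(f"{self.name}: theta must be >= 0")
        if self.mode not in ("equilibrium", "expansion"):
            raise ConfigurationError(f"{self.name}: unknown mode {self.mode!r}")
        if self.mode == "expansion" and self.growth <= 1:
            raise ConfigurationError(f"{self.name}: expansion needs growth > 1")
        if self.mode == "expansion" and self.expansion_time <= 0:
            raise ConfigurationError(f"{self.name}: expansion_time must be > 0")


@dataclass
class SimulationConfig:
    species: list[SpeciesConfig]
    seed: int = 0


@dataclass
class SimulatedSystem:
    """A complete simulated study: alignment + metadata + loads + truth."""

    alignment: Alignment
    metadata: pd.DataFrame
    loads: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _coalescent_branches(
    K: int,
    rng: np.random.Generator,
    expansion_time: float | None = None,
    growth: float = 1.0,
) -> tuple[list[frozenset], np.ndarray]:
    """Neutral coalescent on K lineages -> (leaf sets, branch lengths).

    With ``expansion_time`` T and ``growth`` g > 1, the coalescence rate
    is j(j−1)/2 more recently than T and g·j(j−1)/2 before it — a sudden
    g-fold population expansion T coalescent units ago. Equivalently,
    branch segments older than T are compressed by g: lineages linger in
    the recent (large-population) epoch, then crunch, producing star-like
    genealogies with an excess of external branch length.
    """
    if K == 1:
        return [], np.zeros(0)
    sets = [frozenset([i]) for i in range(K)]
    births = [0.0] * K
    masks: list[frozenset] = []
    lengths: list[float] = []
    t = 0.0
    k = K
    while k > 1:
        rate = k * (k - 1) / 2.0
        if expansion_time is None or t >= expansion_time:
            anc = expansion_time is not None and t >= expansion_time
            t += rng.exponential(1.0 / (rate * (growth if anc else 1.0)))
        else:
            dt = rng.exponential(1.0 / rate)
            if t + dt <= expansion_time:
                t += dt
            else:
                # memoryless: redraw the residual wait at the ancestral rate
                t = expansion_time + rng.exponential(1.0 / (rate * growth))
        i, j = rng.choice(k, size=2, replace=False)
        i, j = int(i), int(j)
        for idx in (i, j):
            masks.append(sets[idx])
            lengths.append(t - births[idx])
        merged = sets[i] | sets[j]
        sets[i], births[i] = merged, t
        sets[j], births[j] = sets[k - 1], births[k - 1]
        del sets[k - 1], births[k - 1]
        k -= 1
    return masks, np.asarray(lengths)


def simulate_species(
    cfg: SpeciesConfig, rng: np.random.Generator
) -> tuple[list[str], list[str], list[SampleMetadata]]:
    """Simulate one species' sequences and per-mite metadata.

    Two-phase coalescent: mites within a bird are assigned uniformly to
    up to ``founders`` lineages (instantaneous within-bird coalescence),
    then the founder lineages follow a neutral coalescent — with all
    branch lengths divided by ``growth`` in expansion mode.
    """
    # phase 1: founder assignment within each bird
    founder_of_mite: list[int] = []  # global founder-lineage index per mite
    lineage_count = 0
    bird_of_mite: list[int] = []
    for b in range(cfg.n_birds):
        if cfg.founders >= cfg.mites_per_bird:
            # enough founders for every mite: unstructured baseline
            assign = rng.choice(cfg.founders, size=cfg.mites_per_bird, replace=False)
        else:
            assign = rng.integers(cfg.founders, size=cfg.mites_per_bird)
        used = {}
        for m, a in enumerate(assign):
            if a not in used:
                used[a] = lineage_count
                lineage_count += 1
            founder_of_mite.append(used[a])
            bird_of_mite.append(b)

    # phase 2: coalescent among founder lineages
    if cfg.mode == "expansion":
        masks, lengths = _coalescent_branches(
            lineage_count, rng, expansion_time=cfg.expansion_time, growth=cfg.growth
        )
    else:
        masks, lengths = _coalescent_branches(lineage_count, rng)

    # mutation dropping: Poisson per branch, distinct uniform positions
    mut_counts = rng.poisson(lengths * cfg.theta / 2.0 * cfg.L) if len(lengths) else np.zeros(0, dtype=int)
    total = int(mut_counts.sum())
    if total > cfg.L:
        raise ConfigurationError(
            f"{cfg.name}: {total} mutations exceed L={cfg.L}; "
            "increase L or decrease theta"
        )
    positions = rng.choice(cfg.L, size=total, replace=False)

    ancestral = rng.integers(4, size=cfg.L)
    lineage_seqs = np.tile(ancestral, (max(lineage_count, 1), 1))
    p = 0
    for mask, c in zip(masks, mut_counts):
        for _ in range(int(c)):
            pos = positions[p]
            p += 1
            derived = (ancestral[pos] + 1 + rng.integers(3)) % 4
            lineage_seqs[list(mask), pos] = derived

    ids, seqs, meta = [], [], []
    counters: dict[int, int] = {}
    for mite, (b, lineage) in enumerate(zip(bird_of_mite, founder_of_mite)):
        counters[b] = counters.get(b, 0) + 1
        sid = f"{cfg.name}_b{b:02d}m{counters[b]}"
        ids.append(sid)
        seqs.append("".join(BASES[x] for x in lineage_seqs[lineage]))
        meta.append(
            SampleMetadata(
                sample_id=sid,
                species=cfg.name,
                bird_id=f"{cfg.name}_bird{b:02d}",
                locality="",  # filled by simulate_system
            )
        )
    return ids, seqs, meta


def simulate_system(
    config: SimulationConfig, seed: int | None = None
) -> SimulatedSystem:
    """Assemble a full multi-species system; deterministic given the seed.

    Each species gets its own substream, so per-species realizations do
    not depend on which other species are configured. Each bird is
    assigned a locality ('ES' with probability 0.8, 'RU' otherwise),
    mimicking a study pooling a main and a distant sampling region.
    """
    if seed is None:
        seed = config.seed
    all_ids, all_seqs, rows = [], [], []
    truth = {}
    for k, cfg in enumerate(config.species):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
        ids, seqs, meta = simulate_species(cfg, rng)
        loc_rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(k, 1))
        )
        locality = {
            m.bird_id: ("RU" if loc_rng.random() < 0.2 else "ES")
            for m in meta
        }
        all_ids.extend(ids)
        all_seqs.extend(seqs)
        for m in meta:
            rows.append({
                "sample_id": m.sample_id, "species": m.species,
                "bird_id": m.bird_id, "locality": locality[m.bird_id],
                "source": "multi_per_bird",
            })
        truth[cfg.name] = {
            "theta": cfg.theta, "mode": cfg.mode,
            "median_load": cfg.median_load, "n_birds": cfg.n_birds,
            "mites_per_bird": cfg.mites_per_bird, "founders": cfg.founders,
        }
    loads = pd.DataFrame(
        [{"species": c.name, "median_load": c.median_load} for c in config.species]
    )
    return SimulatedSystem(
        alignment=Alignment(all_ids, all_seqs),
        metadata=pd.DataFrame(rows),
        loads=loads,
        truth=truth,
    )


def paperlike_config(
    n_species: int = 17,
    theta0: float = 3e-4,
    beta: float = 1.18,
    load_range: tuple[float, float] = (5.0, 50.0),
    n_expansion: int = 2,
    founders: int = 2,
    mites_per_bird: int = 5,
    L: int = 507,
    growth: float = 20.0,
    seed: int = 0,
) -> SimulationConfig:
    """Default preset: 17 species, loads log-spaced over one order of magnitude.

    θ scales as θ0·M^β so that per-site diversity spans roughly
    0.002–0.03; 6–12 birds per species (cycling), 5 mites per bird, 2
    founders per bird. ``n_expansion`` species — the smallest-load ones —
    run in expansion mode, providing the star-like / low-R₂ contrast.
    """
    loads = np.geomspace(load_range[0], load_range[1], n_species)
    species = []
    for k, M in enumerate(loads):
        species.append(
            SpeciesConfig(
                name=f"sp{k + 1:02d}",
                median_load=float(M),
                n_birds=6 + (k % 7),
                mites_per_bird=mites_per_bird,
                founders=founders,
                theta=float(theta0 * M**beta),
                mode="expansion" if k < n_expansion else "equilibrium",
                growth=growth,
                L=L,
            )
        )
    return SimulationConfig(species=species, seed=seed)


def write_fixture(system: SimulatedSystem, out_dir: str | Path) -> dict[str, Path]:
    """Write alignment.fasta, metadata.tsv, loads.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": out / "alignment.fasta",
        "metadata": out / "metadata.tsv",
        "loads": out / "loads.tsv",
        "truth": out / "truth.json",
    }
    write_alignment(system.alignment, paths["alignment"])
    system.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    system.loads.to_csv(paths["loads"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(system.truth, indent=1, sort_keys=True))
    return paths
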