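"""Low-density SNP panel construction.

Replicate panels are drawn at each target density under one of two
strategies: uniform sampling across the genome, or per-chromosome sampling
with counts proportional to chromosome length (largest-remainder rounding).
Each panel carries its own derived seed so panel sets are reproducible and
insensitive to grid extensions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeDataset

__all__ = [
    "GENOMEWIDE_RANDOM",
    "WITHIN_CHROMOSOME",
    "SNPPanel",
    "DensityGrid",
    "DEFAULT_DENSITIES",
    "allocate_proportional",
    "sample_panel",
    "make_panel_set",
]

GENOMEWIDE_RANDOM = "genomewide_random"
WITHIN_CHROMOSOME = "within_chromosome_proportional"
_STRATEGY_CODE = {GENOMEWIDE_RANDOM: 0, WITHIN_CHROMOSOME: 1}

#: Densities evaluated in every dataset; 6000/7000/9000 are appended per
#: dataset when enough QC-passing SNPs remain.
DEFAULT_DENSITIES = [
    100, 200, 300, 400, 500, 600, 700, 800, 900, 1000, 1200, 1400, 1600,
    1800, 2000, 2250, 2500, 2750, 3000, 3500, 4000, 4500, 5000,
]
EXTENDED_DENSITIES = [6000, 7000, 9000]


@dataclass(frozen=True)
class SNPPanel:
    marker_ids: tuple[str, ...]
    density: int
    strategy: str
    replicate_index: int
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("panel contains duplicate marker IDs")
        if len(self.marker_ids) != self.density:
            raise ValueError(f"panel has {len(self.marker_ids)} markers for density {self.density}")


@dataclass(frozen=True)
class DensityGrid:
    densities: tuple[int, ...]

    def __post_init__(self) -> None:
        d = list(self.densities)
        if d != sorted(set(d)):
            raise ValueError("densities must be strictly increasing")
        if d and d[0] < 1:
            raise ValueError("densities must be positive")

    @classmethod
    def default(cls) -> "DensityGrid":
        return cls(tuple(DEFAULT_DENSITIES + EXTENDED_DENSITIES))


def allocate_proportional(chrom_lengths: dict[str, float], k: int) -> dict[str, int]:
    """Integer counts per chromosome proportional to length, summing to k.

    Largest-remainder rounding; ties broken by descending length, then label.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    labels = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in labels], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    quota = k * lengths / lengths.sum()
    base = np.floor(quota).astype(int)
    remainder = quota - base
    short = k - int(base.sum())
    order = sorted(
        range(len(labels)),
        key=lambda i: (-remainder[i], -lengths[i], labels[i]),
    )
    for i in order[:short]:
        base[i] += 1
    return dict(zip(labels, base.tolist()))


def marker_span_lengths(dataset: GenotypeDataset) -> dict[str, int]:
    """Chromosome 'length' as the span of observed marker positions.

    RAD-derived maps have no assembly lengths, so the max-min position span
    per chromosome / linkage group stands in (floor 1 for singletons).
    """
    spans = dataset.markers.groupby("chrom", sort=False)["pos"].agg(lambda s: s.max() - s.min())
    return {c: max(int(v), 1) for c, v in spans.items()}


def sample_panel(dataset: GenotypeDataset, k: int, strategy: str = GENOMEWIDE_RANDOM,
                 seed: int = 0, replicate_index: int = 1) -> SNPPanel:
    """Draw one panel of k markers without replacement, ordered by map position."""
    m = dataset.n_markers
    if k > m:
        raise ValueError(f"requested {k} markers but only {m} available")
    if strategy not in _STRATEGY_CODE:
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    ids = dataset.markers["snp_id"].to_numpy()
    if strategy == GENOMEWIDE_RANDOM:
        chosen = rng.choice(m, size=k, replace=False)
    else:
        alloc = allocate_proportional(marker_span_lengths(dataset), k)
        chrom = dataset.markers["chrom"].to_numpy()
        chosen_parts = []
        for c, count in alloc.items():
            idx = np.flatnonzero(chrom == c)
            if count > idx.size:
                raise ValueError(
                    f"chromosome {c!r} allocated {count} markers but holds {idx.size}; "
                    f"consider strategy {GENOMEWIDE_RANDOM!r}"
                )
            chosen_parts.append(rng.choice(idx, size=count, replace=False))
        chosen = np.concatenate(chosen_parts)
    chosen.sort()  # map order == (chromosome, position) order
    return SNPPanel(tuple(ids[chosen]), k, strategy, replicate_index, int(seed))


def derive_panel_seed(master_seed: int, strategy: str, density: int, replicate: int) -> int:
    """Counter-based per-panel seed: stable under grid or replicate extension."""
    ss = np.random.SeedSequence([int(master_seed), _STRATEGY_CODE[strategy], density, replicate])
    return int(ss.generate_state(1)[0] % (2**31))


def make_panel_set(dataset: GenotypeDataset, grid: DensityGrid, replicates: int = 5,
                   strategy: str = GENOMEWIDE_RANDOM, master_seed: int = 0,
                   ) -> tuple[list[SNPPanel], list[int]]:
    """Replicate panels at every feasible grid density.

    Densities above the dataset's marker count are dropped (returned in the
    second element so callers can log the per-dataset grid reduction).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    m = dataset.n_markers
    feasible = [d for d in grid.densities if d <= m]
    dropped = [d for d in grid.densities if d > m]
    panels = []
    for density in feasible:
        for rep in range(1, replicates + 1):
            seed = derive_panel_seed(master_seed, strategy, density, rep)
            panels.append(sample_panel(dataset, density, strategy, seed, rep))
    return panels, dropped


def write_panel(panel: SNPPanel, ids_path, manifest_path=None) -> None:
    """Serialize as a PLINK --extract style ID list plus a JSON manifest."""
    with open(ids_path, "w") as fh:
        fh.write("\n".join(panel.marker_ids) + "\n")
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump(
                {
                    "density": panel.density,
                    "strategy": panel.strategy,
                    "replicate_index": panel.replicate_index,
                    "seed": panel.seed,
                },
                fh, indent=2,
            )


def full_panel(dataset: GenotypeDataset) -> SNPPanel:
    """The degenerate panel containing every QC-passing marker."""
    ids = tuple(dataset.markers["snp_id"])
    return SNPPanel(ids, len(ids), GENOMEWIDE_RANDOM, 1, 0)
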