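"""Family-structured genotype and polygenic trait simulation.

Generates the kind of data a sib-testing aquaculture breeding program
records: unrelated founder pairs in linkage equilibrium, full-sib offspring
produced by gene dropping with Haldane (Poisson, no-interference)
recombination, and a polygenic trait with a chosen heritability, optional
categorical fixed effects, and optional log transform or right-censored
days-to-death coding.  Within-family linkage disequilibrium — the long
shared haplotypes that let sparse panels capture relatedness — arises from
co-segregation during gene dropping.

Presets mirror four published aquaculture datasets (Atlantic salmon, common
carp, gilthead sea bream, Pacific oyster) in family counts, sample sizes,
QC-passing marker counts, trait scale, and heritability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset, PhenotypeTable
from .panel_design import allocate_proportional

__all__ = [
    "SimConfig",
    "TruthRecord",
    "GeneticMap",
    "PRESETS",
    "preset_config",
    "simulate_founders",
    "drop_gamete",
    "make_families",
    "simulate_trait",
    "simulate_dataset",
]


def split_total(total: int, n_groups: int) -> list[int]:
    """Split ``total`` into near-equal group sizes (remainder spread first)."""
    base, extra = divmod(total, n_groups)
    return [base + (1 if i < extra else 0) for i in range(n_groups)]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    ``offspring_per_family`` is either a single count applied to every family
    or a per-family list; ``fixed_effects`` entries are
    (factor name, n_levels, per-level effects in phenotypic SD units).
    """

    n_families: int
    offspring_per_family: int | tuple[int, ...]
    n_snps: int
    n_chromosomes: int
    chrom_lengths: tuple[float, ...]
    h2_true: float
    n_parents: int | None = None  # default: 2 per family, monogamous pairs
    cm_per_mb: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 500
    fixed_effects: tuple[tuple[str, int, tuple[float, ...]], ...] = ()
    transform: str = "none"  # none | log
    censor_day: int | None = None
    trait_name: str = "trait"
    trait_mean: float = 0.0
    trait_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside (0, 0.5]")
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError("h2_true must lie in [0, 1]")
        if self.h2_true > 0 and self.n_qtl < 1:
            raise ValueError("n_qtl must be >= 1 when h2_true > 0")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed n_snps")
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ValueError("chrom_lengths length must equal n_chromosomes")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.transform not in ("none", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.censor_day is not None and self.censor_day < 1:
            raise ValueError("censor_day must be a positive integer")
        n_parents = self.n_parents if self.n_parents is not None else 2 * self.n_families
        if n_parents // 2 < self.n_families:
            raise ValueError(
                f"{self.n_families} families need {2 * self.n_families} parents, "
                f"only {n_parents} available"
            )

    @property
    def offspring_counts(self) -> list[int]:
        if isinstance(self.offspring_per_family, int):
            return [self.offspring_per_family] * self.n_families
        counts = list(self.offspring_per_family)
        if len(counts) != self.n_families:
            raise ValueError("per-family offspring list length must equal n_families")
        return counts

    @property
    def n_offspring(self) -> int:
        return sum(self.offspring_counts)


@dataclass
class TruthRecord:
    """Ground truth retained from a trait simulation for recovery checks."""

    true_breeding_values: np.ndarray
    qtl_ids: tuple[str, ...]
    qtl_effects: np.ndarray
    realized_h2: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "true_breeding_values": self.true_breeding_values.tolist(),
                    "qtl_ids": list(self.qtl_ids),
                    "qtl_effects": self.qtl_effects.tolist(),
                    "realized_h2": self.realized_h2,
                },
                fh,
            )


# Presets emulating four published aquaculture datasets: family counts,
# post-QC sample and SNP counts, trait scale, fixed-effect structure, and the
# reported genomic heritability of the analysed trait.
_PRESET_SPECS: dict[str, dict] = {
    "salmon": dict(
        n_families=85, total_offspring=1481, n_snps=9866, n_chromosomes=29,
        genome_bp=2.9e9, h2=0.24, trait_name="amoebic_load",
        trait_mean=31.36, trait_sd=3.24,
        fixed_effects=(("tank", 2, (0.0, 0.3)),),
    ),
    "carp": dict(
        n_families=195, total_offspring=1211, n_snps=6966, n_chromosomes=50,
        genome_bp=1.7e9, h2=0.27, trait_name="log_length",
        trait_mean=77.01, trait_sd=7.11, transform="log",
        fixed_effects=(("cross_group", 4, (0.0, 0.3, 0.6, 0.9)),),
    ),
    "seabream": dict(
        n_families=73, total_offspring=741, n_snps=7598, n_chromosomes=24,
        genome_bp=8.4e8, h2=0.20, trait_name="days_to_death",
        trait_mean=10.40, trait_sd=4.08,
    ),
    "oyster": dict(
        n_families=23, total_offspring=718, n_snps=14028, n_chromosomes=10,
        genome_bp=6.0e8, h2=0.49, trait_name="days_to_death",
        trait_mean=6.76, trait_sd=1.91, censor_day=8,
        fixed_effects=(("tank", 2, (0.0, 0.3)),),
    ),
}

PRESETS = tuple(_PRESET_SPECS)


def preset_config(name: str, h2: float | None = None, seed: int = 0, **overrides) -> SimConfig:
    """SimConfig for one of the dataset presets; h2 and seed are overridable."""
    if name not in _PRESET_SPECS:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESETS}")
    s = _PRESET_SPECS[name]
    n_chrom = s["n_chromosomes"]
    cfg = SimConfig(
        n_families=s["n_families"],
        offspring_per_family=tuple(split_total(s["total_offspring"], s["n_families"])),
        n_snps=s["n_snps"],
        n_chromosomes=n_chrom,
        chrom_lengths=tuple([s["genome_bp"] / n_chrom] * n_chrom),
        h2_true=s["h2"] if h2 is None else h2,
        fixed_effects=s.get("fixed_effects", ()),
        transform=s.get("transform", "none"),
        censor_day=s.get("censor_day"),
        trait_name=s["trait_name"],
        trait_mean=s["trait_mean"],
        trait_sd=s["trait_sd"],
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Genetic map and meiosis
# ---------------------------------------------------------------------------

class GeneticMap:
    """Per-chromosome marker slices with positions in Morgans."""

    def __init__(self, markers: pd.DataFrame, cm_per_mb: float):
        if cm_per_mb < 0:
            raise ValueError("cm_per_mb must be non-negative")
        self.blocks: list[tuple[slice, np.ndarray]] = []
        start = 0
        chrom = markers["chrom"].to_numpy()
        pos = markers["pos"].to_numpy(dtype=float)
        for c in pd.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise ValueError("markers of one chromosome are not contiguous")
            block = slice(idx[0], idx[-1] + 1)
            p = pos[block]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"marker positions not sorted on chromosome {c!r}")
            morgans = p * cm_per_mb / 1e6 / 100.0
            self.blocks.append((block, morgans))
            start = idx[-1] + 1
        if start != len(markers):
            raise ValueError("marker map is not grouped by chromosome")


def drop_gamete(parent_haplotypes: np.ndarray, genetic_map: GeneticMap,
                rng: np.random.Generator) -> np.ndarray:
    """One meiosis: Poisson crossovers under Haldane's model, no interference.

    ``parent_haplotypes`` is a (2, m) phased array.  Per chromosome the
    crossover count is Poisson with mean equal to the genetic length in
    Morgans, crossover positions are uniform, and the returned haplotype
    alternates parental strands at each crossover starting from a random
    strand; chromosomes segregate independently.
    """
    hap = np.empty(parent_haplotypes.shape[1], dtype=parent_haplotypes.dtype)
    for block, morgans in genetic_map.blocks:
        length = morgans[-1] - morgans[0] if morgans.size else 0.0
        start = rng.integers(2)
        n_x = rng.poisson(length) if length > 0 else 0
        if n_x:
            xpos = np.sort(rng.uniform(morgans[0], morgans[-1], n_x))
            strand = (start + np.searchsorted(xpos, morgans, side="left")) % 2
            hap[block] = parent_haplotypes[:, block][strand, np.arange(morgans.size)]
        else:
            hap[block] = parent_haplotypes[start, block]
    return hap


# ---------------------------------------------------------------------------
# Founders and families
# ---------------------------------------------------------------------------

def _marker_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    lengths = {str(c + 1): float(l) for c, l in enumerate(config.chrom_lengths)}
    alloc = allocate_proportional(lengths, config.n_snps)
    rows = []
    i = 0
    for c in lengths:
        pos = np.sort(rng.integers(1, int(lengths[c]) + 1, size=alloc[c]))
        for p in pos:
            rows.append((f"snp{i:06d}", c, int(p), "A", "B"))
            i += 1
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "a1", "a2"])


def _founder_haplotypes(config: SimConfig, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    markers = _marker_map(config, rng)
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=config.n_snps)
    n_founders = config.n_parents if config.n_parents is not None else 2 * config.n_families
    hap = (rng.random((n_founders, 2, config.n_snps)) < freqs).astype(np.int8)
    return hap, freqs, markers


def _rng_children(seed: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)]


def simulate_founders(config: SimConfig) -> GenotypeDataset:
    """Unrelated founders in linkage equilibrium at uniform-MAF markers."""
    founder_rng, _, _ = _rng_children(config.seed)
    hap, _, markers = _founder_haplotypes(config, founder_rng)
    n = hap.shape[0]
    samples = pd.DataFrame(
        {
            "fid": [f"FOUNDERS"] * n,
            "iid": [f"P{i:04d}" for i in range(n)],
            "sire": ["0"] * n, "dam": ["0"] * n, "sex": ["0"] * n,
        }
    )
    return GenotypeDataset(hap.sum(axis=1).astype(float), markers, samples)


def make_families(config: SimConfig) -> GenotypeDataset:
    """Full-sib families from monogamous founder pairs by gene dropping.

    Founders are paired in order (0,1), (2,3), ...; each offspring genotype
    is the sum of one gamete from each parent.  The sample table records
    family, sire and dam; the returned dataset holds the offspring.
    """
    founder_rng, meiosis_rng, _ = _rng_children(config.seed)
    hap, _, markers = _founder_haplotypes(config, founder_rng)
    gmap = GeneticMap(markers, config.cm_per_mb)
    counts = config.offspring_counts
    dosages = np.empty((sum(counts), config.n_snps))
    fids, iids, sires, dams = [], [], [], []
    row = 0
    for fam in range(config.n_families):
        sire_i, dam_i = 2 * fam, 2 * fam + 1
        for k in range(counts[fam]):
            g_s = drop_gamete(hap[sire_i], gmap, meiosis_rng)
            g_d = drop_gamete(hap[dam_i], gmap, meiosis_rng)
            dosages[row] = g_s + g_d
            fids.append(f"F{fam + 1:03d}")
            iids.append(f"O{k + 1:03d}")
            sires.append(f"P{sire_i:04d}")
            dams.append(f"P{dam_i:04d}")
            row += 1
    samples = pd.DataFrame({"fid": fids, "iid": iids, "sire": sires, "dam": dams,
                            "sex": ["0"] * row})
    return GenotypeDataset(dosages, markers, samples)


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------

def simulate_trait(dataset: GenotypeDataset, config: SimConfig
                   ) -> tuple[PhenotypeTable, TruthRecord]:
    """Additive polygenic trait with known heritability on ``dataset``.

    ``n_qtl`` causal markers get standard-normal effects; breeding values are
    rescaled so the realized Var(TBV)/Var(TBV + e) equals ``h2_true`` on the
    phenotypic scale (trait_sd units), residuals are normal, fixed-effect
    levels are assigned uniformly at random, and the optional log transform /
    day-censoring is applied last.
    """
    if dataset.n_individuals == 0:
        raise ValueError("empty dataset")
    if config.n_qtl > dataset.n_markers:
        raise ValueError("n_qtl exceeds available markers")
    _, _, trait_rng = _rng_children(config.seed)
    n, m = dataset.dosages.shape

    qtl_idx = np.sort(trait_rng.choice(m, size=config.n_qtl, replace=False))
    effects = trait_rng.standard_normal(config.n_qtl)
    Q = dataset.dosages[:, qtl_idx]
    Q = np.where(np.isnan(Q), np.nanmean(Q, axis=0), Q)
    Qc = Q - Q.mean(axis=0)
    raw = Qc @ effects
    raw_sd = raw.std()
    if config.h2_true > 0:
        if raw_sd == 0:
            raise ValueError("causal genotypes have zero variance; cannot impose h2 > 0")
        scale = config.trait_sd * np.sqrt(config.h2_true) / raw_sd
    else:
        scale = 0.0
    tbv = raw * scale
    e = trait_rng.normal(0.0, config.trait_sd * np.sqrt(1.0 - config.h2_true), size=n)
    core = config.trait_mean + tbv + e
    var_p = np.var(tbv + e)
    realized_h2 = float(np.var(tbv) / var_p) if var_p > 0 else 0.0

    data = {"fid": dataset.samples["fid"].to_numpy()}
    y = core.copy()
    for fname, n_levels, level_effects in config.fixed_effects:
        if len(level_effects) != n_levels:
            raise ValueError(f"factor {fname!r}: {n_levels} levels but "
                             f"{len(level_effects)} effects")
        lv = trait_rng.integers(n_levels, size=n)
        y = y + np.asarray(level_effects)[lv] * config.trait_sd
        data[fname] = np.array([f"{fname}{l + 1}" for l in lv])

    if config.transform == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive phenotypes")
        y = np.log(y)
    if config.censor_day is not None:
        # quantile-preserving integer-day coding: monotone rounding of the
        # continuous liability, survivors capped at censor_day
        y = np.clip(np.round(y), 1, config.censor_day)

    data[config.trait_name] = y
    table = PhenotypeTable(
        pd.DataFrame(data, index=pd.Index(dataset.individual_ids, name="id")),
        trait_columns=[config.trait_name],
        factor_columns=[f[0] for f in config.fixed_effects],
    )
    truth = TruthRecord(
        true_breeding_values=tbv,
        qtl_ids=tuple(dataset.markers["snp_id"].to_numpy()[qtl_idx]),
        qtl_effects=effects * scale,
        realized_h2=realized_h2,
    )
    return table, truth


def simulate_dataset(config: SimConfig
                     ) -> tuple[GenotypeDataset, PhenotypeTable, TruthRecord]:
    """Convenience: families plus trait in one call."""
    dataset = make_families(config)
    phenos, truth = simulate_trait(dataset, config)
    return dataset, phenos, truth
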