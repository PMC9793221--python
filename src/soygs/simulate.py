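"""Synthetic structured diversity panels for genomic-selection benchmarking.

The generator emulates the salient structure of a large cultivated soybean
germplasm panel genotyped on a dense SNP chip: roughly a thousand samples,
thousands of biallelic SNPs surviving a 5% MAF screen, several genetically
diverged subpopulations, and an additive polygenic seed-composition trait
(mg/g scale) with moderate-to-high heritability.

Model
-----
* Ancestral allele frequencies are drawn Uniform(0.05, 0.95).
* Subpopulation frequencies follow the Balding-Nichols construction:
  ``p_s ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` with divergence parameter ``F``
  (Fst).  ``F = 0`` means all subpopulations share the ancestral frequency.
* Within a subpopulation each haplotype is a first-order Markov chain along
  the marker map: at each marker the allele copies the previous marker's
  allele with probability ``ld_rho``, otherwise it is a fresh Bernoulli draw
  at that marker's subpopulation frequency.  The chain restarts at every
  chromosome boundary, so LD never crosses chromosomes.  ``ld_rho = 0``
  gives fully independent markers.
* Genotype dosage = sum of two independent haplotypes, hence Hardy-Weinberg
  proportions hold marker-by-marker within a subpopulation.
* The trait is additive: ``n_qtl`` causal markers drawn without replacement,
  standard-normal effects, genetic value = centered dosages x effects,
  Gaussian noise scaled so var(genetic)/var(phenotype) = h2 in expectation,
  then an affine rescale to the requested trait mean and CV (which leaves
  heritability and any correlation-based accuracy untouched).

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .datatypes import GenotypeMatrix, PhenotypeVector, PopulationPartition
from .errors import ConfigurationError, DataError

#: Subpopulation sizes inferred for the real 1,007-accession panel
#: (largest five genetic groups); used to shape the default benchmark panel.
BENCHMARK_SUBPOP_COUNTS = (259, 174, 108, 86, 79)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic panel.

    ``subpop_proportions=None`` means equal shares.  ``missing_rate`` masks
    a fraction of calls at random (default 0: the chip-style data the panel
    emulates is essentially complete; the knob exists to exercise imputation).
    """

    n_samples: int = 1007
    n_markers: int = 3000
    n_subpops: int = 5
    subpop_proportions: tuple[float, ...] | None = None
    fst: float = 0.1
    ld_rho: float = 0.5
    n_qtl: int = 150
    qtl_effect_corr: float = 1.0
    h2: float = 0.5
    trait_mean: float = 434.2
    trait_cv: float = 6.9
    seed: int = 0
    n_chromosomes: int = 20
    missing_rate: float = 0.0
    trait_name: str = "protein"

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.n_markers < 1:
            raise ConfigurationError("n_markers must be >= 1")
        if self.n_subpops < 1:
            raise ConfigurationError("n_subpops must be >= 1")
        if not 0.0 <= self.fst <= 0.5:
            raise ConfigurationError("fst must lie in [0, 0.5]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        if not 0 <= self.n_qtl <= self.n_markers:
            raise ConfigurationError("n_qtl must lie in [0, n_markers]")
        if not 0.0 <= self.h2 <= 1.0:
            raise ConfigurationError("h2 must lie in [0, 1]")
        if not 0.0 <= self.qtl_effect_corr <= 1.0:
            raise ConfigurationError("qtl_effect_corr must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")
        if self.subpop_proportions is not None:
            p = np.asarray(self.subpop_proportions, dtype=float)
            if len(p) != self.n_subpops:
                raise ConfigurationError(
                    "subpop_proportions length must equal n_subpops"
                )
            if np.any(p <= 0):
                raise ConfigurationError("subpop_proportions entries must be > 0")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError("subpop_proportions must sum to 1 within 1e-9")

    def proportions(self) -> np.ndarray:
        if self.subpop_proportions is None:
            return np.full(self.n_subpops, 1.0 / self.n_subpops)
        return np.asarray(self.subpop_proportions, dtype=float)


@dataclass
class TruthRecord:
    """Ground truth of one simulated trait."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray
    realized_h2: float


def benchmark_config(**overrides) -> SimulationConfig:
    """Default benchmark panel: 1,007 samples, five subpopulations with sizes
    proportional to the real panel's genetic groups, h2 = 0.5."""
    counts = np.asarray(BENCHMARK_SUBPOP_COUNTS, dtype=float)
    cfg = SimulationConfig(
        n_subpops=len(counts),
        subpop_proportions=tuple(counts / counts.sum()),
    )
    return replace(cfg, **overrides)


def _streams(config: SimulationConfig) -> list[np.random.Generator]:
    """Independent, reproducible substreams: freq, haplotype, missing, trait."""
    ss = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(c) for c in ss.spawn(4)]


def _group_sizes(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n samples to groups."""
    raw = proportions * n
    sizes = np.floor(raw).astype(int)
    frac_order = np.argsort(-(raw - sizes), kind="stable")
    for i in range(n - sizes.sum()):
        sizes[frac_order[i]] += 1
    return sizes


def subpopulation_assignment(config: SimulationConfig) -> PopulationPartition:
    """True subpopulation label per sample (contiguous blocks, pop1 first)."""
    config.validate()
    sizes = _group_sizes(config.n_samples, config.proportions())
    labels = np.concatenate(
        [np.full(s, f"pop{i + 1}") for i, s in enumerate(sizes)]
    )
    sample_ids = np.array([f"S{i:04d}" for i in range(config.n_samples)])
    return PopulationPartition(sample_ids, labels, scheme="true_simulated")


def marker_map(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(marker_ids, chrom, pos): markers spread evenly over simulated
    chromosomes, evenly spaced 1-based positions (1 kb grid)."""
    m = config.n_markers
    n_chr = min(config.n_chromosomes, m)
    per_chr = _group_sizes(m, np.full(n_chr, 1.0 / n_chr))
    chrom = np.concatenate([np.full(c, str(i + 1)) for i, c in enumerate(per_chr)])
    pos = np.concatenate([1000 * (np.arange(c) + 1) for c in per_chr])
    ids = np.array([f"M{i:05d}" for i in range(m)])
    return ids, chrom, pos.astype(np.int64)


def simulate_allele_frequencies(
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral and per-subpopulation allele frequencies.

    Uses the same random substream as :func:`simulate_structured_genotypes`,
    so the returned frequencies are exactly those underlying the genotypes
    for the same config -- handy as ground truth in calibration checks.
    """
    config.validate()
    rng = _streams(config)[0]
    m, s = config.n_markers, config.n_subpops
    ancestral = rng.uniform(0.05, 0.95, size=m)
    if config.fst == 0.0:
        subpop = np.tile(ancestral, (s, 1))
    else:
        scale = (1.0 - config.fst) / config.fst
        subpop = rng.beta(ancestral * scale, (1.0 - ancestral) * scale, size=(s, m))
    return ancestral, subpop


def _simulate_haplotypes(
    rng: np.random.Generator,
    freqs: np.ndarray,
    n_hap: int,
    chrom: np.ndarray,
    ld_rho: float,
) -> np.ndarray:
    """First-order Markov haplotypes; chain restarts at chromosome starts."""
    m = len(freqs)
    H = np.empty((n_hap, m), dtype=np.int8)
    fresh = rng.random((n_hap, m)) < freqs
    if ld_rho > 0.0:
        copy = rng.random((n_hap, m)) < ld_rho
    for k in range(m):
        new_chrom = k == 0 or chrom[k] != chrom[k - 1]
        if ld_rho == 0.0 or new_chrom:
            H[:, k] = fresh[:, k]
        else:
            H[:, k] = np.where(copy[:, k], H[:, k - 1], fresh[:, k])
    return H


def simulate_structured_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate {0,1,2} dosages under Balding-Nichols structure + Markov LD."""
    config.validate()
    streams = _streams(config)
    geno_rng, miss_rng = streams[1], streams[2]
    _, subpop_freqs = simulate_allele_frequencies(config)
    partition = subpopulation_assignment(config)
    ids, chrom, pos = marker_map(config)

    dosages = np.empty((config.n_samples, config.n_markers), dtype=float)
    for i in range(config.n_subpops):
        rows = partition.members(f"pop{i + 1}")
        H = _simulate_haplotypes(
            geno_rng, subpop_freqs[i], 2 * len(rows), chrom, config.ld_rho
        )
        dosages[rows] = (H[0::2] + H[1::2]).astype(float)

    if config.missing_rate > 0.0:
        mask = miss_rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    return GenotypeMatrix(
        sample_ids=partition.sample_ids,
        marker_ids=ids,
        chrom=chrom,
        pos=pos,
        dosages=dosages,
    )


def simulate_phenotypes(
    G: GenotypeMatrix, config: SimulationConfig
) -> tuple[PhenotypeVector, TruthRecord]:
    """Additive polygenic trait on an existing genotype matrix.

    Causal markers are drawn without replacement, effects are standard
    normal, and the noise variance is calibrated on the realized genetic
    variance so the variance ratio matches ``h2`` in expectation.  The final
    affine rescale to ``trait_mean``/``trait_cv`` is applied to breeding
    values and effects too, keeping truth and phenotype on one scale.
    """
    config.validate()
    if config.n_qtl > G.n_markers:
        raise DataError("n_qtl exceeds the number of markers in G")
    rng = _streams(config)[3]
    n = G.n_samples

    D = G.dosages
    if np.isnan(D).any():
        # phenotype simulation tolerates masked calls: mean-fill per marker
        col_mean = np.nanmean(D, axis=0)
        D = np.where(np.isnan(D), col_mean, D)

    qtl = np.sort(rng.choice(G.n_markers, size=config.n_qtl, replace=False))
    effects = rng.standard_normal(config.n_qtl)
    Zq = D[:, qtl] - D[:, qtl].mean(axis=0)
    if config.qtl_effect_corr >= 1.0 or config.n_subpops == 1:
        g = Zq @ effects
    else:
        # imperfect cross-subpopulation genetic correlation: each group
        # expresses its own effect vector, correlated r_g with the shared one
        r_g = config.qtl_effect_corr
        if G.n_samples != config.n_samples:
            raise DataError(
                "qtl_effect_corr < 1 needs G simulated from the same config "
                "(subpopulation membership is taken from it)"
            )
        part = subpopulation_assignment(config)
        g = np.empty(n)
        pop_effects = np.empty((config.n_qtl, config.n_subpops))
        for i in range(config.n_subpops):
            specific = rng.standard_normal(config.n_qtl)
            pop_effects[:, i] = r_g * effects + np.sqrt(1.0 - r_g**2) * specific
            rows = part.members(f"pop{i + 1}")
            g[rows] = Zq[rows] @ pop_effects[:, i]
        effects = pop_effects.mean(axis=1)
    var_g = float(np.var(g, ddof=1)) if n > 1 else 0.0

    h2 = config.h2
    if h2 == 0.0 or var_g == 0.0:
        y_raw = rng.standard_normal(n)
        realized = 0.0
    elif h2 == 1.0:
        y_raw = g.copy()
        realized = 1.0
    else:
        var_e = var_g * (1.0 - h2) / h2
        y_raw = g + rng.normal(0.0, np.sqrt(var_e), size=n)
        realized = float(np.clip(var_g / np.var(y_raw, ddof=1), 0.0, 1.0))

    sd_raw = float(np.std(y_raw, ddof=1)) if n > 1 else 0.0
    target_sd = config.trait_cv / 100.0 * config.trait_mean
    a = target_sd / sd_raw if sd_raw > 0 else 1.0
    b = config.trait_mean - a * float(np.mean(y_raw))
    y = a * y_raw + b

    truth = TruthRecord(
        qtl_indices=qtl,
        qtl_effects=a * effects,
        true_breeding_values=a * g,
        realized_h2=realized,
    )
    pheno = PhenotypeVector(G.sample_ids, y, trait_name=config.trait_name)
    return pheno, truth


def make_benchmark_panel(
    config: SimulationConfig | None = None,
) -> tuple[GenotypeMatrix, PhenotypeVector, TruthRecord, PopulationPartition]:
    """One-call bundle: genotypes, trait, truth, true subpopulation labels."""
    cfg = benchmark_config() if config is None else config
    G = simulate_structured_genotypes(cfg)
    y, truth = simulate_phenotypes(G, cfg)
    partition = subpopulation_assignment(cfg)
    return G, y, truth, partition


__all__ = [
    "BENCHMARK_SUBPOP_COUNTS",
    "SimulationConfig",
    "TruthRecord",
    "benchmark_config",
    "make_benchmark_panel",
    "marker_map",
    "simulate_allele_frequencies",
    "simulate_phenotypes",
    "simulate_structured_genotypes",
    "subpopulation_assignment",
]
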