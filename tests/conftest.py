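import numpy as np
import pytest

from soygs.datatypes import GenotypeMatrix, PhenotypeVector
from soygs import io, simulate
from soygs.datatypes import align


def toy_genotypes(dosages, chrom=None, pos=None):
    """GenotypeMatrix from a plain array with auto IDs."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        marker_ids=[f"m{j}" for j in range(m)],
        chrom=chrom if chrom is not None else ["1"] * m,
        pos=pos if pos is not None else np.arange(1, m + 1),
        dosages=dosages,
    )


def toy_phenotype(values, ids=None, name="trait"):
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = [f"s{i}" for i in range(len(values))]
    return PhenotypeVector(ids, values, name)


def random_instance(rng, n=None, m=None, noise=1.0, effect_sd=None):
    """Small random genotype/phenotype instance from a mixed-model draw."""
    n = n or int(rng.integers(12, 31))
    m = m or int(rng.integers(5, 61))
    D = rng.integers(0, 3, size=(n, m)).astype(float)
    Z = D - D.mean(axis=0)
    if effect_sd is None:
        tr = np.trace(Z @ Z.T) / n
        effect_sd = 1.0 / np.sqrt(max(tr, 1e-9))
    y = Z @ rng.normal(0.0, effect_sd, m) + rng.normal(0.0, noise, n)
    return toy_genotypes(D), toy_phenotype(y)


@pytest.fixture(scope="session")
def small_panel():
    """A filtered, imputed 2-subpopulation panel with a h2=0.5 trait."""
    cfg = simulate.SimulationConfig(
        n_samples=200, n_markers=600, n_subpops=2, fst=0.2, ld_rho=0.3,
        n_qtl=40, h2=0.5, seed=20,
    )
    G, y, truth, part = simulate.make_benchmark_panel(cfg)
    G = io.impute_missing_mean(io.maf_filter(G))
    G, y = align(G, y)
    return G, y, truth, part, cfg
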