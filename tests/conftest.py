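import numpy as np
import pandas as pd
import pytest

from germdrug import (EffectPlan, GenotypePanel, PanelConfig, kinship_eigh,
                      realized_relatedness, simulate_genotypes, simulate_panel)


@pytest.fixture(scope="session")
def small_panel():
    """Structured LD panel: 300 samples, 200 variants in blocks of 10."""
    return simulate_genotypes(PanelConfig(
        n_samples=300, n_variants=200, ld_block_size=10, within_block_r=0.7,
        n_chromosomes=4, seed=101))


@pytest.fixture(scope="session")
def independent_panel():
    """Unstructured panel: every variant independent (no LD, one subpop)."""
    return simulate_genotypes(PanelConfig(
        n_samples=500, n_variants=300, ld_block_size=1, within_block_r=0.0,
        n_chromosomes=3, seed=202))


@pytest.fixture(scope="session")
def independent_eig(independent_panel):
    return kinship_eigh(realized_relatedness(independent_panel))


@pytest.fixture(scope="session")
def planted_panel():
    """Panel with one planted germline effect, one somatic effect and a null
    drug; used across QTL/pipeline tests."""
    plans = {
        "germ_drug": EffectPlan(germline_causal=[(30, 0.6)], noise_sd=1.0),
        "som_drug": EffectPlan(somatic_causal=[(3, 1.0)], noise_sd=1.0),
        "null_drug": EffectPlan(noise_sd=1.0),
    }
    cfg = PanelConfig(n_samples=300, n_variants=300, ld_block_size=10,
                      within_block_r=0.7, n_subpops=2, fst_like_divergence=0.05,
                      n_chromosomes=5, seed=303)
    return simulate_panel(cfg, plans)


def manual_panel(dosages, chrom=None, pos=None):
    """Hand-built GenotypePanel for targeted filter tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = chrom if chrom is not None else ["chr1"] * m
    pos = pos if pos is not None else [1000 * (j + 1) for j in range(m)]
    with np.errstate(invalid="ignore"):
        af = np.nanmean(dosages, axis=0) / 2.0
    variants = pd.DataFrame({
        "id": [f"v{j}" for j in range(m)], "chrom": chrom, "pos": pos,
        "ref": "A", "alt": "G", "af": af})
    samples = pd.DataFrame(index=pd.Index([f"s{i}" for i in range(n)],
                                          name="sample"))
    return GenotypePanel(dosages, variants, samples)
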