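"""Synthetic cell-line panel generator.

Emulates the statistical structure of a pharmacogenomic cell-line screen:

* germline dosage genotypes with block-wise linkage disequilibrium (LD),
  generated by a latent-Gaussian threshold (copula) model on haplotypes;
* population structure, with subpopulation allele frequencies drifting from a
  shared ancestral frequency by a Balding-Nichols beta draw;
* binary somatic driver markers, independent of the germline layer;
* tissue-confounded gene expression;
* bounded drug-susceptibility phenotypes (1-AUC units) with additive
  germline, somatic, tissue, interaction, polygenic and noise components.

The copula is calibrated so that the realized dosage correlation between
adjacent variants in a block matches the requested ``within_block_r``: the
latent haplotype correlation is solved from the bivariate-normal orthant
probability so that the implied binary-allele correlation equals the target.
Because a sample's dosage is the sum of two independent haplotypes, the
dosage correlation equals the allele correlation, hence realized adjacent
r^2 ~ within_block_r^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypePanel, PhenotypeTable

__all__ = [
    "PanelConfig",
    "EffectPlan",
    "SyntheticPanel",
    "latent_rho_for_target",
    "simulate_genotypes",
    "simulate_molecular_layers",
    "simulate_drug_response",
    "simulate_panel",
]


@dataclass
class PanelConfig:
    """Configuration of a synthetic genotype panel.

    ``fst_like_divergence`` plays the role of Wright's F_ST in the
    Balding-Nichols model: subpopulation allele frequencies are drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p.
    """

    n_samples: int = 500
    n_variants: int = 1000
    ld_block_size: int = 10
    within_block_r: float = 0.8
    maf_range: tuple[float, float] = (0.02, 0.5)
    n_subpops: int = 1
    fst_like_divergence: float = 0.0
    n_tissues: int = 3
    n_somatic: int = 20
    n_expression_genes: int = 10
    n_chromosomes: int = 5
    somatic_prevalence: tuple[float, float] = (0.05, 0.3)
    variant_spacing_bp: int = 5_000
    dosage_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.within_block_r < 1.0):
            raise ValueError("within_block_r must lie in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if self.fst_like_divergence < 0:
            raise ValueError("fst_like_divergence must be nonnegative")
        plo, phi = self.somatic_prevalence
        if not (0.0 < plo <= phi < 1.0):
            raise ValueError("somatic_prevalence bounds must lie in (0, 1)")


@dataclass
class EffectPlan:
    """Generative effect plan for one simulated drug.

    Germline effects apply to *standardized* dosages, so an effect beta
    contributes variance ~beta^2 when the causal variants are uncorrelated.
    ``interaction`` is (variant index, expression-gene index, effect size) on
    the product of standardized dosage and standardized expression.
    """

    germline_causal: list[tuple[int, float]] = field(default_factory=list)
    somatic_causal: list[tuple[int, float]] = field(default_factory=list)
    tissue_effects: dict[str, float] = field(default_factory=dict)
    interaction: tuple[int, int, float] | None = None
    polygenic_sd: float = 0.0
    noise_sd: float = 1.0

    def validate(self, n_variants: int, n_somatic: int, n_genes: int) -> None:
        for i, _ in self.germline_causal:
            if not 0 <= i < n_variants:
                raise IndexError(f"germline causal index {i} out of range")
        for j, _ in self.somatic_causal:
            if not 0 <= j < n_somatic:
                raise IndexError(f"somatic causal index {j} out of range")
        if self.interaction is not None:
            i, g, _ = self.interaction
            if not 0 <= i < n_variants:
                raise IndexError(f"interaction variant index {i} out of range")
            if not 0 <= g < n_genes:
                raise IndexError(f"interaction gene index {g} out of range")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SyntheticPanel:
    """Bundle of all simulated layers sharing one sample axis."""

    genotypes: GenotypePanel
    somatic: pd.DataFrame
    expression: pd.DataFrame
    tissues: pd.Series
    phenotypes: PhenotypeTable
    truth: dict[str, EffectPlan]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _binary_corr(rho: float, t: float, p: float) -> float:
    # correlation of two Bernoulli(p) indicators 1{z < t} under latent corr rho
    mvn = stats.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]],
                                    allow_singular=True)
    return float((mvn.cdf([t, t]) - p * p) / (p * (1.0 - p)))


def latent_rho_for_target(target_r: float, p: float) -> float:
    """Latent Gaussian correlation whose thresholded binary correlation at
    allele frequency ``p`` equals ``target_r``.  Clipped to [0, 0.999]."""
    if target_r <= 0.0:
        return 0.0
    if target_r >= 1.0:
        raise ValueError("target correlation must be < 1")
    t = stats.norm.ppf(p)
    f = lambda r: _binary_corr(r, t, p) - target_r
    if f(0.999) < 0:
        return 0.999
    return float(optimize.brentq(f, 0.0, 0.999, xtol=1e-4))


def simulate_genotypes(config: PanelConfig) -> GenotypePanel:
    """Simulate an LD-blocked, population-structured dosage panel.

    Variants come in contiguous blocks of ``ld_block_size`` sharing one
    ancestral allele frequency; within a block, adjacent variants are coupled
    through an AR(1) latent Gaussian on each haplotype with the calibrated
    latent correlation; blocks are mutually independent.  Deterministic given
    ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.n_variants
    block_sizes = [cfg.ld_block_size] * (m // cfg.ld_block_size)
    if m % cfg.ld_block_size:
        block_sizes.append(m % cfg.ld_block_size)
    n_blocks = len(block_sizes)

    # balanced subpopulation assignment in a random order
    subpop = np.repeat(np.arange(cfg.n_subpops), -(-n // cfg.n_subpops))[:n]
    rng.shuffle(subpop)

    # per-block ancestral frequency, drifted per subpopulation
    p_anc = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n_blocks)
    F = cfg.fst_like_divergence
    if F > 0 and cfg.n_subpops > 1:
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p_sub = rng.beta(a[:, None], b[:, None], size=(n_blocks, cfg.n_subpops))
        p_sub = np.clip(p_sub, 1e-4, 1 - 1e-4)
    else:
        p_sub = np.repeat(p_anc[:, None], cfg.n_subpops, axis=1)

    rho = (latent_rho_for_target(cfg.within_block_r, float(np.median(p_anc)))
           if cfg.within_block_r > 0 else 0.0)

    dosages = np.empty((n, m))
    thresholds = stats.norm.ppf(p_sub)  # (n_blocks, n_subpops)
    col = 0
    for b, bsize in enumerate(block_sizes):
        # AR(1) latent per haplotype (n, 2, bsize)
        z = np.empty((n, 2, bsize))
        z[:, :, 0] = rng.standard_normal((n, 2))
        for j in range(1, bsize):
            z[:, :, j] = rho * z[:, :, j - 1] + np.sqrt(1 - rho * rho) * \
                rng.standard_normal((n, 2))
        t = thresholds[b, subpop][:, None, None]  # sample-specific threshold
        alleles = (z < t).astype(float)
        dosages[:, col:col + bsize] = alleles.sum(axis=1)
        col += bsize

    if cfg.dosage_mode:
        dosages = np.clip(dosages + rng.normal(0.0, 0.1, size=dosages.shape), 0.0, 2.0)

    # variant metadata: blocks laid contiguously, chromosomes round-robin by block
    chrom_of_block = np.arange(n_blocks) % cfg.n_chromosomes
    chroms, positions = [], []
    pos_counter = dict.fromkeys(range(cfg.n_chromosomes), 0)
    for b, bsize in enumerate(block_sizes):
        c = int(chrom_of_block[b])
        for _ in range(bsize):
            pos_counter[c] += 1
            chroms.append(f"chr{c + 1}")
            positions.append(pos_counter[c] * cfg.variant_spacing_bp)
    af = dosages.mean(axis=0) / 2.0
    variants = pd.DataFrame({
        "id": [f"var{i:06d}" for i in range(m)],
        "chrom": chroms,
        "pos": positions,
        "ref": "A",
        "alt": "G",
        "af": af,
    })
    samples = pd.DataFrame(
        {"subpop": [f"pop{s}" for s in subpop]},
        index=pd.Index([f"cell{i:04d}" for i in range(n)], name="sample"),
    )
    # metadata must be position-sorted within chromosome for the LD filters
    order = np.lexsort((variants["pos"].to_numpy(),
                        variants["chrom"].to_numpy()))
    return GenotypePanel(dosages[:, order],
                         variants.iloc[order].reset_index(drop=True), samples)


# ---------------------------------------------------------------------------
# somatic markers, expression, tissues
# ---------------------------------------------------------------------------

def simulate_molecular_layers(
    genotypes: GenotypePanel,
    config: PanelConfig,
    tissue_offsets: dict[int, np.ndarray] | None = None,
    tissue_effect_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate somatic markers, expression and tissue labels.

    Somatic markers are Bernoulli per marker with prevalence drawn uniformly
    from ``config.somatic_prevalence``, independent of germline genotypes.
    Expression of each gene is a per-tissue mean plus unit Gaussian noise and
    is independent of every germline variant; ``tissue_offsets`` may pin the
    per-tissue means of selected genes (gene index -> length-``n_tissues``
    offset vector).
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = genotypes.n_samples
    ids = genotypes.samples.index

    tissues = pd.Series(
        [f"tissue{t}" for t in rng.integers(cfg.n_tissues, size=n)],
        index=ids, name="tissue",
    )

    prev = rng.uniform(*cfg.somatic_prevalence, size=cfg.n_somatic)
    somatic = pd.DataFrame(
        (rng.random((n, cfg.n_somatic)) < prev).astype(int),
        index=ids, columns=[f"som{j:03d}" for j in range(cfg.n_somatic)],
    )

    means = rng.normal(0.0, tissue_effect_sd,
                       size=(cfg.n_expression_genes, cfg.n_tissues))
    if tissue_offsets:
        for g, off in tissue_offsets.items():
            means[g] = np.asarray(off, dtype=float)
    tissue_idx = tissues.str.removeprefix("tissue").astype(int).to_numpy()
    expr = means[:, tissue_idx].T + rng.standard_normal((n, cfg.n_expression_genes))
    expression = pd.DataFrame(
        expr, index=ids, columns=[f"gene{g:03d}" for g in range(cfg.n_expression_genes)],
    )
    return somatic, expression, tissues


# ---------------------------------------------------------------------------
# drug response
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        warnings.warn("constant vector standardized to zeros")
        return np.zeros_like(x)
    return (x - x.mean()) / s


def raw_response(
    genotypes: GenotypePanel,
    somatic: pd.DataFrame,
    expression: pd.DataFrame,
    tissues: pd.Series,
    plan: EffectPlan,
    rng: np.random.Generator,
    chol_K: np.ndarray | None = None,
) -> np.ndarray:
    """Unsquashed phenotype: the additive generative model on the raw scale."""
    n = genotypes.n_samples
    y = np.zeros(n)
    for t, off in plan.tissue_effects.items():
        y += np.where(tissues.to_numpy() == t, off, 0.0)
    for i, beta in plan.germline_causal:
        y += beta * _standardize(genotypes.dosages[:, i])
    for j, beta in plan.somatic_causal:
        y += beta * somatic.iloc[:, j].to_numpy(dtype=float)
    if plan.interaction is not None:
        i, g, beta = plan.interaction
        y += beta * (_standardize(genotypes.dosages[:, i])
                     * _standardize(expression.iloc[:, g].to_numpy()))
    if plan.polygenic_sd > 0:
        if chol_K is None:
            from .qtl import realized_relatedness
            K = realized_relatedness(genotypes)
            chol_K = np.linalg.cholesky(K + 1e-6 * np.eye(n))
        y += plan.polygenic_sd * (chol_K @ rng.standard_normal(n))
    y += rng.normal(0.0, plan.noise_sd, size=n)
    return y


def squash_unit_interval(y: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Affine rescale of the 0.1-99.9 percentile range onto [0, 1], clipped.

    Preserves the linear signal in the bulk while respecting 1-AUC bounds;
    the (lo, hi) pair is returned so the transform can be inverted."""
    lo, hi = np.percentile(y, [0.1, 99.9])
    if hi <= lo:
        return np.full_like(y, 0.5), (float(lo), float(hi))
    return np.clip((y - lo) / (hi - lo), 0.0, 1.0), (float(lo), float(hi))


def simulate_drug_response(
    genotypes: GenotypePanel,
    somatic: pd.DataFrame,
    expression: pd.DataFrame,
    tissues: pd.Series,
    plans: EffectPlan | dict[str, EffectPlan],
    seed: int,
) -> PhenotypeTable:
    """Simulate one phenotype row per drug from its :class:`EffectPlan`.

    phenotype = tissue offsets + sum(beta_g * standardized dosage)
              + sum(beta_s * marker) + optional interaction
              + polygenic background N(0, sd^2 K) + Gaussian noise,
    then squashed onto [0, 1]; the squash parameters are recorded per drug.
    """
    if isinstance(plans, EffectPlan):
        plans = {"drug0": plans}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    chol_K = None
    if any(p.polygenic_sd > 0 for p in plans.values()):
        from .qtl import realized_relatedness
        K = realized_relatedness(genotypes)
        chol_K = np.linalg.cholesky(K + 1e-6 * np.eye(genotypes.n_samples))
    rows, squash = {}, {}
    for drug, plan in plans.items():
        plan.validate(genotypes.n_variants, somatic.shape[1], expression.shape[1])
        y = raw_response(genotypes, somatic, expression, tissues, plan, rng, chol_K)
        rows[drug], squash[drug] = squash_unit_interval(y)
    values = pd.DataFrame(rows, index=genotypes.samples.index).T
    return PhenotypeTable(values=values, squash=squash)


def simulate_panel(
    config: PanelConfig,
    plans: EffectPlan | dict[str, EffectPlan] | None = None,
    tissue_offsets: dict[int, np.ndarray] | None = None,
) -> SyntheticPanel:
    """End-to-end convenience: genotypes, molecular layers and phenotypes."""
    genotypes = simulate_genotypes(config)
    somatic, expression, tissues = simulate_molecular_layers(
        genotypes, config, tissue_offsets=tissue_offsets)
    genotypes.samples["tissue"] = tissues
    if plans is None:
        plans = {"drug0": EffectPlan()}
    elif isinstance(plans, EffectPlan):
        plans = {"drug0": plans}
    phenotypes = simulate_drug_response(
        genotypes, somatic, expression, tissues, plans, seed=config.seed)
    return SyntheticPanel(genotypes, somatic, expression, tissues, phenotypes,
                          truth=dict(plans))
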