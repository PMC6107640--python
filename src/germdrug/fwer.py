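"""Genome-wide multiple-testing correction for QTL mapping.

Germline tests are corrected with a permutation scheme that respects LD:
for each drug, the sample axis of one chromosome's genotype block is permuted
(preserving LD among variants while breaking genotype-phenotype linkage), the
mixed-model scan is rerun, and the minimum P value recorded.  Chromosome-level
minima are extrapolated to genome scale by a Sidak-style adjustment with a
factor equal to the genome length divided by the target chromosome's length
(~15.6 for chromosome 3 on GRCh37).  Minima pooled across permutations and
drugs form an empirical null from which adjusted P values are computed.
Somatic tests, being few and LD-free, use Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qtl import KinshipEigen, lmm_scan

__all__ = [
    "GRCH37_LENGTHS",
    "NullDistribution",
    "genome_extrapolation_factor",
    "permutation_min_p",
    "extrapolate_pvalue",
    "empirical_adjusted_p",
    "bonferroni_adjust",
    "call_significant",
]

#: GRCh37 primary-assembly chromosome lengths in base pairs.
GRCH37_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}


@dataclass
class NullDistribution:
    """Pooled genome-wide-extrapolated minimum P values across permutations
    and drugs, with per-drug contribution counts."""

    values: np.ndarray
    counts_per_drug: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and ((self.values < 0).any() or (self.values > 1).any()):
            raise ValueError("null P values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return int(self.values.size)


def genome_extrapolation_factor(lengths: dict[str, int], target_chromosome: str
                                ) -> float:
    """(total genome length) / (target chromosome length); >= 1."""
    if target_chromosome not in lengths:
        raise KeyError(f"chromosome {target_chromosome!r} not in lengths table")
    for c, L in lengths.items():
        if L <= 0:
            raise ValueError(f"non-positive length for chromosome {c!r}")
    return float(sum(lengths.values()) / lengths[target_chromosome])


def permutation_min_p(
    y,
    W,
    eig: KinshipEigen,
    chr_genotypes: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Chromosome-level minimum P values under genotype permutation.

    Each permutation applies one random permutation of the sample axis to the
    *entire* chromosome genotype block (preserving LD among variants) and
    reruns :func:`lmm_scan`; the phenotype, covariates and kinship stay fixed.
    Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    chr_genotypes = np.asarray(chr_genotypes, dtype=float)
    if chr_genotypes.ndim != 2 or chr_genotypes.shape[1] == 0:
        raise ValueError("chromosome genotype block must be nonempty 2-D")
    rng = np.random.default_rng(seed)
    n = chr_genotypes.shape[0]
    out = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        res = lmm_scan(y, W, chr_genotypes[perm], eig)
        out[k] = np.nanmin(res["p_value"].to_numpy())
    return out


def extrapolate_pvalue(p_chr, factor: float, method: str = "quantile"):
    """Map a chromosome-level minimum P value to the genome-wide scale.

    Treating the genome as ``factor`` independent copies of the chromosome,
    the genome-wide minimum is the minimum of ``factor`` chromosome-level
    minima.  If the chromosome minimum is the smallest of E effective uniform
    tests, its CDF is 1-(1-t)^E and the genome minimum's is 1-(1-t)^(E*C);
    quantile-matching a chromosome draw m to the genome distribution gives

        p_gw = 1 - (1 - m)^(1/factor)  ~  m / factor for small m,

    independent of E.  Null chromosome minima extrapolated this way are
    directly comparable to an observed genome-wide minimum P value.
    ``linear`` uses the small-p tail approximation p / factor.
    """
    p = np.asarray(p_chr, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P values must lie in [0, 1]")
    if factor < 1:
        raise ValueError("extrapolation factor must be >= 1")
    if method == "quantile":
        with np.errstate(divide="ignore"):
            out = -np.expm1(np.log1p(-p) / factor)
    elif method == "linear":
        out = p / factor
    else:
        raise ValueError(f"unknown method {method!r}")
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(p_chr) or np.ndim(p_chr) == 0 else out


def empirical_adjusted_p(observed_min_p_gw: float, null: NullDistribution) -> float:
    """Add-one empirical P: (1 + #{null <= observed}) / (1 + N)."""
    if null.n == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.count_nonzero(null.values <= observed_min_p_gw))
                 / (1 + null.n))


def bonferroni_adjust(p: float, n_tests: int) -> float:
    if not 0.0 <= p <= 1.0:
        raise ValueError("P value must lie in [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(min(1.0, p * n_tests))


def call_significant(records: pd.DataFrame, fwer: float = 0.05) -> pd.DataFrame:
    """Flag per-drug, per-test-type lead associations at the FWER threshold.

    ``records`` needs columns ``drug, test_type, adjusted_p`` and, for
    germline rows, ``ld_confirmed`` (the post-hoc LD check): a germline lead
    failing it is excluded regardless of its P value.
    """
    req = {"drug", "test_type", "adjusted_p"}
    if not req.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    rec = records.copy()
    sig = rec["adjusted_p"] < fwer
    if "ld_confirmed" in rec.columns:
        germline = rec["test_type"] == "germline"
        sig &= ~germline | rec["ld_confirmed"].fillna(False).astype(bool)
    rec["significant"] = sig
    return rec
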