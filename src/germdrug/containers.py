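"""Shared in-memory containers for cell-line panel data.

The analyses operate on four aligned objects: a genotype dosage matrix with
per-variant metadata (:class:`GenotypePanel`), a binary somatic marker matrix
(plain :class:`pandas.DataFrame`, samples x markers), a drugs x samples
phenotype table in 1-AUC units (:class:`PhenotypeTable`) and per-sample
covariates (tissue labels).  All share the sample axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ("id", "chrom", "pos", "ref", "alt", "af")


@dataclass
class GenotypePanel:
    """Samples x variants dosage matrix plus variant and sample metadata.

    Parameters
    ----------
    dosages
        Array of shape ``(n_samples, n_variants)`` with values in ``[0, 2]``
        (hard calls in ``{0, 1, 2}`` unless dosage mode was used); missing
        entries are ``NaN``.
    variants
        One row per variant with columns ``id, chrom, pos, ref, alt, af``
        (``pos`` 1-based, ``af`` alternate-allele frequency).
    samples
        One row per sample, indexed by sample id; may carry ``tissue`` and
        ``subpop`` columns.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValueError(f"sample metadata has {len(self.samples)} rows, dosages {n}")
        if len(self.variants) != m:
            raise ValueError(f"variant metadata has {len(self.variants)} rows, dosages {m}")
        missing = [c for c in VARIANT_COLUMNS[:5] if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant metadata missing columns: {missing}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def subset_variants(self, mask_or_idx) -> "GenotypePanel":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(
            self.dosages[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            self.samples,
        )

    def subset_samples(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(self.dosages[idx], self.variants, self.samples.iloc[idx])

    def variant_index(self, variant_id: str) -> int:
        hits = np.flatnonzero(self.variants["id"].to_numpy() == variant_id)
        if hits.size == 0:
            raise KeyError(f"variant {variant_id!r} not in panel")
        return int(hits[0])


@dataclass
class PhenotypeTable:
    """Drugs x samples drug-susceptibility table in 1-AUC units.

    ``values`` is a DataFrame indexed by drug id with sample-id columns;
    entries lie in [0, 1] (higher = more sensitive).  ``squash`` records, per
    drug, the affine map (lo, hi) used to place a raw simulated phenotype on
    the 1-AUC scale, so the transform is invertible on the unclipped bulk.
    """

    values: pd.DataFrame
    squash: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def drugs(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def drug_vector(self, drug: str) -> np.ndarray:
        return self.values.loc[drug].to_numpy(dtype=float)


def validate_kinship(K: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Validate a realized-relatedness matrix: symmetric, PSD (to ``tol``),
    mean diagonal ~1.  Returns the symmetrized matrix."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kinship matrix must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("kinship matrix must be symmetric")
    K = 0.5 * (K + K.T)
    w = np.linalg.eigvalsh(K)
    if w.min() < -tol:
        raise ValueError(f"kinship matrix not PSD (min eigenvalue {w.min():.3g})")
    return K
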