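"""Variant quality control and germline-authenticity filtering.

Common inherited variants sit in local linkage disequilibrium with their
neighbours, whereas somatic artefacts in a cell-line panel do not.  The
authenticity filter exploits this: after a minor-allele-frequency cut, a
variant is kept only if it is in LD (r^2 above a threshold) with at least one
of its nearest neighbouring variants on the same chromosome.  A related
post-hoc check confirms that a putative germline QTL has at least one LD
partner within a base-pair window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypePanel

__all__ = [
    "FilterReport",
    "allele_frequency",
    "pairwise_r2",
    "maf_filter",
    "germline_authenticity_filter",
    "confirm_qtl_ld",
    "reference_af_concordance",
]


@dataclass
class FilterReport:
    """Funnel counts for the QC filter chain (monotone by construction)."""

    n_input: int
    n_after_maf: int
    n_after_ld: int
    removed_ids: list[str] = field(default_factory=list)
    retained_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.n_input >= self.n_after_maf >= self.n_after_ld >= 0):
            raise ValueError("filter funnel must be monotone non-increasing")


def allele_frequency(dosages) -> tuple[float, float]:
    """Alternate-allele frequency and MAF from dosages in [0, 2].

    Missing entries (NaN) are ignored; an all-missing variant is unusable.
    """
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    if not ok.any():
        raise ValueError("all dosages missing: variant unusable")
    af = float(d[ok].mean() / 2.0)
    return af, min(af, 1.0 - af)


def pairwise_r2(x, y, *, return_flag: bool = False):
    """Squared Pearson correlation over pairwise-complete entries.

    A constant vector leaves the correlation undefined; it is reported as 0.0
    with ``flag=False`` (and a warning) rather than raising, so bulk LD scans
    can proceed past monomorphic variants.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        warnings.warn("r^2 undefined (constant or too-short vector); reported as 0")
        return (0.0, False) if return_flag else 0.0
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(min(r * r, 1.0))
    return (r2, True) if return_flag else r2


def maf_filter(panel: GenotypePanel, maf_min: float = 0.02,
               max_missing: float = 0.10) -> np.ndarray:
    """Boolean mask of variants passing missingness and MAF thresholds."""
    d = panel.dosages
    miss = np.isnan(d).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        af = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    return (miss <= max_missing) & (maf > maf_min) & ~np.isnan(af)


def _check_sorted(variants: pd.DataFrame) -> None:
    for _, grp in variants.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError("variants must be sorted by (chromosome, position)")


def _neighbour_order(pos: np.ndarray, i: int, window: int) -> np.ndarray:
    """Indices of up to ``window`` nearest neighbours of variant ``i`` on one
    chromosome, pooled across both sides, nearest first."""
    dist = np.abs(pos - pos[i])
    dist[i] = np.iinfo(np.int64).max  # exclude self
    order = np.argsort(dist, kind="stable")[: min(window, pos.size - 1)]
    return order


def germline_authenticity_filter(
    panel: GenotypePanel,
    window_snps: int = 50,
    r2_min: float = 0.4,
    maf_min: float = 0.02,
    max_missing: float = 0.10,
) -> FilterReport:
    """MAF cut followed by the LD-authenticity cut.

    After removing variants with MAF <= ``maf_min`` (or missingness above
    ``max_missing``), a variant is retained iff its maximum r^2 against the
    nearest ``window_snps`` surviving variants on the same chromosome (both
    sides pooled, nearest by base-pair distance first) reaches ``r2_min``.
    Requires position-sorted variants.
    """
    _check_sorted(panel.variants)
    n_input = panel.n_variants
    ids = panel.variants["id"].to_numpy()

    keep_maf = maf_filter(panel, maf_min=maf_min, max_missing=max_missing)
    n_after_maf = int(keep_maf.sum())
    sub = panel.subset_variants(keep_maf)

    d = sub.dosages
    has_missing = np.isnan(d).any()
    if not has_missing:
        centred = d - d.mean(axis=0)
        norms = np.sqrt((centred ** 2).sum(axis=0))

    keep_ld = np.zeros(sub.n_variants, dtype=bool)
    for chrom, grp in sub.variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy().copy()
        for local_i, gi in enumerate(idx):
            for local_j in _neighbour_order(pos, local_i, window_snps):
                gj = idx[local_j]
                if has_missing:
                    r2 = pairwise_r2(d[:, gi], d[:, gj])
                else:
                    denom = norms[gi] * norms[gj]
                    if denom == 0:
                        continue
                    r = float(centred[:, gi] @ centred[:, gj]) / denom
                    r2 = r * r
                if r2 >= r2_min:
                    keep_ld[gi] = True
                    break

    retained = set(sub.variants.loc[keep_ld, "id"])
    removed = [v for v in ids if v not in retained]
    return FilterReport(
        n_input=n_input,
        n_after_maf=n_after_maf,
        n_after_ld=int(keep_ld.sum()),
        removed_ids=removed,
        retained_ids=[v for v in ids if v in retained],
    )


def confirm_qtl_ld(
    variant_id: str,
    panel: GenotypePanel,
    window_bp: int = 100_000,
    r2_min: float = 0.4,
) -> bool:
    """True iff some *other* variant within +/- ``window_bp`` on the same
    chromosome has r^2 >= ``r2_min`` with the lead variant.  Used to rule out
    somatic contamination of putative germline QTLs."""
    i = panel.variant_index(variant_id)
    v = panel.variants.iloc[i]
    near = panel.variants[
        (panel.variants["chrom"] == v["chrom"])
        & (np.abs(panel.variants["pos"] - v["pos"]) <= window_bp)
        & (panel.variants.index != i)
    ]
    x = panel.dosages[:, i]
    for j in near.index:
        if pairwise_r2(x, panel.dosages[:, j]) >= r2_min:
            return True
    return False


def reference_af_concordance(
    observed: float, reference: float, max_abs_diff: float
) -> tuple[bool, float]:
    """Compare an observed allele frequency to a reference population's.

    Frequencies are aligned to the minor allele before differencing, so a
    flipped allele coding (e.g. 0.72 vs 0.30) still scores as concordant.
    Returns (pass, |difference|).
    """
    for f in (observed, reference):
        if not 0.0 <= f <= 1.0:
            raise ValueError("frequencies must lie in [0, 1]")
    diff = abs(min(observed, 1.0 - observed) - min(reference, 1.0 - reference))
    return diff <= max_abs_diff, diff
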