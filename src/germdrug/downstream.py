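"""Post-QTL analyses: colocalization with eQTLs, proxy-based replication,
and genotype x expression interaction with stratified response profiles.

Colocalization is scored as the Pearson correlation between matched
-log10(P) association profiles of drug response and gene expression over a
shared variant set.  Replication re-tests discovery (variant, drug) pairs
with the same association machinery, adjusts with Benjamini-Hochberg, and
requires effect-direction concordance.  The interaction analysis tests the
product term expression x genotype-group in a linear model containing the
main effects, with the genotype coded as a binary functional group by
default (e.g. CC/CT carriers of a functional allele vs the loss-of-function
homozygote).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import GenotypePanel
from .filters import pairwise_r2
from .qtl import KinshipEigen, lm_association, lmm_association

__all__ = [
    "ReplicationPair",
    "InteractionResult",
    "bh_adjust",
    "select_proxy",
    "coloc_call",
    "replicate_candidates",
    "interaction_test",
    "stratified_profile",
    "boxplot_outliers",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_proxy(
    lead_id: str,
    candidate_ids,
    panel: GenotypePanel,
    window_bp: int = 1_000_000,
    r2_min: float = 0.8,
) -> tuple[str, float] | None:
    """Best-LD proxy for a lead variant among candidates on its chromosome.

    Returns (proxy id, r^2) for the candidate with maximum r^2 to the lead
    within ``window_bp``, or None if the best falls below ``r2_min``.  The
    lead itself, if among the candidates, wins with r^2 = 1.  Ties go to the
    smallest position.
    """
    i = panel.variant_index(lead_id)
    lead = panel.variants.iloc[i]
    x = panel.dosages[:, i]
    cand = set(candidate_ids)
    if lead_id in cand:
        return lead_id, 1.0
    best: tuple[str, float, int] | None = None
    for j, row in panel.variants.iterrows():
        if row["id"] not in cand or row["chrom"] != lead["chrom"]:
            continue
        if abs(row["pos"] - lead["pos"]) > window_bp:
            continue
        r2 = pairwise_r2(x, panel.dosages[:, j])
        if best is None or r2 > best[1] + 1e-12 or \
                (abs(r2 - best[1]) <= 1e-12 and row["pos"] < best[2]):
            best = (row["id"], r2, int(row["pos"]))
    if best is None or best[1] < r2_min:
        return None
    return best[0], best[1]


def coloc_call(drug_logp, eqtl_logp, corr_min: float = 0.8
               ) -> tuple[float, bool]:
    """Colocalization call from matched -log10(P) profiles.

    Returns (Pearson correlation, colocalized), colocalized iff correlation
    strictly exceeds ``corr_min``; a constant profile leaves the correlation
    undefined (NaN) and the call negative.
    """
    a = np.asarray(drug_logp, dtype=float)
    b = np.asarray(eqtl_logp, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("profiles must be matched and of length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant -log10 P profile: correlation undefined")
        return float("nan"), False
    r = float(np.corrcoef(a, b)[0, 1])
    return r, bool(r > corr_min)


@dataclass
class ReplicationPair:
    drug: str
    variant: str
    proxy: str | None
    r2_lead_proxy: float
    discovery_beta: float | None
    replication_beta: float = np.nan
    replication_p: float = np.nan
    adjusted_p: float = np.nan
    status: str = "skipped"  # replicated | not_replicated | skipped
    skip_reason: str | None = None


def replicate_candidates(
    pairs,
    panel: GenotypePanel,
    phenotypes,
    W=None,
    eig: KinshipEigen | None = None,
    fdr: float = 0.20,
    maf_min: float = 0.02,
) -> list[ReplicationPair]:
    """Re-test discovery (variant, drug[, beta]) pairs in a replication panel.

    Pairs whose variant is absent or below ``maf_min``, or whose drug is
    missing from the phenotype table, are skipped (not failed).  Tested pairs
    are BH-adjusted jointly; a pair replicates iff adjusted P < ``fdr`` and,
    when a discovery effect direction was supplied, the replication effect
    has the same sign.  Germline tests use the kinship LMM when ``eig`` is
    given, the plain linear model otherwise.
    """
    results: list[ReplicationPair] = []
    tested_idx: list[int] = []
    for pair in pairs:
        variant, drug = pair[0], pair[1]
        disc_beta = pair[2] if len(pair) > 2 else None
        rp = ReplicationPair(drug=drug, variant=variant, proxy=variant,
                             r2_lead_proxy=1.0, discovery_beta=disc_beta)
        if drug not in phenotypes.drugs:
            rp.skip_reason = "drug not in replication screen"
            results.append(rp)
            continue
        try:
            i = panel.variant_index(variant)
        except KeyError:
            rp.skip_reason = "variant not in replication panel"
            results.append(rp)
            continue
        x = panel.dosages[:, i]
        af = np.nanmean(x) / 2.0
        if min(af, 1 - af) < maf_min:
            rp.skip_reason = f"MAF {min(af, 1 - af):.3f} below {maf_min}"
            results.append(rp)
            continue
        y = phenotypes.drug_vector(drug)
        if eig is not None:
            rec = lmm_association(y, W, x, eig=eig, drug=drug, variant=variant)
        else:
            rec = lm_association(y, W, x, drug=drug, variant=variant)
        rp.replication_beta = rec.beta
        rp.replication_p = rec.p_value
        rp.status = "not_replicated"
        tested_idx.append(len(results))
        results.append(rp)
    if tested_idx:
        adj = bh_adjust([results[i].replication_p for i in tested_idx])
        for i, a in zip(tested_idx, adj):
            rp = results[i]
            rp.adjusted_p = float(a)
            direction_ok = (rp.discovery_beta is None
                            or np.sign(rp.replication_beta) == np.sign(rp.discovery_beta))
            if a < fdr and direction_ok:
                rp.status = "replicated"
    return results


@dataclass
class InteractionResult:
    drug: str
    variant: str
    gene: str
    beta_interaction: float
    p_value: float
    profile: pd.DataFrame | None = field(default=None, repr=False)


def interaction_test(
    y,
    expr,
    geno,
    W=None,
    coding: str = "group",
    drug: str = "drug",
    variant: str = "variant",
    gene: str = "gene",
    n_bins: int = 4,
) -> InteractionResult:
    """LR test of the expression x genotype product term.

    The model contains intercept, covariates W, the expression and genotype
    main effects, and their product; the product coefficient is tested with a
    chi^2(1) likelihood-ratio test.  ``coding='group'`` dichotomizes the
    genotype as functional-allele carriers (dosage < 2) vs loss-of-function
    homozygotes (dosage == 2); ``coding='additive'`` uses the 0/1/2 dosage.
    """
    y = np.asarray(y, dtype=float)
    expr = np.asarray(expr, dtype=float)
    geno = np.asarray(geno, dtype=float)
    if np.std(expr) == 0:
        raise ValueError("expression vector is constant")
    if coding == "group":
        g = (geno < 2).astype(float)  # 1 = carries a functional allele
        for label, mask in (("functional (dosage<2)", g == 1),
                            ("homozygous-alternate", g == 0)):
            if not mask.any():
                raise ValueError(f"empty genotype group: {label}")
    elif coding == "additive":
        g = geno
    else:
        raise ValueError(f"unknown coding {coding!r}")
    base = [expr, g]
    if W is not None and np.size(W):
        Wm = np.atleast_2d(np.asarray(W, dtype=float))
        if Wm.shape[0] != y.size:
            Wm = Wm.T
        base = [Wm[:, j] for j in range(Wm.shape[1])] + base
    W_full = np.column_stack(base)
    rec = lm_association(y, W_full, expr * g, drug=drug, variant=variant)
    prof = stratified_profile(y, expr, g, n_bins=n_bins)
    return InteractionResult(drug=drug, variant=variant, gene=gene,
                             beta_interaction=rec.beta, p_value=rec.p_value,
                             profile=prof)


def stratified_profile(y, expr, geno_groups, n_bins: int = 4) -> pd.DataFrame:
    """Mean response +/- SEM per (expression quantile bin, genotype group).

    Bins are quantiles of the pooled expression values; empty cells appear
    with n = 0 and missing mean/SEM.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 expression bins")
    y = np.asarray(y, dtype=float)
    expr = np.asarray(expr, dtype=float)
    groups = pd.Series(geno_groups).astype(str).to_numpy()
    bins = pd.qcut(expr, q=n_bins, labels=False, duplicates="drop")
    rows = []
    for b in range(int(np.nanmax(bins)) + 1):
        for grp in sorted(set(groups)):
            mask = (bins == b) & (groups == grp)
            n = int(mask.sum())
            if n == 0:
                rows.append({"bin": b, "group": grp, "n": 0,
                             "mean": np.nan, "sem": np.nan})
            else:
                vals = y[mask]
                sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
                rows.append({"bin": b, "group": grp, "n": n,
                             "mean": float(vals.mean()), "sem": sem})
    return pd.DataFrame(rows)


def boxplot_outliers(x) -> np.ndarray:
    """Tukey box-plot outlier mask: outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]
    with linear-interpolation (type-7) quartiles."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
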