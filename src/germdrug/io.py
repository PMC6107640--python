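"""Readers, writers and the end-to-end pipeline driver.

Formats: minimal VCF (GT-encoded hard calls, read via cyvcf2), a TSV dosage
dialect (variant metadata columns + one column per sample, ``NA`` missing),
TSV matrices for somatic/expression/phenotype/covariate tables, and JSON for
truth sidecars, filter reports and the run manifest.  Coordinates are
1-based inclusive throughout, as in VCF.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypePanel, PhenotypeTable
from .filters import confirm_qtl_ld, germline_authenticity_filter
from .fwer import (NullDistribution, bonferroni_adjust, call_significant,
                   empirical_adjusted_p, extrapolate_pvalue,
                   genome_extrapolation_factor, permutation_min_p)
from .prediction import evaluate_repeated_cv
from .qtl import (effect_size_original_scale, kinship_eigh, lm_scan, lmm_scan,
                  quantile_normalize, realized_relatedness, tissue_covariates)
from .synthetic import EffectPlan, PanelConfig, simulate_panel

__all__ = [
    "load_genotypes",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "load_matrix_tsv",
    "write_matrix_tsv",
    "load_phenotypes_tsv",
    "write_phenotypes_tsv",
    "align_samples",
    "lengths_from_panel",
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
]

logger = logging.getLogger("germdrug")

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1"}


# ---------------------------------------------------------------------------
# genotype formats
# ---------------------------------------------------------------------------

def write_genotypes_vcf(panel: GenotypePanel, path) -> None:
    """Minimal VCF 4.2 with genotypes encoded as GT hard calls.

    Continuous dosages are rounded to the nearest hard call; missing entries
    become ``./.``.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=germdrug\n")
        for chrom in pd.unique(panel.variants["chrom"]):
            mx = panel.variants.loc[panel.variants["chrom"] == chrom, "pos"].max()
            fh.write(f"##contig=<ID={chrom},length={int(mx) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        for j, row in panel.variants.iterrows():
            calls = []
            for d in panel.dosages[:, j]:
                calls.append("./." if np.isnan(d)
                             else _GT_CODES[int(round(min(max(d, 0), 2)))])
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t"
                     f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def _load_vcf(path, multiallelic: str) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")
    rows, dosage_rows = [], []
    n_skipped_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            if multiallelic == "skip":
                n_skipped_multi += 1
                continue
            raise ValueError(f"{path}: multi-allelic site at "
                             f"{v.CHROM}:{v.POS} (policy: error)")
        gt = np.asarray(v.gt_types, dtype=float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        dosage_rows.append(dos)
        rows.append({"id": v.ID or f"{v.CHROM}:{v.POS}", "chrom": v.CHROM,
                     "pos": v.POS, "ref": v.REF, "alt": v.ALT[0]})
    if n_skipped_multi:
        logger.info("skipped %d multi-allelic site(s)", n_skipped_multi)
    if not rows:
        raise ValueError(f"{path}: no usable variant records")
    dosages = np.column_stack(dosage_rows) if dosage_rows else np.empty((len(samples), 0))
    variants = pd.DataFrame(rows)
    with np.errstate(invalid="ignore"):
        variants["af"] = np.nanmean(dosages, axis=0) / 2.0
    samples_df = pd.DataFrame(index=pd.Index(samples, name="sample"))
    return GenotypePanel(dosages, variants, samples_df)


def write_genotypes_tsv(panel: GenotypePanel, path) -> None:
    """TSV dosage dialect: metadata columns id/chrom/pos/ref/alt, then one
    dosage column per sample; missing written as ``NA``."""
    meta = panel.variants[["id", "chrom", "pos", "ref", "alt"]]
    dosage_cols = pd.DataFrame(panel.dosages.T, columns=panel.sample_ids,
                               index=meta.index)
    pd.concat([meta, dosage_cols], axis=1).to_csv(path, sep="\t", index=False,
                                                  na_rep="NA")


def _load_tsv_genotypes(path) -> GenotypePanel:
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise ValueError(f"{path}: malformed TSV genotype file: {exc}") from exc
    meta_cols = ["id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns")
    dosages = df[sample_cols].to_numpy(dtype=float).T
    variants = df[meta_cols].copy()
    with np.errstate(invalid="ignore"):
        variants["af"] = np.nanmean(dosages, axis=0) / 2.0
    samples_df = pd.DataFrame(index=pd.Index(sample_cols, name="sample"))
    return GenotypePanel(dosages, variants.reset_index(drop=True), samples_df)


def load_genotypes(path, fmt: str | None = None, multiallelic: str = "skip"
                   ) -> GenotypePanel:
    """Load a genotype panel from VCF or the TSV dosage dialect.

    ``fmt`` is inferred from the extension when omitted.  Multi-allelic VCF
    sites are skipped (counted) or rejected per ``multiallelic``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "tsv"
    if fmt == "vcf":
        return _load_vcf(path, multiallelic)
    if fmt == "tsv":
        return _load_tsv_genotypes(path)
    raise ValueError(f"unsupported genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# simple matrices
# ---------------------------------------------------------------------------

def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


def load_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.shape[1] == 0:
        raise ValueError(f"{path}: matrix has no data columns")
    return df


def write_phenotypes_tsv(phenotypes: PhenotypeTable, path) -> None:
    """Drugs x samples with a header row of sample ids."""
    phenotypes.values.to_csv(path, sep="\t", na_rep="NA")


def load_phenotypes_tsv(path) -> PhenotypeTable:
    return PhenotypeTable(values=load_matrix_tsv(path))


# ---------------------------------------------------------------------------
# sample alignment
# ---------------------------------------------------------------------------

def _ids_of(table) -> list[str]:
    if isinstance(table, GenotypePanel):
        return table.sample_ids
    if isinstance(table, PhenotypeTable):
        return table.sample_ids
    if isinstance(table, pd.DataFrame) or isinstance(table, pd.Series):
        return list(table.index)
    raise TypeError(f"cannot align object of type {type(table).__name__}")


def _take(table, ids: list[str]):
    if isinstance(table, GenotypePanel):
        pos = [table.sample_ids.index(i) for i in ids]
        return table.subset_samples(pos)
    if isinstance(table, PhenotypeTable):
        return PhenotypeTable(values=table.values[ids], squash=table.squash)
    return table.loc[ids]


def align_samples(*tables) -> tuple[list, dict[int, list[str]]]:
    """Restrict every table to the shared sample ids, in the first table's
    order.  Returns (aligned tables, {table index: dropped ids})."""
    id_sets = [set(_ids_of(t)) for t in tables]
    common = set.intersection(*id_sets)
    if not common:
        raise ValueError("empty sample-id intersection across tables")
    order = [i for i in _ids_of(tables[0]) if i in common]
    dropped = {k: sorted(ids - common) for k, ids in enumerate(id_sets)
               if ids - common}
    return [_take(t, order) for t in tables], dropped


def lengths_from_panel(panel: GenotypePanel, pad_bp: int = 0) -> dict[str, int]:
    """Chromosome lengths implied by the panel's maximum variant positions."""
    return {c: int(g["pos"].max()) + pad_bp
            for c, g in panel.variants.groupby("chrom", sort=False)}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Either file paths (``genotypes``/``somatic``/``phenotypes``/``tissues``)
    or a :class:`~germdrug.synthetic.PanelConfig` + effect plans must be
    supplied.  Thresholds default to the analysis' standard values: MAF 2%,
    LD window of 50 variants at r^2 >= 0.4, post-hoc QTL confirmation within
    100 kb, FWER 5%.
    """

    out_dir: str = "germdrug_out"
    genotypes: str | None = None
    somatic: str | None = None
    phenotypes: str | None = None
    tissues: str | None = None
    simulate: PanelConfig | None = None
    plans: dict[str, EffectPlan] | None = None
    maf_min: float = 0.02
    ld_window_snps: int = 50
    ld_r2_min: float = 0.4
    qtl_confirm_window_bp: int = 100_000
    qtl_confirm_r2_min: float = 0.4
    fwer: float = 0.05
    perm_chromosome: str | None = None
    n_perm: int = 100
    extrapolation: str = "quantile"
    run_prediction: bool = False
    cv_folds: int = 5
    cv_repeats: int = 10
    seed: int = 0

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run filters -> (optional) prediction -> QTL mapping -> permutation
    FWER -> significance calls, persisting each stage's outputs plus a
    manifest under ``config.out_dir``.  Deterministic given the seed; a
    stage failure raises :class:`PipelineError` naming the stage, with the
    outputs of completed stages already on disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "inputs": {},
        "stages": {},
    }
    results: dict = {"manifest": manifest}

    def run_stage(name, fn):
        t0 = time.time()
        try:
            info = fn()
        except Exception as exc:
            _write_json(out / "manifest.json", manifest)
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3),
                                    **(info or {})}
        logger.info("stage %s done in %.2fs", name,
                    manifest["stages"][name]["seconds"])

    state: dict = {}

    # -- load / simulate ----------------------------------------------------
    def _load():
        if config.simulate is not None:
            sp = simulate_panel(config.simulate, config.plans)
            state.update(panel=sp.genotypes, somatic=sp.somatic,
                         phenotypes=sp.phenotypes, tissues=sp.tissues)
            results["truth"] = sp.truth
            return {"n_samples": sp.genotypes.n_samples,
                    "n_variants": sp.genotypes.n_variants, "source": "synthetic"}
        if not (config.genotypes and config.phenotypes):
            raise ValueError("need genotype and phenotype paths, or a "
                             "simulation config")
        for key in ("genotypes", "somatic", "phenotypes", "tissues"):
            p = getattr(config, key)
            if p:
                manifest["inputs"][key] = _sha256(Path(p))
        panel = load_genotypes(config.genotypes)
        phenotypes = load_phenotypes_tsv(config.phenotypes)
        somatic = load_matrix_tsv(config.somatic) if config.somatic else None
        tissues = (load_matrix_tsv(config.tissues).iloc[:, 0]
                   if config.tissues else None)
        tables = [t for t in (panel, phenotypes, somatic, tissues)
                  if t is not None]
        aligned, dropped = align_samples(*tables)
        it = iter(aligned)
        state["panel"] = next(it)
        state["phenotypes"] = next(it)
        state["somatic"] = next(it) if somatic is not None else None
        state["tissues"] = next(it) if tissues is not None else None
        return {"n_samples": state["panel"].n_samples,
                "n_variants": state["panel"].n_variants,
                "dropped_ids": {str(k): v for k, v in dropped.items()},
                "source": "files"}

    run_stage("load", _load)

    # -- variant filters ----------------------------------------------------
    def _filter():
        panel = state["panel"]
        report = germline_authenticity_filter(
            panel, window_snps=config.ld_window_snps, r2_min=config.ld_r2_min,
            maf_min=config.maf_min)
        keep = panel.variants["id"].isin(report.retained_ids).to_numpy()
        results["filter_report"] = report
        state["panel"] = panel.subset_variants(keep)
        results["filtered_panel"] = state["panel"]
        _write_json(out / "filter_report.json", {
            "n_input": report.n_input, "n_after_maf": report.n_after_maf,
            "n_after_ld": report.n_after_ld,
            "n_removed": len(report.removed_ids)})
        return {"n_input": report.n_input, "n_after_ld": report.n_after_ld}

    run_stage("filter", _filter)

    # -- kinship ------------------------------------------------------------
    def _kinship():
        results["K"] = realized_relatedness(state["panel"])
        results["eig"] = kinship_eigh(results["K"])
        return {"n_samples": results["K"].shape[0]}

    run_stage("kinship", _kinship)

    tissues = state["tissues"]
    W, _ = tissue_covariates(tissues) if tissues is not None else (None, [])

    # -- prediction (optional) ----------------------------------------------
    if config.run_prediction and state["somatic"] is not None:
        def _predict():
            from .prediction import residualize_covariates
            rows = []
            phenotypes = state["phenotypes"]
            for drug in phenotypes.drugs:
                y_res = residualize_covariates(phenotypes.drug_vector(drug), W)
                res = evaluate_repeated_cv(
                    state["somatic"].to_numpy(dtype=float),
                    state["panel"].dosages, y_res,
                    k=config.cv_folds, n_repeats=config.cv_repeats,
                    seed=config.seed, drug=drug)
                rows.append({"drug": drug, "r_somatic": res.r_somatic,
                             "r_joint": res.r_joint,
                             "r_germline_component": res.r_germline_component,
                             "sd_diff": res.sd_diff,
                             "n_selected_germline": res.n_selected_germline,
                             "significant": res.significant})
            df = pd.DataFrame(rows)
            df.to_csv(out / "prediction.tsv", sep="\t", index=False)
            results["prediction"] = df
            return {"n_drugs": len(rows)}

        run_stage("prediction", _predict)

    # -- QTL mapping --------------------------------------------------------
    def _qtl():
        panel = state["panel"]
        somatic = state["somatic"]
        phenotypes = state["phenotypes"]
        lead_rows = []
        for drug in phenotypes.drugs:
            y_raw = phenotypes.drug_vector(drug)
            y = quantile_normalize(y_raw)
            germ = lmm_scan(y, W, panel.dosages, results["eig"])
            gi = int(np.nanargmin(germ["p_value"].to_numpy()))
            lead_rows.append({
                "drug": drug, "test_type": "germline",
                "variant": panel.variants["id"].iloc[gi],
                "chrom": panel.variants["chrom"].iloc[gi],
                "pos": int(panel.variants["pos"].iloc[gi]),
                "p_value": float(germ["p_value"].iloc[gi]),
                "beta": effect_size_original_scale(
                    y_raw, W, panel.dosages[:, gi], eig=results["eig"]),
                "n_tests": panel.n_variants,
            })
            if somatic is not None:
                som = lm_scan(y, W, somatic.to_numpy(dtype=float))
                si = int(np.nanargmin(som["p_value"].to_numpy()))
                lead_rows.append({
                    "drug": drug, "test_type": "somatic",
                    "variant": somatic.columns[si], "chrom": "", "pos": 0,
                    "p_value": float(som["p_value"].iloc[si]),
                    "beta": effect_size_original_scale(
                        y_raw, W, somatic.iloc[:, si].to_numpy(dtype=float),
                        test_type="somatic"),
                    "n_tests": somatic.shape[1],
                })
        leads = pd.DataFrame(lead_rows)
        leads.to_csv(out / "qtl_leads.tsv", sep="\t", index=False)
        results["leads"] = leads
        return {"n_drugs": len(phenotypes.drugs)}

    run_stage("qtl", _qtl)

    # -- permutation FWER ---------------------------------------------------
    def _fwer():
        panel = state["panel"]
        phenotypes = state["phenotypes"]
        lengths = lengths_from_panel(panel)
        chrom = config.perm_chromosome or max(lengths, key=lengths.get)
        factor = genome_extrapolation_factor(lengths, chrom)
        chr_mask = (panel.variants["chrom"] == chrom).to_numpy()
        chr_block = panel.dosages[:, chr_mask]
        pooled, counts = [], {}
        rng = np.random.default_rng(config.seed)
        for drug in phenotypes.drugs:
            y = quantile_normalize(phenotypes.drug_vector(drug))
            minp = permutation_min_p(y, W, results["eig"], chr_block,
                                     n_perm=config.n_perm,
                                     seed=int(rng.integers(2 ** 31)))
            gw = extrapolate_pvalue(minp, factor, method=config.extrapolation)
            pooled.extend(np.atleast_1d(gw).tolist())
            counts[drug] = config.n_perm
        null = NullDistribution(values=np.array(pooled), counts_per_drug=counts)
        results["null"] = null
        pd.DataFrame({"min_p_gw": null.values}).to_csv(
            out / "null_min_p.tsv", sep="\t", index=False)
        obs_rows = []
        for _, row in results["leads"].iterrows():
            if row["test_type"] == "germline":
                # the observed minimum is already genome-wide (full scan), so
                # it is compared to the extrapolated null without re-adjustment
                adj = empirical_adjusted_p(row["p_value"], null)
                confirmed = confirm_qtl_ld(
                    row["variant"], panel,
                    window_bp=config.qtl_confirm_window_bp,
                    r2_min=config.qtl_confirm_r2_min)
                obs_rows.append({**row, "adjusted_p": adj,
                                 "ld_confirmed": confirmed})
            else:
                adj = bonferroni_adjust(row["p_value"], int(row.get("n_tests", 1)))
                obs_rows.append({**row, "adjusted_p": adj, "ld_confirmed": True})
        calls = call_significant(pd.DataFrame(obs_rows), fwer=config.fwer)
        calls.to_csv(out / "qtl_calls.tsv", sep="\t", index=False)
        results["calls"] = calls
        return {"factor": factor, "chromosome": chrom, "n_null": null.n,
                "n_significant": int(calls["significant"].sum())}

    run_stage("fwer", _fwer)

    _write_json(out / "manifest.json", manifest)
    return results


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
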