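"""End-to-end orchestration: simulate -> DMR call -> quantify -> split ->
select -> train -> integrate -> evaluate, under one config and one master
seed. Every stage draws its seed deterministically from the master seed and
logs its input/output sizes; a manifest records the config and per-stage
wall time.
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
import yaml

from . import classify, dmr as dmr_mod, evaluate as eval_mod, mutation, selection
from .io import write_dmr_bed, write_sample_sheet, write_variant_table
from .simulate import Cohort, SimConfig, simulate_cohort, true_dmrs_to_frame

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One config to drive the whole analysis on a synthetic cohort."""

    sim: SimConfig = field(default_factory=SimConfig)
    criteria: dmr_mod.DmrCriteria = field(default_factory=dmr_mod.DmrCriteria)
    train_fraction: float = 0.7
    split_mode: str = "random"  # random | cohort
    target_specificity: float = 0.95
    ca199_cutoff: float = 37.0
    n_folds: int = 10
    boruta_iter: int = 50
    selection_alpha: float = 0.05
    selection_cv_folds: int = 5
    selection_estimators: int = 200
    rf_params: dict = field(default_factory=dict)
    bi_omics: str | None = "kras_tp53"  # kras_tp53 | top_genes | top_hotspots | None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.split_mode not in ("random", "cohort"):
            raise ValueError("split_mode must be 'random' or 'cohort'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = SimConfig(**_tupled(data.pop("sim", {})))
        criteria = dmr_mod.DmrCriteria(**data.pop("criteria", {}))
        return cls(sim=sim, criteria=criteria, **data)

    def to_dict(self) -> dict:
        """YAML/JSON-safe nested dict (tuples become lists)."""
        return json.loads(json.dumps(dataclasses.asdict(self)))


def _tupled(d: dict) -> dict:
    from .simulate import Ca199Params
    for key in ("dmr_len_bp", "tumor_fraction_range", "ch_af_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    for key in ("stage_probs", "hotspot_defs", "tumor_gene_probs"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(tuple(x) for x in d[key])
    if isinstance(d.get("ca199_params"), dict):
        d["ca199_params"] = Ca199Params(**d["ca199_params"])
    return d


def _stage_seed(master: int, label: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# cohort split
# ---------------------------------------------------------------------------

def split_cohort(sheet: pd.DataFrame, train_fraction: float = 0.7,
                 seed: int = 0, mode: str = "random",
                 cohort_splits: dict[str, str] | None = None) -> pd.DataFrame:
    """Assign train/test splits, stratified by group.

    ``random`` mode splits every group train_fraction/rest at random.
    ``cohort`` mode reproduces the cohort-aware layout: whole cohorts can be
    pinned via ``cohort_splits`` (e.g. {"cohort3": "train", "cohort4":
    "test"}); remaining samples are split at random within group.
    """
    sheet = sheet.reset_index(drop=True).copy()
    rng = np.random.default_rng(seed)
    split = pd.Series("NA", index=sheet.index, dtype=object)
    pinned = pd.Series(False, index=sheet.index)
    if mode == "cohort":
        if cohort_splits is None:
            cohort_splits = {"cohort3": "train", "cohort4": "test"}
        for cohort, assignment in cohort_splits.items():
            sel = sheet["cohort"] == cohort
            split[sel] = assignment
            pinned |= sel
    for _, idx in sheet[~pinned].groupby("group").groups.items():
        idx = np.asarray(list(idx))
        n_train = int(round(train_fraction * len(idx)))
        order = rng.permutation(len(idx))
        split[idx[order[:n_train]]] = "train"
        split[idx[order[n_train:]]] = "test"
    sheet["split"] = split
    return sheet


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """In-memory outputs of one full pipeline run."""

    config: PipelineConfig
    cohort: Cohort
    cpg_stats: pd.DataFrame
    dmrs: pd.DataFrame
    region_matrix: pd.DataFrame
    sheet: pd.DataFrame
    selection: selection.SelectionReport
    bundle: classify.ModelBundle | None
    predictions: pd.DataFrame
    evaluation: dict
    manifest: dict


def run_full(config: PipelineConfig, outdir: str | Path | None = None,
             mutation_enabled: bool = True) -> RunResult:
    """Execute every stage; optionally persist outputs under ``outdir``."""
    t_all = time.time()
    manifest: dict = {"config": _manifest_config(config), "stages": {}}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(label):
        t0 = time.time()

        def done(**info):
            manifest["stages"][label] = {"seconds": round(time.time() - t0, 3), **info}
            logger.info("stage %s done in %.1fs %s", label,
                        time.time() - t0, info)
        return done

    # 1. simulate -----------------------------------------------------------
    done = _stage("simulate")
    sim_config = dataclasses.replace(config.sim, seed=_stage_seed(config.seed, "simulate"))
    cohort = simulate_cohort(sim_config)
    done(n_tissue_pairs=sim_config.n_tissue_pairs,
         n_plasma=len(cohort.plasma_tables),
         n_true_dmrs=len(cohort.true_dmrs))

    # 2. DMR calling --------------------------------------------------------
    done = _stage("dmr_calling")
    cpg_stats = dmr_mod.test_cpg_differential(cohort.tumor_tables,
                                              cohort.nat_tables, config.criteria)
    dmrs = dmr_mod.call_dmrs(cpg_stats, config.criteria)
    done(n_cpg_tested=int(cpg_stats.attrs["qc"]["n_cpg_tested"]),
         n_dmrs=len(dmrs),
         n_hyper=int((dmrs["direction"] == "hyper").sum()),
         n_hypo=int((dmrs["direction"] == "hypo").sum()))

    # 3. plasma quantification ---------------------------------------------
    done = _stage("region_methylation")
    region_matrix = dmr_mod.compute_region_methylation(cohort.plasma_tables, dmrs)
    done(n_samples=region_matrix.shape[0], n_regions=region_matrix.shape[1])

    # 4. split --------------------------------------------------------------
    done = _stage("split")
    sheet = split_cohort(cohort.sample_sheet, config.train_fraction,
                         _stage_seed(config.seed, "split"), config.split_mode)
    done(n_train=int((sheet["split"] == "train").sum()),
         n_test=int((sheet["split"] == "test").sum()))

    sheet_idx = sheet.set_index("sample_id")
    y_all = (sheet_idx["group"] == "PDAC").astype(int)
    train_ids = sheet_idx.index[sheet_idx["split"] == "train"]
    test_ids = sheet_idx.index[sheet_idx["split"] == "test"]
    directions = {f"{r['chrom']}:{int(r['start'])}-{int(r['end'])}": r["direction"]
                  for _, r in dmrs.iterrows()}

    # 5. marker selection (training rows only) ------------------------------
    done = _stage("selection")
    X_train = region_matrix.loc[train_ids]
    sel = selection.select_markers(
        X_train, y_all.loc[train_ids].to_numpy(), directions,
        seed=_stage_seed(config.seed, "selection"),
        boruta_iter=config.boruta_iter, alpha=config.selection_alpha,
        cv_folds=config.selection_cv_folds,
        n_estimators=config.selection_estimators)
    done(stage1=len(sel.stage1_selected), stage2=len(sel.stage2_selected),
         final=len(sel.final_markers))

    markers = sel.final_markers or sel.stage2_selected or sel.stage1_selected
    if not markers:
        logger.warning("selection produced no markers; falling back to all regions")
        markers = list(region_matrix.columns)

    # 6. mutation features (optional) ---------------------------------------
    mut_matrix = None
    if mutation_enabled and config.bi_omics and len(cohort.cfdna_variants):
        done = _stage("mutation_features")
        retained, shared = mutation.filter_wbc_shared(cohort.cfdna_variants,
                                                      cohort.wbc_variants)
        concordance = mutation.af_concordance(shared)
        mut_matrix = mutation.build_mutation_features(
            retained, config.bi_omics, training_samples=list(train_ids),
            all_samples=list(sheet_idx.index))
        manifest["af_concordance"] = concordance
        done(n_retained=len(retained), n_shared=len(shared),
             n_features=mut_matrix.shape[1])
    elif mutation_enabled and config.bi_omics:
        logger.warning("variant tables empty; mutation stages skipped")

    # 7. train the methylation-only model (the primary classifier) ----------
    done = _stage("train")
    med = region_matrix.loc[train_ids, markers].median().fillna(0.5)
    X_model = region_matrix[markers].fillna(med)
    y_train = y_all.loc[train_ids].to_numpy()
    bundle, oof, cv_auc = classify.train_rf_cv(
        X_model.loc[train_ids], y_train,
        n_folds=config.n_folds, seed=_stage_seed(config.seed, "train"),
        rf_params=config.rf_params)
    bundle.threshold = classify.choose_threshold(
        oof.to_numpy(), y_train, config.target_specificity)
    done(cv_auc=round(cv_auc, 4), threshold=round(bundle.threshold, 4))

    # 7b. bi-omics model (methylation + mutation status), evaluated apart ----
    bi_report = None
    if mut_matrix is not None:
        done = _stage("bi_omics")
        X_bi = classify.fuse_bi_omics(X_model, mut_matrix)
        bi_bundle, bi_oof, bi_cv_auc = classify.train_rf_cv(
            X_bi.loc[train_ids], y_train, n_folds=config.n_folds,
            seed=_stage_seed(config.seed, "train_bi"), rf_params=config.rf_params)
        bi_bundle.threshold = classify.choose_threshold(
            bi_oof.to_numpy(), y_train, config.target_specificity)
        bi_preds = classify.predict(bi_bundle, X_bi.loc[test_ids])
        y_bi = (sheet_idx.loc[test_ids, "group"] == "PDAC").to_numpy()
        bi_auc, _ = eval_mod.roc_auc(bi_preds["score"], y_bi)
        bi_report = {
            "feature_def": config.bi_omics,
            "cv_auc_train": bi_cv_auc,
            "test_auc": bi_auc,
            **eval_mod.sensitivity_specificity(bi_preds["call"], y_bi),
        }
        done(cv_auc=round(bi_cv_auc, 4), test_auc=round(bi_auc, 4))

    # 8. predict + integrate + evaluate on the test split --------------------
    done = _stage("evaluate")
    preds = classify.predict(bundle, X_model.loc[test_ids])
    preds["group"] = sheet_idx.loc[test_ids, "group"]
    preds["stage"] = sheet_idx.loc[test_ids, "stage"]
    preds["ca19_9"] = sheet_idx.loc[test_ids, "ca19_9"]
    preds["combined_call"] = classify.integrate_ca199(
        preds["call"], preds["ca19_9"], config.ca199_cutoff)
    y_test = (preds["group"] == "PDAC").to_numpy()
    evaluation = {
        "cv_auc_train": cv_auc,
        "methylation": eval_mod.evaluation_report(
            preds["score"], preds["call"], y_test, stages=preds["stage"],
            ca199=preds["ca19_9"], threshold=bundle.threshold,
            seed=_stage_seed(config.seed, "bootstrap")),
        "combined": {
            **eval_mod.sensitivity_specificity(preds["combined_call"], y_test),
            "by_stage": eval_mod.sensitivity_by_stage(
                preds["combined_call"], y_test, preds["stage"]).to_dict("records"),
        },
        "markers": markers,
    }
    if bi_report is not None:
        evaluation["bi_omics"] = bi_report
    done(test_auc=round(evaluation["methylation"]["auc"], 4))

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    result = RunResult(config, cohort, cpg_stats, dmrs, region_matrix, sheet,
                       sel, bundle, preds, evaluation, manifest)
    if out is not None:
        _persist(result, out)
    return result


def _manifest_config(config: PipelineConfig) -> dict:
    d = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]
    d["config_hash"] = digest
    return d


def _persist(result: RunResult, out: Path) -> None:
    write_dmr_bed(result.dmrs, out / "dmrs.bed")
    write_dmr_bed(true_dmrs_to_frame(result.cohort.true_dmrs), out / "true_dmrs.bed")
    write_sample_sheet(result.sheet, out / "sample_sheet.tsv")
    if len(result.cohort.cfdna_variants):
        write_variant_table(result.cohort.cfdna_variants, out / "cfdna_variants.tsv")
        write_variant_table(result.cohort.wbc_variants, out / "wbc_variants.tsv")
    result.region_matrix.to_csv(out / "region_methylation.tsv", sep="\t")
    (out / "selection_report.json").write_text(json.dumps({
        "stage1_selected": result.selection.stage1_selected,
        "stage2_selected": result.selection.stage2_selected,
        "final_markers": result.selection.final_markers,
    }, indent=2))
    if result.bundle is not None:
        result.bundle.save(out / "model.json")
    result.predictions.to_csv(out / "predictions.tsv", sep="\t")
    (out / "evaluation.json").write_text(
        json.dumps(result.evaluation, indent=2, default=_json_default))
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("records")
    return str(obj)
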