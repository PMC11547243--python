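"""cfDNA variant handling: clonal-hematopoiesis (CH) filtering against
matched WBC sequencing, allele-fraction concordance, recurrent-hotspot
calling, and binary mutation feature matrices.
"""

from __future__ import annotations

import logging
import re
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VARIANT_KEY = ["sample_id", "chrom", "pos", "ref", "alt"]


def filter_wbc_shared(cfdna: pd.DataFrame, wbc: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove cfDNA variants whose identical allele appears in the same
    individual's WBC table (CH contamination).

    Returns (retained, shared); shared rows carry ``wbc_shared=True`` and a
    ``wbc_allele_fraction`` column for the concordance report. Samples with
    no WBC table are passed through unfiltered with a warning, since WBC was
    sequenced only for cfDNA-mutation-positive participants.
    """
    cfdna = cfdna.copy()
    if not len(cfdna):
        return cfdna, cfdna.copy()
    wbc_samples = set(wbc["sample_id"]) if len(wbc) else set()
    unmatched = sorted(set(cfdna["sample_id"]) - wbc_samples)
    if unmatched and len(wbc):
        logger.warning("no WBC table for %d sample(s); their variants pass unfiltered",
                       len(unmatched))
    if not len(wbc):
        cfdna["wbc_shared"] = False
        return cfdna, cfdna.iloc[0:0].copy()
    wbc_af = (wbc[VARIANT_KEY + ["allele_fraction"]]
              .drop_duplicates(VARIANT_KEY)
              .rename(columns={"allele_fraction": "wbc_allele_fraction"}))
    merged = cfdna.merge(wbc_af, on=VARIANT_KEY, how="left")
    shared_mask = merged["wbc_allele_fraction"].notna()
    merged["wbc_shared"] = shared_mask
    shared = merged[shared_mask].reset_index(drop=True)
    retained = (merged[~shared_mask].drop(columns=["wbc_allele_fraction"])
                .reset_index(drop=True))
    return retained, shared


def af_concordance(shared: pd.DataFrame) -> dict:
    """Pearson correlation of cfDNA vs WBC allele fractions on shared calls.

    Returns r, r2, their log10-scale variants and n; fewer than 3 pairs is
    undefined and reported as missing.
    """
    n = len(shared)
    if n < 3:
        logger.warning("only %d shared variant pairs; AF concordance undefined", n)
        return {"n": n, "r": np.nan, "r2": np.nan, "r_log": np.nan, "r2_log": np.nan}
    x = shared["allele_fraction"].to_numpy(float)
    y = shared["wbc_allele_fraction"].to_numpy(float)
    r = float(stats.pearsonr(x, y).statistic)
    r_log = float(stats.pearsonr(np.log10(x), np.log10(y)).statistic)
    return {"n": n, "r": r, "r2": r * r, "r_log": r_log, "r2_log": r_log * r_log}


_PROTEIN_RE = re.compile(r"^(?:p\.)?([A-Za-z*]{1,3}?\d+)")


def parse_protein_position(protein_change: str) -> str | None:
    """Collapse a protein change to its residue (G12D -> G12, p.R249S -> R249)."""
    if not isinstance(protein_change, str):
        return None
    m = _PROTEIN_RE.match(protein_change.strip())
    return m.group(1) if m else None


def identify_hotspots(variants: pd.DataFrame, min_patients: int = 3) -> pd.DataFrame:
    """Recurrent mutational hotspots at residue resolution.

    Variants are grouped by (gene, residue) after dropping the alternate
    amino acid; groups carried by >= min_patients distinct patients are
    hotspots, ranked by patient count with lexicographic tie-break.
    """
    if not len(variants):
        return pd.DataFrame(columns=["gene", "residue", "hotspot", "n_patients"])
    v = variants.copy()
    v["residue"] = [parse_protein_position(pc) for pc in v["protein_change"]]
    skipped = v["residue"].isna()
    if skipped.any():
        logger.info("skipped %d variant(s) with unparseable protein change",
                    int(skipped.sum()))
    v = v[~skipped]
    grouped = (v.groupby(["gene", "residue"])["sample_id"].nunique()
               .reset_index(name="n_patients"))
    hs = grouped[grouped["n_patients"] >= min_patients].copy()
    hs["hotspot"] = hs["gene"] + ":" + hs["residue"]
    hs = hs.sort_values(["n_patients", "gene", "residue"],
                        ascending=[False, True, True]).reset_index(drop=True)
    return hs[["gene", "residue", "hotspot", "n_patients"]]


def top_mutated_genes(variants: pd.DataFrame, k: int = 10,
                      rank_by: str = "patients") -> list[str]:
    """Top-k genes ranked by distinct mutated patients (or variant count)."""
    v = variants[variants["non_synonymous"]]
    if not len(v):
        return []
    if rank_by == "patients":
        counts = v.groupby("gene")["sample_id"].nunique()
    elif rank_by == "variants":
        counts = v.groupby("gene").size()
    else:
        raise ValueError(f"rank_by must be 'patients' or 'variants', got {rank_by!r}")
    ranked = counts.sort_index().sort_values(ascending=False, kind="mergesort")
    return ranked.index[:k].tolist()


def build_mutation_features(variants: pd.DataFrame, feature_def: str,
                            training_samples: Sequence[str],
                            all_samples: Sequence[str] | None = None,
                            top_k: int = 10, min_patients: int = 3,
                            rank_by: str = "patients") -> pd.DataFrame:
    """Binary mutation feature matrix.

    feature_def: ``top_genes`` (top-k most frequently mutated genes),
    ``kras_tp53`` (the two dominant drivers) or ``top_hotspots`` (top-k
    recurrent hotspots). The feature list is frozen on training samples
    only; only non-synonymous retained variants contribute. Samples without
    any qualifying variant get all-zero rows.
    """
    training_samples = list(training_samples)
    if all_samples is None:
        all_samples = training_samples
    v = variants[variants["non_synonymous"]].copy()
    train_v = v[v["sample_id"].isin(training_samples)]
    if feature_def == "kras_tp53":
        features = ["KRAS", "TP53"]
        key = "gene"
    elif feature_def == "top_genes":
        features = top_mutated_genes(train_v, k=top_k, rank_by=rank_by)
        key = "gene"
    elif feature_def == "top_hotspots":
        hs = identify_hotspots(train_v, min_patients=min_patients)
        features = hs["hotspot"].iloc[:top_k].tolist()
        v["residue"] = [parse_protein_position(pc) for pc in v["protein_change"]]
        v = v[v["residue"].notna()]
        v["hotspot"] = v["gene"] + ":" + v["residue"]
        key = "hotspot"
    else:
        raise ValueError(f"unknown feature_def {feature_def!r}")
    mat = pd.DataFrame(0, index=pd.Index(all_samples, name="sample_id"),
                       columns=[f"mut_{f}" for f in features], dtype=np.int64)
    if len(v) and features:
        hits = v[v[key].isin(features)]
        for _, row in hits.iterrows():
            if row["sample_id"] in mat.index:
                mat.loc[row["sample_id"], f"mut_{row[key]}"] = 1
    return mat
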