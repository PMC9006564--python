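"""End-to-end orchestration: simulate -> maps -> radiomics -> rank -> evaluate.

A single JSON-serialisable config drives a reproducible run that
produces, for each model variant, a feature table, an SRC ranking and a
model report, plus a one-row-per-variant summary table.  The four
variants compare display-image radiomics against progressively richer
RF-map sets:

=====  =======================================
GM     grayscale (reconstructed B-mode) ROI only
DM     DEA map
DSM    DEA + SSD maps
DSNM   DEA + SSD + NRD maps
=====  =======================================

The GM variant reconstructs the B-mode from the same RF frame (an
emulation: clinically it would come from saved display images) and runs
the identical radiomics chain on the grayscale ROI.

Every artifact is stamped with a hash of the resolved config, and a
JSONL log records per-stage progress.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, radiomics, selection
from .feature_maps import FeatureMap, compute_dea_map, compute_nrd_map, compute_ssd_map
from .rf_core import ValidationError, crop_roi, read_rf_frame, reconstruct_bmode
from .simulate import CohortSpec, PhantomSpec, simulate_cohort

__all__ = ["DEFAULT_CONFIG", "VARIANT_MAPS", "run_pipeline", "compute_patient_maps", "build_feature_tables"]

logger = logging.getLogger("rfrad")

VARIANT_MAPS = {
    "GM": ("GRAYSCALE",),
    "DM": ("DEA",),
    "DSM": ("DEA", "SSD"),
    "DSNM": ("DEA", "SSD", "NRD"),
}

DEFAULT_CONFIG = {
    "seed": 0,
    "cohort": {
        "n_per_class": 20,
        "class_deltas": {"attenuation": [50.0, 60.0], "coherent_amp": [0.0, 0.8]},
        "phantom": {},  # PhantomSpec overrides
    },
    "manifest": None,  # path to an existing cohort manifest instead of simulating
    "ng": 64,
    "wavelet": "haar",
    "nrd": {"axial_step": 2, "lateral_step": 1, "input_transform": "envelope"},
    "omp": {"max_atoms": None, "tol": 1e-6},
    "svm": {"C": 0.8, "gamma": 1.0},
    "k_max": 15,
    "n_boot": 2000,
    "variants": ["GM", "DM", "DSM", "DSNM"],
    "bmode": {"smooth_len": 5, "dynamic_range_db": 60.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if k not in base:
            raise ValidationError(f"unknown config key {k!r}")
        if isinstance(base[k], dict) and isinstance(v, dict) and base[k]:
            out[k] = _merge(base[k], v)
        else:
            # open sections (e.g. phantom overrides, class deltas) are
            # validated by their dataclasses, not by the schema merge
            out[k] = v
    return out


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def compute_patient_maps(frame, roi, config: dict, kinds) -> dict[str, FeatureMap]:
    """All requested feature maps of one patient's ROI."""
    rf_crop, mask = crop_roi(frame.samples, roi)
    maps: dict[str, FeatureMap] = {}
    if "DEA" in kinds:
        maps["DEA"] = compute_dea_map(rf_crop, mask, c=frame.c, fs=frame.fs)
    if "SSD" in kinds:
        maps["SSD"] = compute_ssd_map(rf_crop, mask)
    if "NRD" in kinds:
        maps["NRD"] = compute_nrd_map(
            rf_crop,
            mask,
            input_transform=config["nrd"]["input_transform"],
            axial_step=config["nrd"]["axial_step"],
            lateral_step=config["nrd"]["lateral_step"],
        )
    if "GRAYSCALE" in kinds:
        bmode = reconstruct_bmode(
            frame,
            smooth_len=config["bmode"]["smooth_len"],
            dynamic_range_db=config["bmode"]["dynamic_range_db"],
        )
        gray_crop, gmask = crop_roi(bmode.pixels, roi)
        maps["GRAYSCALE"] = FeatureMap(values=gray_crop, valid=gmask, kind="GRAYSCALE")
    return maps


def build_feature_tables(cohort, config: dict, variants=None) -> dict[str, pd.DataFrame]:
    """Per-variant feature tables (rows = patients; id and label first)."""
    variants = list(variants or config["variants"])
    needed = sorted({k for v in variants for k in VARIANT_MAPS[v]})
    per_map_rows: dict[str, list] = {k: [] for k in needed}
    ids, labels = [], []
    for pid, frame, roi, label in cohort:
        ids.append(pid)
        labels.append(label)
        maps = compute_patient_maps(frame, roi, config, needed)
        for kind in needed:
            per_map_rows[kind].append(
                radiomics.extract_map_features(
                    maps[kind], ng=config["ng"], wavelet=config["wavelet"]
                )
            )
    per_map = {k: pd.DataFrame(rows) for k, rows in per_map_rows.items()}
    tables = {}
    for v in variants:
        df = pd.concat([per_map[k] for k in VARIANT_MAPS[v]], axis=1)
        df.insert(0, "label", labels)
        df.insert(0, "patient_id", ids)
        tables[v] = df
    return tables


def _evaluate_table(table: pd.DataFrame, config: dict, seed: int) -> dict:
    y = table["label"].to_numpy()
    X = table.drop(columns=["patient_id", "label"]).to_numpy(dtype=float)
    ranking = selection.rank_by_src(
        X, y, max_atoms=config["omp"]["max_atoms"], tol=config["omp"]["tol"]
    )
    k_max = min(config["k_max"], X.shape[1])
    report = evaluation.evaluate_model(
        X,
        y,
        ranking,
        k_max,
        C=config["svm"]["C"],
        gamma=config["svm"]["gamma"],
        seed=seed,
        n_boot=config["n_boot"],
    )
    return {"ranking": ranking, "report": report, "n_features": X.shape[1]}


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run the full pipeline; optionally persist artifacts under ``out_dir``.

    Returns ``{"summary": DataFrame, "tables": ..., "results": ...,
    "config": resolved config, "hash": config hash}``.
    """
    config = _merge(DEFAULT_CONFIG, config or {})
    chash = config_hash(config)
    t0 = time.time()
    logger.info(json.dumps({"stage": "start", "hash": chash}))
    if config["manifest"]:
        cohort = _load_cohort(config["manifest"])
    else:
        c = config["cohort"]
        spec = CohortSpec(
            n_per_class=c["n_per_class"],
            class_deltas={k: tuple(v) for k, v in c["class_deltas"].items()},
            base=PhantomSpec(**_tuplify(c["phantom"])),
            base_seed=config["seed"],
        )
        cohort = simulate_cohort(spec)
    logger.info(json.dumps({"stage": "cohort", "n": len(cohort)}))
    tables = build_feature_tables(cohort, config)
    logger.info(json.dumps({"stage": "features", "widths": {v: t.shape[1] - 2 for v, t in tables.items()}}))
    results = {}
    rows = []
    for v in config["variants"]:
        res = _evaluate_table(tables[v], config, seed=config["seed"])
        results[v] = res
        rep = res["report"]
        rows.append(
            {
                "model": v,
                "n_features": res["n_features"],
                "best_k": rep.sweep.best_k,
                "auc_pct": rep.auc,
                "acc_pct": rep.acc,
                "sens_pct": rep.sens,
                "spec_pct": rep.spec,
                "auc_ci_lo": rep.auc_ci[0],
                "auc_ci_hi": rep.auc_ci[1],
                "bep": rep.bep,
                "anova_p": rep.anova_p,
            }
        )
        logger.info(json.dumps({"stage": "evaluate", "variant": v, "auc": rows[-1]["auc_pct"]}))
    summary = pd.DataFrame(rows)
    out = {"summary": summary, "tables": tables, "results": results, "config": config, "hash": chash}
    if out_dir is not None:
        _persist(out, Path(out_dir))
    logger.info(json.dumps({"stage": "done", "seconds": round(time.time() - t0, 2)}))
    return out


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def _load_cohort(manifest_path):
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    cohort = []
    for _, row in df.iterrows():
        frame, roi = read_rf_frame(manifest_path.parent / row["path"])
        if roi is None:
            raise ValidationError(f"{row['path']}: cohort frames need an ROI")
        cohort.append((str(row["patient_id"]), frame, roi, int(row["label"])))
    return cohort


def _feature_table_to_hdf5(table: pd.DataFrame, path: Path) -> None:
    """HDF5 mirror of a feature table: values matrix + id/label/name axes."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("patient_id", data=np.array(table["patient_id"], dtype="S"))
        h5.create_dataset("label", data=table["label"].to_numpy(dtype=np.int64))
        h5.create_dataset(
            "feature_name", data=np.array(table.columns[2:], dtype="S")
        )
        h5.create_dataset(
            "features", data=table.iloc[:, 2:].to_numpy(dtype=np.float64)
        )


def _persist(out: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = out["hash"]
    meta = {"config": out["config"], "hash": chash}
    (out_dir / "config.json").write_text(json.dumps(meta, indent=2))
    out["summary"].assign(config_hash=chash).to_csv(out_dir / "summary.csv", index=False)
    for v, table in out["tables"].items():
        table.to_csv(out_dir / f"features_{v}.csv", index=False)
        _feature_table_to_hdf5(table, out_dir / f"features_{v}.h5")
    for v, res in out["results"].items():
        rep = res["report"]
        ranking = res["ranking"]
        names = out["tables"][v].columns[2:]
        pd.DataFrame(
            {
                "rank": np.arange(1, ranking.order.size + 1),
                "feature_name": names[ranking.order],
                "beta": ranking.beta[ranking.order],
                "abs_corr": ranking.abs_corr[ranking.order],
            }
        ).to_csv(out_dir / f"ranking_{v}.csv", index=False)
        report_json = {
            "config_hash": chash,
            "auc_pct": rep.auc,
            "auc_ci": list(rep.auc_ci),
            "acc_pct": rep.acc,
            "sens_pct": rep.sens,
            "spec_pct": rep.spec,
            "bep": rep.bep,
            "anova_p": rep.anova_p,
            "tukey_p": rep.tukey_p,
            "best_k": rep.sweep.best_k,
            "scores": rep.scores.tolist(),
            "sweep": {
                "k": rep.sweep.k_values.tolist(),
                "auc_pct": rep.sweep.auc.tolist(),
                "acc_pct": rep.sweep.acc.tolist(),
            },
        }
        (out_dir / f"report_{v}.json").write_text(json.dumps(report_json, indent=2))
        pd.DataFrame({"fpr": rep.roc[0], "tpr": rep.roc[1]}).to_csv(
            out_dir / f"roc_{v}.csv", index=False
        )
        pd.DataFrame({"recall": rep.prc[0], "precision": rep.prc[1]}).to_csv(
            out_dir / f"prc_{v}.csv", index=False
        )
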