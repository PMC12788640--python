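"""End-to-end orchestration: synth -> qc -> deconv -> labels -> mil -> survival.

A single YAML/dict config drives the chain on a fully synthetic cohort:

1. build a signature reference and simulate single cells; QC-filter them;
2. train the deconvolution ensemble on pseudo-bulk mixtures and score it;
3. simulate a patient cohort whose true immune status ("high"/"low" in a
   target cell type) drives both a per-patient bulk profile and the planted
   tile-signal density of that patient's slide;
4. median-split the ensemble's estimated fractions into pseudo-labels and
   train a MIL classifier on the slides under that weak supervision;
5. draw survival times with a planted hazard ratio between the true groups
   and log-rank test the MIL-predicted stratification (and, for comparison,
   the deconvolution-based stratification).

Every stage is seeded from the config seed; re-running the same config
reproduces byte-identical metrics.  Stage toggles are validated up front so a
stage never starts with a missing dependency.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .deconv import DeconvolutionEnsemble, make_pseudobulk, pcc_eval, simulate_pseudobulk_dataset
from .mil import MILClassifier, evaluate_mil
from .qc_norm import QCThresholds, qc_filter
from .survival import SurvivalRecord, logrank_test, median_split, records_to_frame
from .synthetic_data import make_reference, simulate_cells, simulate_slide_bag, simulate_survival_cohort

logger = logging.getLogger("histoimmune.pipeline")

STAGES = ["synthetic", "qc", "deconv", "labeling", "mil", "survival"]
DEPENDS = {
    "qc": ["synthetic"],
    "deconv": ["qc"],
    "labeling": ["deconv"],
    "mil": ["labeling"],
    "survival": ["mil"],
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {s: True for s in STAGES},
    "synthetic": {
        "n_types": 5,
        "n_genes": 400,
        "marker_frac": 0.05,
        "cells_per_type": 250,
        "n_batches": 2,
        "lowq_frac": 0.15,
        "batch_effect": 1.2,
    },
    "qc": {"min_features": 250, "max_features": 2500, "max_mito": 0.05},
    "deconv": {
        "n_train": 2000,
        "n_val": 500,
        "n_cells": 400,
        "epochs": 25,
        "target_cell_type": "type_0",
    },
    "cohort": {
        "n_patients": 200,
        "hazard_ratio": 2.0,
        "censor_rate": 0.2,
        "high_boost": 6.0,
        "bulk_cells": 400,
    },
    "mil": {
        "mode": "att",
        "epochs": 25,
        "patience": 8,
        "tiles_per_slide": 24,
        "tile_size": 32,
        "signal_density": {0: 0.05, 1: 0.5},
        "val_fraction": 0.3,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    return _merge(DEFAULT_CONFIG, user)


def validate_stages(config: dict) -> None:
    """Pre-flight: every enabled stage needs its dependencies enabled."""
    toggles = config["stages"]
    unknown = set(toggles) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage, deps in DEPENDS.items():
        if toggles.get(stage, False):
            for dep in deps:
                if not toggles.get(dep, False):
                    raise ValueError(f"stage '{stage}' requires stage '{dep}' to be enabled")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Execute the enabled stages in order; returns the metrics dict.

    Writes ``metrics.json`` (deterministic, byte-identical across reruns of
    the same config) and ``manifest.json`` (config hash, seeds, versions,
    stage list) into ``outdir``.
    """
    config = load_config(config)
    validate_stages(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    on = config["stages"]
    metrics: dict = {}
    logger.info("pipeline start (seed=%d, hash=%s)", seed, _config_hash(config))

    cells = None
    if on["synthetic"]:
        sc = config["synthetic"]
        ref = make_reference(sc["n_types"], sc["n_genes"], sc["marker_frac"], seed=seed)
        cells = simulate_cells(
            ref,
            cells_per_type=sc["cells_per_type"],
            batch_ids=[f"batch_{i}" for i in range(sc["n_batches"])],
            lowq_frac=sc["lowq_frac"],
            batch_effect=sc["batch_effect"],
            seed=seed + 1,
        )
        metrics["synthetic"] = {"n_cells": int(cells.n_obs), "n_genes": int(cells.n_vars)}

    if on["qc"]:
        thr = QCThresholds(**config["qc"])
        cells, report = qc_filter(cells, thr)
        if report.n_after == 0:
            raise ValueError(
                "QC removed every cell; check that n_genes and library size can "
                "support the detected-gene window"
            )
        metrics["qc"] = {
            "n_before": report.n_before,
            "n_after": report.n_after,
            "retained_fraction": round(report.retained_fraction, 6),
        }
        logger.info("QC retained %d/%d cells", report.n_after, report.n_before)

    ens = cell_types = None
    if on["deconv"]:
        dc = config["deconv"]
        n_total = dc["n_train"] + dc["n_val"]
        X, F, cell_types = simulate_pseudobulk_dataset(
            cells, n_total, n_cells=dc["n_cells"], seed=seed + 2
        )
        ens = DeconvolutionEnsemble(epochs=dc["epochs"], seed=seed + 3)
        ens.fit(
            X[: dc["n_train"]],
            F[: dc["n_train"]],
            X_val=X[dc["n_train"] :],
            y_val=F[dc["n_train"] :],
        )
        pred = ens.predict(X[dc["n_train"] :])
        r = pcc_eval(pred, F[dc["n_train"] :])
        metrics["deconv"] = {
            "median_per_sample_pcc": round(float(np.nanmedian(r["per_sample"])), 6),
            "mean_per_type_pcc": round(float(np.nanmean(r["per_type"])), 6),
        }

    patient_truth = fractions_hat = None
    if on["labeling"]:
        dc = config["deconv"]
        co = config["cohort"]
        n_pat = co["n_patients"]
        target = dc["target_cell_type"]
        if target not in cell_types:
            raise ValueError(f"target cell type {target!r} not in reference")
        t_idx = cell_types.index(target)
        rng = np.random.default_rng(seed + 4)
        # true status: first half high (matches the survival generator's layout)
        patient_truth = np.array(["high"] * (n_pat // 2) + ["low"] * (n_pat - n_pat // 2))
        bulk = np.empty((n_pat, cells.n_vars), dtype=np.float32)
        for i in range(n_pat):
            alpha = np.ones(len(cell_types))
            if patient_truth[i] == "high":
                alpha[t_idx] = co["high_boost"]
            frac = rng.dirichlet(alpha)
            pb = make_pseudobulk(
                cells, frac, n_cells=co["bulk_cells"], seed=int(rng.integers(2**31)), cell_types=cell_types
            )
            bulk[i] = pb.expression
        fractions_hat = ens.predict(bulk)[:, t_idx]
        labels = median_split(
            {f"pt_{i:04d}": float(fractions_hat[i]) for i in range(n_pat)}, cell_type=target
        )
        pseudo = np.array([1 if labels.label_of[f"pt_{i:04d}"] == "high" else 0 for i in range(n_pat)])
        metrics["labeling"] = {
            "threshold": round(labels.threshold, 6),
            "n_high": labels.n_high,
            "n_low": labels.n_low,
            "agreement_with_truth": round(float(np.mean((pseudo == 1) == (patient_truth == "high"))), 6),
        }

    mil_pred = None
    if on["mil"]:
        mc = config["mil"]
        co = config["cohort"]
        n_pat = co["n_patients"]
        density = {int(k): float(v) for k, v in mc["signal_density"].items()}
        slides = [
            simulate_slide_bag(
                immune_level=1 if patient_truth[i] == "high" else 0,
                n_tiles=mc["tiles_per_slide"],
                tile_size=mc["tile_size"],
                signal_density=density,
                seed=seed + 100 + i,
                slide_id=f"pt_{i:04d}",
            )
            for i in range(n_pat)
        ]
        bags = [s.tiles for s in slides]
        rng = np.random.default_rng(seed + 5)
        order = rng.permutation(n_pat)
        n_val = max(1, int(round(mc["val_fraction"] * n_pat)))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        clf = MILClassifier(
            mode=mc["mode"], epochs=mc["epochs"], patience=mc["patience"], seed=seed + 6
        )
        clf.fit(
            [bags[i] for i in tr_idx],
            pseudo[tr_idx],
            val_bags=[bags[i] for i in val_idx],
            val_labels=pseudo[val_idx],
        )
        val_metrics = evaluate_mil(clf, [bags[i] for i in val_idx], pseudo[val_idx])
        mil_pred = clf.predict(bags)
        metrics["mil"] = {
            "mode": mc["mode"],
            "val_accuracy_vs_pseudo": round(val_metrics["accuracy"], 6),
            "val_qwk_vs_pseudo": round(val_metrics["qwk"], 6),
            "accuracy_vs_truth": round(float(np.mean((mil_pred == 1) == (patient_truth == "high"))), 6),
        }

    if on["survival"]:
        co = config["cohort"]
        n_pat = co["n_patients"]
        # survival generator puts the first n//2 patients in the planted "high"
        # hazard group — exactly the layout of patient_truth above
        cohort = simulate_survival_cohort(
            n_pat, hazard_ratio=co["hazard_ratio"], censor_rate=co["censor_rate"], seed=seed + 7
        )
        def _stratify(group_labels):
            recs = [
                SurvivalRecord(r.patient_id, r.time, r.event, g)
                for r, g in zip(cohort, group_labels)
            ]
            try:
                stat, p = logrank_test(recs)
            except ValueError as err:  # e.g. a degenerate one-group stratification
                return {"chi2": None, "p": None, "error": str(err)}, recs
            return {"chi2": round(stat, 6), "p": round(p, 8)}, recs

        wsi_groups = ["high" if c == 1 else "low" for c in mil_pred]
        ccd_groups = ["high" if c == 1 else "low" for c in pseudo]
        metrics["survival"] = {
            "wsi_stratification": _stratify(wsi_groups)[0],
            "ccd_stratification": _stratify(ccd_groups)[0],
            "true_group_stratification": _stratify(list(patient_truth))[0],
        }
        records_to_frame(_stratify(wsi_groups)[1]).to_csv(outdir / "survival_wsi_groups.csv", index=False)

    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    manifest = {
        "config_hash": _config_hash(config),
        "config": config,
        "version": __version__,
        "numpy": np.__version__,
        "stages_run": [s for s in STAGES if on[s]],
        "seed": seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    logger.info("pipeline done: %s", outdir / "metrics.json")
    return metrics
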