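"""Reference benchmarks at the package's study conditions.

These functions define the canonical synthetic experiments the test suite and
the reproduction script both run: the deconvolution recovery benchmark
(8 cell types x 500 genes, 8,000 training / 2,000 validation pseudo-bulk
mixtures), the planted-signal MIL benchmark (200 bags of 44 64-px tiles,
binary labels, ~50% signal tiles in positive bags), log-rank calibration
(type-I error and power at hazard ratio 2, n = 200), and the end-to-end
pipeline run.  Every function is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np

from .deconv import DeconvolutionEnsemble, pcc_eval, simulate_pseudobulk_dataset
from .mil import MILClassifier, evaluate_mil
from .survival import logrank_test
from .synthetic_data import make_reference, simulate_cells, simulate_slide_bag, simulate_survival_cohort

__all__ = [
    "deconv_recovery_benchmark",
    "make_planted_signal_bags",
    "planted_signal_benchmark",
    "mil_mode_ranking",
    "logrank_calibration",
]


def deconv_recovery_benchmark(
    seed: int = 0,
    n_types: int = 8,
    n_genes: int = 500,
    n_train: int = 8000,
    n_val: int = 2000,
    epochs: int = 40,
) -> dict:
    """Train the ensemble on simulated mixtures and score validation recovery."""
    ref = make_reference(n_types, n_genes, marker_frac=0.05, seed=seed)
    cells = simulate_cells(ref, 300, ["b1", "b2"], batch_effect=1.2, seed=seed + 1)
    X, F, _ = simulate_pseudobulk_dataset(cells, n_train + n_val, n_cells=500, seed=seed + 2)
    est = DeconvolutionEnsemble(epochs=epochs, seed=seed + 3)
    est.fit(X[:n_train], F[:n_train], X_val=X[n_train:], y_val=F[n_train:])
    pred = est.predict(X[n_train:])
    r = pcc_eval(pred, F[n_train:])
    losses = est.validation_losses_(X[n_train:], F[n_train:])
    return {
        "median_per_sample_pcc": float(np.nanmedian(r["per_sample"])),
        "per_type_pcc": r["per_type"],
        "predictions": pred,
        "member_val_losses": losses[:-1],
        "ensemble_val_loss": losses[-1],
        "history": est.history_,
        "estimator": est,
    }


def make_planted_signal_bags(
    seed: int = 0,
    n_bags: int = 200,
    n_tiles: int = 44,
    tile_size: int = 64,
    signal_density: dict | None = None,
):
    """Balanced binary bags with planted signal-tile masks."""
    density = signal_density or {0: 0.0, 1: 0.5}
    slides = [
        simulate_slide_bag(
            i % 2, n_tiles=n_tiles, tile_size=tile_size, signal_density=density,
            seed=seed * 100_000 + i, slide_id=f"bag_{i:04d}",
        )
        for i in range(n_bags)
    ]
    labels = np.array([s.immune_level for s in slides])
    return slides, labels


def planted_signal_benchmark(
    seed: int = 0,
    mode: str = "att",
    n_bags: int = 200,
    epochs: int = 30,
    val_fraction: float = 0.3,
    bags=None,
) -> dict:
    """Train one MIL aggregator on the planted-signal bags.

    Returns validation accuracy/QWK and, for attention modes, the fraction of
    positive validation bags whose mean attention weight on planted signal
    tiles exceeds the mean weight on background tiles.  Pass ``bags`` (the
    output of :func:`make_planted_signal_bags`) to reuse one generated cohort
    across modes.
    """
    slides, labels = bags if bags is not None else make_planted_signal_bags(seed=seed, n_bags=n_bags)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_bags)
    n_val = int(round(val_fraction * n_bags))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    clf = MILClassifier(mode=mode, epochs=epochs, patience=8, min_epochs=10, seed=seed)
    clf.fit(
        [slides[i].tiles for i in tr_idx],
        labels[tr_idx],
        val_bags=[slides[i].tiles for i in val_idx],
        val_labels=labels[val_idx],
    )
    m = evaluate_mil(clf, [slides[i].tiles for i in val_idx], labels[val_idx])
    out = {
        "mode": mode,
        "val_accuracy": m["accuracy"],
        "val_qwk": m["qwk"],
        "epochs_run": len(clf.history_["train_loss"]),
        "classifier": clf,
    }
    if mode in ("att", "att_trans"):
        enriched = total = 0
        for i in val_idx:
            s = slides[i]
            if s.immune_level != 1 or s.signal_mask.sum() in (0, len(s.signal_mask)):
                continue
            w = clf.attention_weights(s.tiles)
            total += 1
            enriched += w[s.signal_mask].mean() > w[~s.signal_mask].mean()
        out["attention_enrichment_rate"] = enriched / total if total else np.nan
        out["n_positive_val_bags"] = total
    return out


def mil_mode_ranking(seeds=(0, 1, 2), n_bags: int = 200, epochs: int = 30) -> dict:
    """Mean validation accuracy per aggregator over seeds (shared bags per seed)."""
    accs = {"mean": [], "att": [], "att_trans": []}
    results = {}
    for seed in seeds:
        shared = make_planted_signal_bags(seed=seed, n_bags=n_bags)
        for mode in accs:
            r = planted_signal_benchmark(seed=seed, mode=mode, n_bags=n_bags, epochs=epochs, bags=shared)
            accs[mode].append(r["val_accuracy"])
            results[(mode, seed)] = r
    return {
        "mean_accuracy": {mode: float(np.mean(v)) for mode, v in accs.items()},
        "per_seed": {mode: v for mode, v in accs.items()},
        "results": results,
    }


def logrank_calibration(
    seed: int = 0,
    n: int = 200,
    n_null: int = 1000,
    n_power: int = 500,
    hazard_ratio: float = 2.0,
    censor_rate: float = 0.2,
) -> dict:
    """Monte-Carlo type-I error at hazard ratio 1 and power at the given ratio."""
    base = seed * 1_000_000
    null_rej = 0
    for i in range(n_null):
        cohort = simulate_survival_cohort(n, 1.0, censor_rate=0.1, seed=base + i)
        null_rej += logrank_test(cohort)[1] < 0.05
    power_rej = 0
    for i in range(n_power):
        cohort = simulate_survival_cohort(n, hazard_ratio, censor_rate=censor_rate, seed=base + n_null + i)
        power_rej += logrank_test(cohort)[1] < 0.05
    return {
        "type_i_error": null_rej / n_null,
        "power": power_rej / n_power,
        "n": n,
        "replicates": (n_null, n_power),
    }
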