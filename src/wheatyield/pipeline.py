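"""End-to-end orchestration of the two experiment variants.

The *multispectral* variant follows the full chain: yield grid ->
simulated monthly multispectral scenes -> cloud-filtered monthly VI
composites (4 x 9) -> LSTM + RF/GBDT/SVR -> metrics, permutation
importance, predicted yield map.  The *hyperspectral* variant selects
two-band indices on a small ground-sample table, then extracts the
three custom indices on each acquisition date (3 x n_dates) for every
grid cell and trains the same models.

Every run writes a deterministic directory layout::

    <out>/config.json
    <out>/data/       generated tables + true-yield GeoTIFF
    <out>/features/   VI matrix / custom features, band surfaces
    <out>/models/     training logs
    <out>/reports/    metrics.json, importance.json, scatter CSV, maps
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import band_selection as bs
from . import evaluation, indices, models, raster, synth
from .config import VI_NAMES, BaselineConfig, PipelineConfig

__all__ = ["run_full_pipeline"]

logger = logging.getLogger("wheatyield")

BASELINE_KINDS = ("RF", "GBDT", "SVR")


def _feature_groups(names: list[str], n_steps: int) -> dict[str, np.ndarray]:
    """Flat-column ownership of each feature under index-major order."""
    return {
        name: np.arange(k * n_steps, (k + 1) * n_steps)
        for k, name in enumerate(names)
    }


def _train_all(X_seq, X_flat, y, cfg: PipelineConfig, feature_names):
    """Split once, train the LSTM and the three baselines."""
    tr, te = models.split_train_test(len(y), cfg.split)
    fitted = {}
    fitted["LSTM"] = models.train_lstm_regressor(
        X_seq[tr], y[tr], cfg.lstm, feature_names=feature_names
    )
    groups = _feature_groups(feature_names, X_seq.shape[1])
    for kind in BASELINE_KINDS:
        bcfg = BaselineConfig(model=kind, seed=cfg.seed)
        fitted[kind] = models.train_baseline_regressor(
            X_flat[tr], y[tr], bcfg, feature_names=feature_names,
            feature_groups=groups,
        )
    return fitted, tr, te


def _evaluate_all(fitted, X_seq, X_flat, y, tr, te):
    reports = {}
    preds = {}
    for kind, model in fitted.items():
        X = X_seq if model.schema[0] == "sequence" else X_flat
        pred = models.predict_yield(model, X)
        preds[kind] = pred
        reports[kind] = {
            "test": evaluation.compute_metrics(y[te], pred[te], split="test").to_dict(),
            "train": evaluation.compute_metrics(y[tr], pred[tr], split="train").to_dict(),
            "full": evaluation.compute_metrics(y, pred, split="full").to_dict(),
        }
        if model.oob_r2 is not None:
            reports[kind]["oob_r2"] = model.oob_r2
    return reports, preds


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2))


def run_full_pipeline(
    config: PipelineConfig, variant: str = "multispectral"
) -> Path:
    """Run one experiment variant end to end; returns the run directory."""
    if variant not in ("multispectral", "hyperspectral"):
        raise ValueError("variant must be 'multispectral' or 'hyperspectral'")
    out = Path(config.output_dir)
    for sub in ("data", "features", "models", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    logger.info("stage=config run_dir=%s variant=%s", out, variant)

    grid = synth.generate_yield_grid(config.scene)
    y = grid.yields
    raster.write_yield_map(grid, grid.values, out / "data" / "yield_true.tif")
    synth.write_scene_sidecar(config.scene, out / "data" / "scene_config.json")
    logger.info("stage=simulate n_cells=%d", y.size)

    if variant == "multispectral":
        series = synth.simulate_multispectral_series(grid, config.scene)
        series.to_frame().to_csv(out / "data" / "multispectral.csv", index=False)
        vim = indices.monthly_composite(series, config.cloud_threshold)
        vim.to_tidy().to_csv(out / "features" / "vi_matrix.csv", index=False)
        X_seq = vim.sequences()                       # (n, 9, 4)
        X_flat = indices.flatten_vi_matrix(vim)       # (n, 36)
        feature_names = list(VI_NAMES)
        logger.info("stage=indices shape=%s", X_seq.shape)
    else:
        ground = dataclasses.replace(config.scene)
        rng = np.random.default_rng(config.seed)
        gidx = rng.choice(y.size, size=min(ground.n_hyper_samples, y.size),
                          replace=False)
        ground_table = synth.simulate_hyperspectral_samples(y[gidx], ground)
        ground_table.to_frame().to_csv(
            out / "data" / "hyperspectral_ground.csv", index=False
        )
        selection = bs.select_all_index_types(ground_table, config.selection_alpha)
        _write_json(
            {t: e.to_dict() for t, e in selection.items()},
            out / "features" / "band_selection.json",
        )
        surfaces = pd.concat(
            [
                bs.pairwise_correlation_surface(ground_table, t).to_frame()
                for t in bs.INDEX_TYPES
            ]
        )
        surfaces.to_csv(out / "features" / "band_surfaces.csv", index=False)
        logger.info("stage=select-bands n_pairs=%d", len(surfaces))

        # per-date spectra for the whole grid, features 3 x n_dates
        tables = []
        for d, _date in enumerate(config.hyper_dates):
            cfgd = dataclasses.replace(config.scene, seed=config.scene.seed + 100 + d)
            tables.append(synth.simulate_hyperspectral_samples(y, cfgd))
        feats, feature_names, dates = bs.extract_custom_features(
            tables, selection, list(config.hyper_dates)
        )
        X_seq = np.transpose(feats, (0, 2, 1))        # (n, n_dates, 3)
        X_flat = feats.reshape(feats.shape[0], -1)    # (n, 3 * n_dates)
        logger.info("stage=features shape=%s", X_seq.shape)

    fitted, tr, te = _train_all(X_seq, X_flat, y, config, feature_names)
    for kind, model in fitted.items():
        if model.training_log:
            pd.DataFrame(model.training_log, columns=["epoch", "loss"]).to_csv(
                out / "models" / f"{kind.lower()}_training_log.csv", index=False
            )
    logger.info("stage=train n_train=%d n_test=%d", tr.size, te.size)

    reports, preds = _evaluate_all(fitted, X_seq, X_flat, y, tr, te)
    _write_json(reports, out / "reports" / "metrics.json")
    pd.DataFrame(
        {"y_true": y[te], **{k: p[te] for k, p in preds.items()}}
    ).to_csv(out / "reports" / "scatter_test.csv", index=False)
    raster.write_yield_map(
        grid, preds["LSTM"], out / "reports" / "yield_pred_lstm.tif"
    )
    logger.info("stage=evaluate lstm_test_rmse=%.4f",
                reports["LSTM"]["test"]["rmse"])

    imp_seed = config.seed + PipelineConfig.SEED_OFFSETS["importance"]
    imp = evaluation.permutation_feature_importance(
        fitted["LSTM"], X_seq[te], y[te], n_repeats=10, seed=imp_seed
    )
    _write_json(imp.to_dict(), out / "reports" / "importance.json")

    mgmt = synth.generate_management_table(config.scene, n_samples=max(len(y) // 4, 40))
    mgmt.data.to_csv(out / "data" / "management.csv", index=False)
    evaluation.summarize_management_effects(mgmt).to_csv(
        out / "reports" / "management_summary.csv", index=False
    )
    logger.info("stage=importance top=%s", imp.ranking[0])
    return out
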