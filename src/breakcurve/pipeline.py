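"""End-to-end orchestration: load → normalize → split → tune → fit → evaluate
→ applicability domain → comparator table.

The run writes a small manifest of artifacts (comparator statistics table,
predictions, Williams-plot data, tuning trace, serialized model, run report
JSON) into an output directory, and every stage is deterministic given the
configured seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataset as ds
from . import diagnostics, gmdh, lssvm, pso, synthetic

logger = logging.getLogger(__name__)

#: literature comparator column (no ANN is trained here; reported as-is)
ANN_LITERATURE = {"MSE": 0.0005, "AAD": 1.9111, "R2": 0.9946, "STD": 0.0271}


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; exactly one data source."""

    data_path: str | None = None
    column_map: dict | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    train_fraction: float = 0.75
    split_seed: int = 42
    split_method: str = "random"
    pso: pso.PSOConfig = field(default_factory=lambda: pso.PSOConfig(swarm_size=30, iterations=100))
    objective_mode: str = "validation"  # or "train"
    val_fraction: float = 0.2
    normalize_fit_on: str = "train"  # or "all"
    normalize_target: bool = False
    gmdh_permutation: tuple[int, int, int, int] = (0, 1, 2, 3)
    gmdh_scaling: str = "normalized"  # or "raw"
    gmdh_output_variant: str = "printed"
    run_reproduction_search: bool = False
    out_dir: str = "breakcurve_run"

    def __post_init__(self) -> None:
        if (self.data_path is None) == (self.synthetic is None):
            raise ValueError("configure exactly one data source (data_path or synthetic)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            for key in ("c0_values", "h0_values", "u_values"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = synthetic.SyntheticConfig(**syn)
        if "pso" in raw and raw["pso"] is not None:
            p = raw["pso"]
            if "bounds" in p:
                p["bounds"] = tuple(tuple(b) for b in p["bounds"])
            raw["pso"] = pso.PSOConfig(**p)
        if "gmdh_permutation" in raw:
            raw["gmdh_permutation"] = tuple(raw["gmdh_permutation"])
        return cls(**raw)


@dataclass
class RunReport:
    """Serializable summary of one pipeline run."""

    stats: dict  # model -> partition -> StatReport fields
    tuned_gamma: float
    tuned_sigma2: float
    tuned_mse: float
    leverage_counts: dict
    warning_leverage: float
    n_train: int
    n_test: int
    manifest: dict
    notes: list

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)


def _load_data(config: RunConfig) -> ds.Dataset:
    if config.data_path is not None:
        return ds.load_table(config.data_path, column_map=config.column_map)
    return synthetic.generate(config.synthetic)


def run(config: RunConfig) -> RunReport:
    """Execute all stages in order and write the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    notes: list[str] = []
    t0 = time.perf_counter()

    data = _load_data(config)
    logger.info("stage load: %d records", len(data))

    train, test = ds.split(data, config.train_fraction, config.split_seed, config.split_method)
    norm_source = data if config.normalize_fit_on == "all" else train
    normalizer = ds.fit_normalizer(
        norm_source, include_target=config.normalize_target
    )
    logger.info("stage split: %d train / %d test (seed=%d)", len(train), len(test), config.split_seed)

    tuned = pso.tune_lssvm(
        train, normalizer, config.pso,
        objective_mode=config.objective_mode,
        val_fraction=config.val_fraction,
        val_seed=config.pso.seed,
        normalize_target=config.normalize_target,
    )
    trace_path = out / "tuning_trace.csv"
    tuned.trace.to_csv(trace_path, index=False)
    manifest["tuning_trace"] = str(trace_path)
    logger.info("stage tune: gamma=%.6g sigma2=%.6g (objective MSE %.3g)",
                tuned.gamma, tuned.sigma2, tuned.best_mse)

    y_train = train.y
    if config.normalize_target:
        y_train = normalizer.transform_column(y_train, ds.TARGET)
    model = lssvm.fit(
        normalizer.transform(train.X), y_train, tuned.gamma, lssvm.KernelParams(tuned.sigma2)
    )
    model_path = out / "model.json"
    model.save(model_path, extra={"normalization": normalizer.to_dict(),
                                  "normalize_target": config.normalize_target})
    manifest["model"] = str(model_path)

    def predict(dataset: ds.Dataset) -> np.ndarray:
        pred = model.predict(normalizer.transform(dataset.X))
        if config.normalize_target:
            pred = normalizer.inverse_column(pred, ds.TARGET)
        return pred

    pred_train, pred_test = predict(train), predict(test)
    pred_total = np.concatenate([pred_train, pred_test])
    obs_total = np.concatenate([train.y, test.y])

    lssvm_stats = [
        diagnostics.compute_stats(pred_train, train.y, "train"),
        diagnostics.compute_stats(pred_test, test.y, "test"),
        diagnostics.compute_stats(pred_total, obs_total, "total"),
    ]

    # frozen GMDH comparator on all points
    X_all_norm = ds.NormalizationSpec.fit(data).transform(data.X)
    X_gmdh = (X_all_norm if config.gmdh_scaling == "normalized" else data.X)[
        :, list(config.gmdh_permutation)
    ]
    gmdh_pred = gmdh.default_network(config.gmdh_output_variant).predict(X_gmdh)
    gmdh_stats = [diagnostics.compute_stats(gmdh_pred, data.y, "total")]

    table = diagnostics.stats_table({"LSSVM": lssvm_stats, "GMDH": gmdh_stats})
    table["ANN_literature_total"] = pd.Series(ANN_LITERATURE)
    table_path = out / "stats_table.csv"
    table.to_csv(table_path)
    manifest["stats_table"] = str(table_path)
    notes.append("ANN column is a literature value only; no ANN is trained.")

    preds = pd.concat([
        train.frame.assign(partition="train", lssvm_pred=pred_train),
        test.frame.assign(partition="test", lssvm_pred=pred_test),
    ], ignore_index=True)
    preds_path = out / "predictions.csv"
    preds.to_csv(preds_path, index=False)
    manifest["predictions"] = str(preds_path)

    # applicability domain over the union of train and test predictions
    X_design = np.vstack([normalizer.transform(train.X), normalizer.transform(test.X)])
    leverage = diagnostics.classify_domain(pred_total, obs_total, X_design)
    williams_path = out / "williams.csv"
    leverage.to_frame().to_csv(williams_path, index=False)
    manifest["williams"] = str(williams_path)

    if config.run_reproduction_search:
        report = gmdh.reproduction_search(X_all_norm, data.X, data.y)
        search_path = out / "gmdh_reproduction_search.csv"
        report.to_csv(search_path, index=False)
        manifest["gmdh_reproduction_search"] = str(search_path)
        notes.append(
            "GMDH reproduction search ranks all 24 input permutations × "
            "{normalized, raw} scaling × 2 output variants by %AAD; the "
            "published supplementary table is not distributed with this "
            "package, so the search documents the attempt on the data supplied."
        )

    report = RunReport(
        stats={
            "LSSVM": {s.label: s.as_row() for s in lssvm_stats},
            "GMDH": {s.label: s.as_row() for s in gmdh_stats},
            "ANN_literature": {"total": ANN_LITERATURE},
        },
        tuned_gamma=tuned.gamma,
        tuned_sigma2=tuned.sigma2,
        tuned_mse=tuned.best_mse,
        leverage_counts=leverage.counts(),
        warning_leverage=leverage.warning_leverage,
        n_train=len(train),
        n_test=len(test),
        manifest=manifest,
        notes=notes,
    )
    report_path = out / "run_report.json"
    report.to_json(report_path)
    report.manifest["run_report"] = str(report_path)
    logger.info("run complete in %.2f s; artifacts in %s", time.perf_counter() - t0, out)
    return report


def condition_slice(
    model: lssvm.LSSVMModel,
    normalizer: ds.NormalizationSpec,
    c0: float,
    h0: float,
    u: float,
    t_grid: np.ndarray,
    normalize_target: bool = False,
) -> pd.DataFrame:
    """Predicted breakthrough curve (t, C/C0) at a fixed operating condition."""
    t_grid = np.asarray(t_grid, float)
    X = np.column_stack([
        np.full_like(t_grid, c0), np.full_like(t_grid, h0),
        np.full_like(t_grid, u), t_grid,
    ])
    Xn = normalizer.transform(X)
    if np.any(np.abs(Xn) > 1.0 + 1e-12):
        logger.warning("condition (%g, %g, %g) extrapolates beyond the fitted range", c0, h0, u)
    pred = model.predict(Xn)
    if normalize_target:
        pred = normalizer.inverse_column(pred, ds.TARGET)
    return pd.DataFrame({"t": t_grid, "ratio_pred": pred})
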