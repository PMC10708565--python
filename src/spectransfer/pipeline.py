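"""End-to-end orchestration of the transfer/hybrid workflow.

The full chain is: scatter-correct each physical form against its own
calibration mean, screen wavelengths per form with CARS and take the union,
train the crushed-form (master) SVR, transfer full-form spectra into the
master space with direct standardization fitted on paired standard samples,
and finally augment the master calibration set with transferred full-form
spectra (hybrid models). ``run_experiment`` works on in-memory datasets;
``run_pipeline`` wraps it with file I/O and a config file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tomllib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration_transfer import apply_transfer, fit_transfer
from .core import Dataset
from .errors import ParameterError
from .hsi_io import read_spectra_table, write_spectra_table
from .modeling import (
    SVRConfig,
    cross_validate,
    evaluate,
    hybrid_sweep,
    train_svr,
)
from .preprocessing import msc_fit, msc_apply
from .sample_selection import pair_standard_sets, random_split, select_standards
from .synthetic_fixtures import FixtureConfig, generate_dataset_pair
from .variable_selection import cars_run, map_wavelengths_to_bands, merge_variable_sets

logger = logging.getLogger(__name__)

# fixed offsets deriving every stage seed from the single master seed
SEED_OFFSETS = {"split": 1, "cars_cs": 2, "cars_fs": 3, "svr": 4, "hybrid": 5}


@dataclass
class PipelineConfig:
    """Stage-block configuration; defaults are the winning configuration
    (SPXY standards from the crushed calibration set, 70 standards, hybrid
    sweep over 5..80 added spectra)."""

    seed: int = 0
    io: dict = field(default_factory=dict)  # cs/fs/tvc paths or {"simulate": {...}}
    msc: dict = field(default_factory=lambda: {"pooled": False})
    cars: dict = field(default_factory=lambda: {
        "iterations": 50, "folds": 10, "mc_ratio": 0.8, "max_components": 10,
    })
    split: dict = field(default_factory=lambda: {"ratio": [4, 1]})
    standards: dict = field(default_factory=lambda: {
        "method": "spxy", "scheme": "crushed_as_standard", "n": 70,
    })
    transfer: dict = field(default_factory=lambda: {"svd_tol": 1e-6})
    model: dict = field(default_factory=lambda: {"grid": "coarse"})
    hybrid: dict = field(default_factory=lambda: {"k_start": 5, "k_stop": 80, "k_step": 5})

    @classmethod
    def from_toml(cls, path: str) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config sections: {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return self.seed + SEED_OFFSETS[stage]

    def svr_config(self) -> SVRConfig:
        fixed = {k: self.model[k] for k in ("C", "gamma", "epsilon") if k in self.model}
        if self.model.get("grid", "coarse") == "coarse":
            return SVRConfig.coarse(**fixed)
        return SVRConfig(**fixed)

    def k_grid(self) -> list[int]:
        h = self.hybrid
        return list(range(int(h.get("k_start", 5)), int(h.get("k_stop", 80)) + 1, int(h.get("k_step", 5))))


def run_experiment(
    cs: Dataset,
    fs: Dataset,
    config: PipelineConfig | None = None,
) -> dict:
    """Execute the full workflow on in-memory paired datasets.

    Returns a dict with the split, selected wavelengths, before/after-transfer
    metric reports, the hybrid sweeps and every intermediate artifact needed
    to reproduce them.
    """
    config = config or PipelineConfig()
    if set(cs.sample_ids) != set(fs.sample_ids):
        raise ParameterError("crushed and full datasets must share sample ids")

    # 1. shared calibration/prediction split
    ratio = tuple(config.split.get("ratio", (4, 1)))
    split = random_split(cs.sample_ids, seed=config.stage_seed("split"), ratio=ratio)
    cs = cs.with_split(split.calibration_ids, split.prediction_ids)
    fs = fs.with_split(split.calibration_ids, split.prediction_ids)

    # 2. MSC per form, reference frozen on the calibration mean
    pooled = bool(config.msc.get("pooled", False))
    if pooled:
        both = np.vstack([cs.calibration.spectra.X, fs.calibration.spectra.X])
        ref_set = dataclasses.replace(
            cs.calibration.spectra,
            X=both,
            sample_ids=[f"p{i}" for i in range(both.shape[0])],
            form=None,
        )
        msc_cs = msc_fs = msc_fit(ref_set)
    else:
        msc_cs = msc_fit(cs.calibration.spectra)
        msc_fs = msc_fit(fs.calibration.spectra)
    cs_c = Dataset(msc_apply(msc_cs, cs.spectra), cs.y,
                   split.calibration_ids, split.prediction_ids)
    fs_c = Dataset(msc_apply(msc_fs, fs.spectra), fs.y,
                   split.calibration_ids, split.prediction_ids)

    # 3. CARS per form on the calibration sets, then the union rule
    cars_kw = dict(
        n_iterations=int(config.cars.get("iterations", 50)),
        n_folds=int(config.cars.get("folds", 10)),
        mc_ratio=float(config.cars.get("mc_ratio", 0.8)),
        max_components=int(config.cars.get("max_components", 10)),
    )
    wl = cs.spectra.wavelengths
    cars_cs = cars_run(cs_c.calibration.spectra.X, cs_c.calibration.y,
                       seed=config.stage_seed("cars_cs"), wavelengths=wl, **cars_kw)
    cars_fs = cars_run(fs_c.calibration.spectra.X, fs_c.calibration.y,
                       seed=config.stage_seed("cars_fs"), wavelengths=wl, **cars_kw)
    union_wl = merge_variable_sets(cars_cs.selected_wavelengths, cars_fs.selected_wavelengths)
    bands = map_wavelengths_to_bands(union_wl, wl)

    # 4. master (crushed) model on the union variable set
    svr_config = config.svr_config()
    svr_seed = config.stage_seed("svr")
    cs_cal = cs_c.calibration
    master = train_svr(cs_cal.spectra.X[:, bands], cs_cal.y, config=svr_config,
                       seed=svr_seed, selected_wavelengths=wl[bands],
                       fit_ids=cs_cal.sample_ids)
    fixed = SVRConfig(kernel=master.kernel, C=master.C, gamma=master.gamma,
                      epsilon=master.epsilon)
    rcv2, rmsecv = cross_validate(cs_cal.spectra.X[:, bands], cs_cal.y,
                                  model_config=fixed, seed=svr_seed)
    master.metrics = dataclasses.replace(master.metrics, Rcv2=rcv2, RMSECV=rmsecv)

    # 5. full-form prediction before transfer
    fs_pred = fs_c.prediction
    metrics_before = evaluate(master, fs_pred.spectra.X[:, bands], fs_pred.y)

    # 6. standards, DS transfer (full band grid), prediction after transfer
    std = config.standards
    n_standards = min(int(std.get("n", 70)), len(split.calibration_ids))
    selection = select_standards(cs_c.calibration, fs_c.calibration,
                                 scheme=std.get("scheme", "crushed_as_standard"),
                                 method=std.get("method", "spxy"), n=n_standards)
    slave, master_std, std_ids = pair_standard_sets(selection, cs_c.calibration, fs_c.calibration)
    ds = fit_transfer(slave, master_std, svd_tol=float(config.transfer.get("svd_tol", 1e-6)),
                      ids=std_ids)
    fs_pred_t = apply_transfer(ds, fs_pred.spectra.X)
    metrics_after = evaluate(master, fs_pred_t[:, bands], fs_pred.y)

    # 7. hybrid sweeps: augment the crushed base with full-form calibration
    #    spectra, raw and transferred, and evaluate on the matching FS pool
    fs_cal = fs_c.calibration
    fs_cal_t = apply_transfer(ds, fs_cal.spectra.X)
    base = Dataset(cs_cal.spectra.select_bands(bands), cs_cal.y)
    pool_raw = Dataset(fs_cal.spectra.select_bands(bands), fs_cal.y)
    pool_t = Dataset(fs_cal.spectra.select_bands(bands).with_X(fs_cal_t[:, bands]), fs_cal.y)
    k_grid = [k for k in config.k_grid() if k <= len(fs_cal.sample_ids)]
    hybrid_cfg = SVRConfig(kernel=master.kernel, C=master.C, gamma=master.gamma,
                           epsilon=master.epsilon)
    hybrid_seed = config.stage_seed("hybrid")
    sweep_raw = hybrid_sweep(base, pool_raw, fs_pred.spectra.X[:, bands], fs_pred.y,
                             k_grid=k_grid, transferred=False,
                             model_config=hybrid_cfg, seed=hybrid_seed)
    sweep_t = hybrid_sweep(base, pool_t, fs_pred_t[:, bands], fs_pred.y,
                           k_grid=k_grid, transferred=True,
                           model_config=hybrid_cfg, seed=hybrid_seed)

    return {
        "split": split,
        "msc": {"crushed": msc_cs, "full": msc_fs},
        "cars": {"crushed": cars_cs, "full": cars_fs},
        "union_wavelengths": union_wl,
        "bands": bands,
        "master_model": master,
        "transfer_model": ds,
        "metrics_master": master.metrics,
        "metrics_before": metrics_before,
        "metrics_after": metrics_after,
        "sweep_raw": sweep_raw,
        "sweep_transferred": sweep_t,
        "fs_prediction_transferred": fs_pred_t,
    }


def _sweep_frame(rows) -> pd.DataFrame:
    records = []
    for row in rows:
        rec = {"k_added": row.k_added, "transferred": row.transferred}
        rec.update({k: v for k, v in row.metrics.to_dict().items() if v is not None})
        records.append(rec)
    return pd.DataFrame(records)


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """File-level wrapper: load (or simulate) inputs, run, write artifacts."""
    os.makedirs(out_dir, exist_ok=True)
    io = config.io
    if "simulate" in io or not io:
        sim = dict(io.get("simulate", {}))
        sim.setdefault("seed", config.seed)
        cs, fs, _ = generate_dataset_pair(FixtureConfig(**sim))
    else:
        cs_spec = read_spectra_table(io["cs"], form="crushed")
        fs_spec = read_spectra_table(io["fs"], form="full")
        tvc = pd.read_csv(io["tvc"], dtype={"sample_id": str}).set_index("sample_id")
        y_cs = tvc.loc[cs_spec.sample_ids, "log10_tvc"].to_numpy(float)
        y_fs = tvc.loc[fs_spec.sample_ids, "log10_tvc"].to_numpy(float)
        cs, fs = Dataset(cs_spec, y_cs), Dataset(fs_spec, y_fs)

    result = run_experiment(cs, fs, config)

    def dump(name: str, payload: dict) -> None:
        with open(os.path.join(out_dir, name), "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    dump("metrics_master.json", result["metrics_master"].to_dict())
    dump("metrics_before_transfer.json", result["metrics_before"].to_dict())
    dump("metrics_after_transfer.json", result["metrics_after"].to_dict())
    dump("split.json", {
        "calibration_ids": result["split"].calibration_ids,
        "prediction_ids": result["split"].prediction_ids,
        "seed": result["split"].seed,
    })
    dump("variables.json", {
        "union_wavelengths": result["union_wavelengths"].tolist(),
        "band_indices": result["bands"].tolist(),
        "crushed_selected": result["cars"]["crushed"].selected_wavelengths.tolist(),
        "full_selected": result["cars"]["full"].selected_wavelengths.tolist(),
    })
    result["transfer_model"].to_json(os.path.join(out_dir, "transfer_model.json"))
    _sweep_frame(result["sweep_raw"]).to_csv(os.path.join(out_dir, "hybrid_sweep_raw.csv"), index=False)
    _sweep_frame(result["sweep_transferred"]).to_csv(
        os.path.join(out_dir, "hybrid_sweep_transferred.csv"), index=False)
    fs_pred_ids = result["split"].prediction_ids
    transferred = fs.spectra.subset(fs_pred_ids).with_X(result["fs_prediction_transferred"])
    write_spectra_table(transferred, os.path.join(out_dir, "fs_prediction_transferred.csv"))
    logger.info("pipeline artifacts written to %s", out_dir)
    return result
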