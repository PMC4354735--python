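"""Readers, writers, reports, and the end-to-end pipeline.

File conventions: comma-separated values with a mandatory header row and '.'
decimals; MATLAB containers target the common level-5 .mat format.  Every
file written here is re-parseable by the readers in this module.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import yaml

from .cv import (FitResult, PathSpec, Standardizer, cross_validate, evaluate)
from .features import (FeatureConfig, FusedFeatureMatrix, TrialSet,
                       extract_fused, resample_trial)
from .model import GroupStructure
from .solver import SolverSettings
from .synthetic import EEGSimSpec, gen_eeg_trials

logger = logging.getLogger("sgleeg")

__all__ = ["read_trials", "write_trials", "read_features", "write_features",
           "write_report", "result_to_dict", "result_from_dict",
           "PipelineConfig", "run_pipeline", "config_from_yaml"]


class DataFormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------- trial IO

def write_trials(trials: TrialSet, path: str | Path, fmt: str = "csv",
                 mat_fields: tuple[str, str] = ("data", "labels")) -> Path:
    """Write a TrialSet as a directory of per-trial CSVs or one .mat file."""
    path = Path(path)
    if fmt == "csv":
        path.mkdir(parents=True, exist_ok=True)
        files = []
        for t in range(trials.n_trials):
            fname = f"trial_{t:04d}.csv"
            df = pd.DataFrame(
                trials.trials[t],
                columns=[f"t{k}" for k in range(trials.n_samples)])
            df.to_csv(path / fname, index=False)
            files.append(fname)
        manifest = pd.DataFrame({"file": files, "label": trials.labels})
        manifest.to_csv(path / "manifest.csv", index=False)
        meta = {"fs": trials.fs, "channel_names": trials.channel_names}
        (path / "meta.json").write_text(json.dumps(meta))
        return path
    if fmt == "mat":
        if path.suffix != ".mat":
            path = path.with_suffix(".mat")
        data_field, label_field = mat_fields
        payload = {data_field: trials.trials, label_field: trials.labels,
                   "fs": trials.fs}
        if trials.channel_names is not None:
            payload["channel_names"] = np.asarray(trials.channel_names,
                                                  dtype=object)
        sio.savemat(path, payload)
        return path
    raise DataFormatError(f"unknown trial format {fmt!r}")


def read_trials(path: str | Path, fmt: str | None = None,
                mat_fields: tuple[str, str] = ("data", "labels")) -> TrialSet:
    """Read a TrialSet written by :func:`write_trials` (CSV dir or .mat)."""
    path = Path(path)
    if fmt is None:
        fmt = "mat" if path.suffix == ".mat" else "csv"
    if fmt == "csv":
        manifest_path = path / "manifest.csv"
        if not manifest_path.exists():
            raise DataFormatError(f"no manifest.csv found in {path}")
        manifest = pd.read_csv(manifest_path)
        meta = {}
        if (path / "meta.json").exists():
            meta = json.loads((path / "meta.json").read_text())
        mats, shapes = [], set()
        for fname in manifest["file"]:
            fpath = path / fname
            if not fpath.exists():
                raise DataFormatError(
                    f"manifest lists {fname} but the file is missing")
            arr = pd.read_csv(fpath).to_numpy(dtype=float)
            mats.append(arr)
            shapes.add(arr.shape)
        if len(shapes) > 1:
            raise DataFormatError(
                f"trials have inconsistent channel/sample counts: {shapes}")
        return TrialSet(trials=np.stack(mats),
                        labels=manifest["label"].to_numpy(),
                        fs=float(meta.get("fs", 1.0)),
                        channel_names=meta.get("channel_names"))
    if fmt == "mat":
        raw = sio.loadmat(path, squeeze_me=False)
        data_field, label_field = mat_fields
        for f in (data_field, label_field):
            if f not in raw:
                raise DataFormatError(f"field {f!r} not found in {path}")
        data = np.asarray(raw[data_field], dtype=float)
        labels = np.asarray(raw[label_field]).ravel()
        fs = float(np.asarray(raw.get("fs", 1.0)).ravel()[0])
        names = None
        if "channel_names" in raw:
            names = [str(np.asarray(v).ravel()[0])
                     for v in np.asarray(raw["channel_names"]).ravel()]
        return TrialSet(trials=data, labels=labels, fs=fs,
                        channel_names=names)
    raise DataFormatError(f"unknown trial format {fmt!r}")


# -------------------------------------------------------------- feature IO

def write_features(fm: FusedFeatureMatrix, labels: np.ndarray,
                   prefix: str | Path) -> tuple[Path, Path, Path]:
    """Feature matrix CSV + labels CSV + sidecar JSON group map."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    feat_path = prefix.with_name(prefix.name + "_features.csv")
    lab_path = prefix.with_name(prefix.name + "_labels.csv")
    grp_path = prefix.with_name(prefix.name + "_groups.json")
    pd.DataFrame(fm.values, columns=fm.feature_labels).to_csv(
        feat_path, index=False)
    pd.DataFrame({"label": labels}).to_csv(lab_path, index=False)
    grp_path.write_text(json.dumps({
        "group_index": [int(g) for g in fm.group_index],
        "d": fm.d}))
    return feat_path, lab_path, grp_path


def read_features(feat_path: str | Path, grp_path: str | Path,
                  lab_path: str | Path | None = None):
    feats = pd.read_csv(feat_path)
    grp = json.loads(Path(grp_path).read_text())
    fm = FusedFeatureMatrix(values=feats.to_numpy(dtype=float),
                            group_index=np.asarray(grp["group_index"]),
                            feature_labels=list(feats.columns),
                            d=int(grp["d"]))
    labels = None
    if lab_path is not None:
        labels = pd.read_csv(lab_path)["label"].to_numpy()
    return fm, labels


# ------------------------------------------------------------ model/report

def result_to_dict(result: FitResult) -> dict:
    return {
        "classes": np.asarray(result.classes).tolist(),
        "chosen_alpha": result.chosen_alpha,
        "chosen_lambda": result.chosen_lambda,
        "coefficients": result.beta.tolist(),
        "intercepts": None if result.intercept is None
        else result.intercept.tolist(),
        "group_index": np.asarray(result.group_index).tolist(),
        "standardizer": {"mean": result.standardizer.mean.tolist(),
                         "scale": result.standardizer.scale.tolist()},
        "selected_channels": [int(c) for c in result.selected_channels],
        "selected_features": [int(f) for f in result.selected_features],
        "fit_intercept": result.fit_intercept,
        "diagnostics": {k: (float(v) if isinstance(v, (int, float, np.floating))
                            else v)
                        for k, v in result.diagnostics.items()},
    }


def result_from_dict(doc: dict) -> FitResult:
    return FitResult(
        beta=np.asarray(doc["coefficients"], dtype=float),
        intercept=None if doc["intercepts"] is None
        else np.asarray(doc["intercepts"], dtype=float),
        classes=np.asarray(doc["classes"]),
        group_index=np.asarray(doc["group_index"]),
        standardizer=Standardizer(
            mean=np.asarray(doc["standardizer"]["mean"], dtype=float),
            scale=np.asarray(doc["standardizer"]["scale"], dtype=float)),
        chosen_alpha=float(doc["chosen_alpha"]),
        chosen_lambda=float(doc["chosen_lambda"]),
        cv_table=pd.DataFrame(),
        selected_channels=list(doc["selected_channels"]),
        selected_features=list(doc["selected_features"]),
        fit_intercept=bool(doc.get("fit_intercept", True)),
        diagnostics=dict(doc.get("diagnostics", {})))


SELECTION_COLUMNS = ["channel", "channel_name", "selected",
                     "n_features_selected", "n_features_total",
                     "proportion_pct"]


def write_report(result: FitResult, prefix: str | Path,
                 channel_names: list[str] | None = None) -> dict[str, Path]:
    """Model JSON, per-channel selection CSV, CV table CSV and a text log."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "model": prefix.with_name(prefix.name + "_model.json"),
        "selection": prefix.with_name(prefix.name + "_selection.csv"),
        "cv_table": prefix.with_name(prefix.name + "_cv_table.csv"),
        "log": prefix.with_name(prefix.name + "_log.txt"),
    }
    paths["model"].write_text(json.dumps(result_to_dict(result), indent=1))

    groups = GroupStructure(result.group_index)
    beta = np.atleast_2d(np.asarray(result.beta, dtype=float).T).T
    nz_feature = np.any(beta != 0.0, axis=1)
    rows = []
    for j, (gid, sl) in enumerate(zip(groups.ids, groups.slices)):
        n_sel = int(nz_feature[sl].sum())
        n_tot = sl.stop - sl.start
        name = channel_names[j] if channel_names else f"ch{int(gid):02d}"
        rows.append({"channel": int(gid), "channel_name": name,
                     "selected": bool(n_sel > 0),
                     "n_features_selected": n_sel,
                     "n_features_total": n_tot,
                     "proportion_pct": 100.0 * n_sel / n_tot})
    pd.DataFrame(rows, columns=SELECTION_COLUMNS).to_csv(
        paths["selection"], index=False)
    result.cv_table.to_csv(paths["cv_table"], index=False)

    n_chan = groups.n_groups
    n_feat = groups.n_features
    n_sel_chan = len(result.selected_channels)
    n_sel_feat = len(result.selected_features)
    lines = [
        "sgleeg selection report",
        f"chosen alpha: {result.chosen_alpha:g}",
        f"chosen lambda: {result.chosen_lambda:.6g}",
        f"selected channels: {n_sel_chan} / {n_chan} "
        f"({100.0 * n_sel_chan / n_chan:.2f}%)",
        f"selected features: {n_sel_feat} / {n_feat} "
        f"({100.0 * n_sel_feat / n_feat:.2f}%)",
    ]
    if result.test_error is not None:
        lines.append(f"test error rate: {100.0 * result.test_error:.2f}%")
    for k, v in result.diagnostics.items():
        lines.append(f"{k}: {v}")
    paths["log"].write_text("\n".join(lines) + "\n")
    return paths


# ---------------------------------------------------------------- pipeline

@dataclass
class PipelineConfig:
    """End-to-end run: data source, extraction, CV selection, evaluation."""

    input_path: str | None = None
    input_format: str | None = None
    simulate: EEGSimSpec | None = None
    fs_target: float | None = None
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    path_spec: PathSpec = field(default_factory=PathSpec)
    solver: SolverSettings = field(default_factory=SolverSettings)
    fit_intercept: bool = True
    test_fraction: float = 0.25
    split_seed: int = 0
    out_prefix: str | None = None


def _stratified_split(labels: np.ndarray, test_fraction: float,
                      seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(idx.size)]
        n_test = int(round(test_fraction * idx.size))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), \
        np.sort(np.concatenate(test_idx))


def run_pipeline(config: PipelineConfig) -> FitResult:
    """resample -> extract -> cross-validate -> refit -> evaluate.

    Deterministic given the seeds in the config; the held-out trials are
    never touched before the final evaluation.
    """
    if config.simulate is not None:
        logger.info("simulating EEG trials: %s", config.simulate)
        trials = gen_eeg_trials(config.simulate)
    elif config.input_path is not None:
        logger.info("reading trials from %s", config.input_path)
        trials = read_trials(config.input_path, config.input_format)
    else:
        raise ValueError("config must provide either input_path or simulate")

    if config.fs_target is not None and config.fs_target != trials.fs:
        logger.info("resampling %g Hz -> %g Hz", trials.fs, config.fs_target)
        res = np.stack([resample_trial(tr, trials.fs, config.fs_target)
                        for tr in trials.trials])
        trials = TrialSet(trials=res, labels=trials.labels,
                          fs=config.fs_target,
                          channel_names=trials.channel_names)

    tr_idx, te_idx = _stratified_split(trials.labels, config.test_fraction,
                                       config.split_seed)
    train = TrialSet(trials=trials.trials[tr_idx],
                     labels=trials.labels[tr_idx], fs=trials.fs,
                     channel_names=trials.channel_names)
    logger.info("extracting fused features (%d train trials, %d channels)",
                train.n_trials, train.n_channels)
    fm_train = extract_fused(train, config.feature_config)
    logger.info("cross-validating: %d alphas x %d lambdas, %d folds",
                len(config.path_spec.alpha_grid), config.path_spec.n_lambda,
                config.path_spec.folds)
    result = cross_validate(fm_train.values, train.labels,
                            fm_train.group_index, config.path_spec,
                            config.solver, config.fit_intercept)
    if te_idx.size:
        test = TrialSet(trials=trials.trials[te_idx],
                        labels=trials.labels[te_idx], fs=trials.fs,
                        channel_names=trials.channel_names)
        fm_test = extract_fused(test, config.feature_config)
        result.test_error = evaluate(result, fm_test.values, test.labels)
        logger.info("holdout error rate: %.4f", result.test_error)
    if config.out_prefix is not None:
        write_report(result, config.out_prefix,
                     channel_names=trials.channel_names)
    return result


# ------------------------------------------------------------------- YAML

def _dataclass_from_dict(cls, doc: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**doc)


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML document of nested mappings."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(doc)
    if "simulate" in kwargs and kwargs["simulate"] is not None:
        sim = dict(kwargs["simulate"])
        for key in ("active_channels", "rhythm_band", "amplitude_by_class"):
            if key in sim:
                sim[key] = tuple(sim[key])
        kwargs["simulate"] = _dataclass_from_dict(EEGSimSpec, sim)
    if "feature_config" in kwargs and kwargs["feature_config"] is not None:
        fc = dict(kwargs["feature_config"])
        if "bands" in fc:
            fc["bands"] = tuple(tuple(b) for b in fc["bands"])
        kwargs["feature_config"] = _dataclass_from_dict(FeatureConfig, fc)
    if "path_spec" in kwargs and kwargs["path_spec"] is not None:
        ps = dict(kwargs["path_spec"])
        if "alpha_grid" in ps:
            ps["alpha_grid"] = tuple(ps["alpha_grid"])
        kwargs["path_spec"] = _dataclass_from_dict(PathSpec, ps)
    if "solver" in kwargs and kwargs["solver"] is not None:
        kwargs["solver"] = _dataclass_from_dict(SolverSettings,
                                                dict(kwargs["solver"]))
    return _dataclass_from_dict(PipelineConfig, kwargs)
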