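"""Metrics, per-domain/per-flight reporting, and the experiment harnesses.

Accuracy is reported as the coefficient of determination

    R2 = 1 - sum((y - yhat)^2) / sum((y - ybar)^2)

(which can be negative) and the root-mean-square error in days.  Pooled
rows are always computed on concatenated residuals, never by averaging
per-group metrics.  Epoch curves are smoothed with a forward window mean
before turning-point detection.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import split_checks, split_train_test


def r2(observed, predicted) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal shapes")
    if observed.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R2 undefined for a constant observed vector")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(observed, predicted) -> float:
    """Root-mean-square error (days)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal shapes")
    if observed.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def evaluate_by_group(samples: pd.DataFrame, predicted, by="flight_day") -> pd.DataFrame:
    """Per-group R2/RMSE rows plus a pooled row over all samples.

    ``samples`` must carry an ``rmd`` column; ``by`` is one column name or a
    list (e.g. ``["domain_id", "flight_day"]``).  Groups with a constant
    observed vector get ``R2 = NaN`` with a warning; the pooled row uses the
    concatenated residuals of all rows.
    """
    by = [by] if isinstance(by, str) else list(by)
    predicted = np.asarray(predicted, dtype=float)
    if len(predicted) != len(samples):
        raise ValueError("predicted length must match samples")
    obs = samples["rmd"].to_numpy(dtype=float)

    rows = []
    frame = samples.reset_index(drop=True)
    for key, grp in frame.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        idx = grp.index.to_numpy()
        if len(idx) == 0:
            warnings.warn(f"empty group {key}; dropped", stacklevel=2)
            continue
        o, p = obs[idx], predicted[idx]
        try:
            group_r2 = r2(o, p)
        except ValueError:
            warnings.warn(f"R2 undefined for group {key}", stacklevel=2)
            group_r2 = np.nan
        rows.append(dict(zip(by, key)) | {"n": len(idx), "r2": group_r2, "rmse": rmse(o, p)})
    pooled = {col: "pooled" for col in by}
    pooled |= {"n": len(obs), "r2": r2(obs, predicted), "rmse": rmse(obs, predicted)}
    rows.append(pooled)
    return pd.DataFrame(rows)


def smooth_forward(series, window: int = 10) -> np.ndarray:
    """Forward windowed mean: element t averages elements t .. t+window-1.

    Tail elements average whatever remains of the series.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        return series
    return np.array(
        [series[t : t + window].mean() for t in range(len(series))]
    )


def detect_turning_point(series, patience: int = 3):
    """First index where a (smoothed) accuracy series starts decreasing.

    Returns the first index t such that the series strictly decreases for at
    least ``patience`` consecutive steps after t and never regains its value
    at t; ``None`` when no such index exists (no clear turning point).
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    for t in range(n - patience):
        window = series[t : t + patience + 1]
        if np.all(np.diff(window) < 0) and np.max(series[t + 1 :]) < series[t]:
            return t
    return None


# ---------------------------------------------------------------------------
# experiment harnesses


def _split_scenario(frame: pd.DataFrame, ratio: float = 0.8, seed: int = 0):
    """80/20 source and target splits in the study's layout."""
    source = frame.loc[frame["is_source"].astype(bool)]
    target = frame.loc[~frame["is_source"].astype(bool)]
    src = split_train_test(source, ratio=ratio, seed=seed)
    tgt = split_train_test(target, ratio=ratio, seed=seed + 1)
    return src, tgt


def run_ratio_sweep(frame: pd.DataFrame, ratios=None, arch=None, config=None,
                    eval_frame: pd.DataFrame | None = None,
                    finetune_epochs: int | None = 50) -> pd.DataFrame:
    """Fine-tuning data-volume sweep.

    Pre-trains once on the labelled source rows, then for each ratio
    fine-tunes on that fraction of the target-training split and evaluates
    before/after on the remaining target data (or on ``eval_frame`` when a
    fixed evaluation set is supplied).  Returns one row per ratio with
    before/after target metrics and after-fine-tuning source metrics.
    The sweep protocol fine-tunes for 50 epochs (``finetune_epochs=None``
    keeps the config value).
    """
    from dataclasses import replace

    from .training import TrainingConfig, finetune, pretrain

    ratios = list(np.round(np.arange(0.1, 1.0, 0.1), 10)) if ratios is None else list(ratios)
    for r in ratios:
        if not 0.0 < r < 1.0:
            raise ValueError("ratios must be in (0, 1)")
    config = config or TrainingConfig()
    if finetune_epochs is not None:
        config = replace(config, epochs_finetune=finetune_epochs)
    src, tgt = _split_scenario(frame, seed=config.seed)
    base = pretrain(src.train, arch=arch, config=config)

    rows = []
    for r in ratios:
        part = split_train_test(tgt.train, ratio=r, seed=config.seed + 17)
        eval_set = eval_frame if eval_frame is not None else part.test
        tuned = finetune(base, part.train, config=config)
        obs = eval_set["rmd"].to_numpy(dtype=float)
        obs_src = src.test["rmd"].to_numpy(dtype=float)
        rows.append(
            {
                "ratio": r,
                "n_finetune": len(part.train),
                "r2_target_before": r2(obs, base.predict(eval_set)),
                "rmse_target_before": rmse(obs, base.predict(eval_set)),
                "r2_target_after": r2(obs, tuned.predict(eval_set)),
                "rmse_target_after": rmse(obs, tuned.predict(eval_set)),
                "r2_source_after": r2(obs_src, tuned.predict(src.test)),
                "rmse_source_after": rmse(obs_src, tuned.predict(src.test)),
            }
        )
    return pd.DataFrame(rows)


def run_batch_sweep(frame: pd.DataFrame, source_batch_sizes=None, arch=None,
                    config=None, smoothing_window: int = 10, patience: int = 3):
    """Source-batch-size sweep for single-source adversarial adaptation.

    One adversarial training per batch size (target batch size fixed by the
    config); returns ``(sweep_table, histories)`` where the table carries the
    final metrics and the detected turning point of each smoothed target
    accuracy curve.
    """
    from dataclasses import replace

    from .training import TrainingConfig, train_single_source_da

    sizes = list(range(40, 201, 20)) if source_batch_sizes is None else list(source_batch_sizes)
    config = config or TrainingConfig()
    src, tgt = _split_scenario(frame, seed=config.seed)
    eval_sets = {"source": src.test, "target": tgt.test}

    histories = {}
    rows = []
    for bs in sizes:
        cfg = replace(config, batch_source=bs)
        fit = train_single_source_da(src.train, tgt.train, arch=arch, config=cfg,
                                     eval_sets=eval_sets)
        histories[bs] = fit.history
        curve = smooth_forward(fit.history["r2_target"].to_numpy(), smoothing_window)
        tp = detect_turning_point(curve, patience=patience)
        last = fit.history.iloc[-1]
        rows.append(
            {
                "batch_source": bs,
                "turning_point": np.nan if tp is None else fit.history["epoch"].iloc[tp],
                "r2_source": last["r2_source"],
                "rmse_source": last["rmse_source"],
                "r2_target": last["r2_target"],
                "rmse_target": last["rmse_target"],
            }
        )
    return pd.DataFrame(rows), histories


def run_independent_trial_scenario(frame: pd.DataFrame, arch=None, config=None) -> pd.DataFrame:
    """Compare the three techniques on fully held-out target trials.

    The pretrained model (sources, 80/20) is fine-tuned per target trial on
    that trial's check lines only and evaluated on its breeding lines; the
    adversarial arms use each trial's features without labels and are
    evaluated on all of the trial's samples.  A pretrain-only baseline row is
    reported for every trial.
    """
    from .training import TrainingConfig, finetune, pretrain, train_multi_source_da, \
        train_single_source_da

    config = config or TrainingConfig()
    source = frame.loc[frame["is_source"].astype(bool)]
    target = frame.loc[~frame["is_source"].astype(bool)]
    if len(target) == 0:
        raise ValueError("scenario has no target rows")

    src = split_train_test(source, ratio=0.8, seed=config.seed)
    base = pretrain(src.train, arch=arch, config=config)
    source_frames = [g for _, g in src.train.groupby("domain_id", sort=True)]

    rows = []
    for domain_id, trial in target.groupby("domain_id", sort=True):
        checks, breeding = split_checks(trial)
        obs_all = trial["rmd"].to_numpy(dtype=float)

        if len(checks) > 0 and len(breeding) > 0:
            obs_b = breeding["rmd"].to_numpy(dtype=float)
            rows.append({"domain_id": domain_id, "technique": "pretrain_only",
                         "n_finetune": 0, "n_test": len(breeding),
                         "r2": r2(obs_b, base.predict(breeding)),
                         "rmse": rmse(obs_b, base.predict(breeding))})
            tuned = finetune(base, checks, config=config)
            rows.append({"domain_id": domain_id, "technique": "finetune",
                         "n_finetune": len(checks), "n_test": len(breeding),
                         "r2": r2(obs_b, tuned.predict(breeding)),
                         "rmse": rmse(obs_b, tuned.predict(breeding))})
        else:
            warnings.warn(f"no check lines in {domain_id}; fine-tune arm skipped",
                          stacklevel=2)

        single = train_single_source_da(src.train, trial, arch=arch, config=config)
        rows.append({"domain_id": domain_id, "technique": "single_da",
                     "n_finetune": 0, "n_test": len(trial),
                     "r2": r2(obs_all, single.predict(trial)),
                     "rmse": rmse(obs_all, single.predict(trial))})
        multi = train_multi_source_da(source_frames, trial, arch=arch, config=config)
        rows.append({"domain_id": domain_id, "technique": "multi_da",
                     "n_finetune": 0, "n_test": len(trial),
                     "r2": r2(obs_all, multi.predict(trial)),
                     "rmse": rmse(obs_all, multi.predict(trial))})
    return pd.DataFrame(rows)


def domain_probe_accuracy(features_source, features_target, seed: int = 0,
                          test_fraction: float = 0.3) -> float:
    """Held-out accuracy of a logistic-regression domain probe.

    Measures how distinguishable two feature sets are: rows from both
    domains are pooled, split train/test, and a logistic regression is fit
    to predict the domain.  Near 0.5 means the representations are aligned;
    near 1.0 means the domains remain separable.
    """
    from sklearn.linear_model import LogisticRegression

    Xs = np.asarray(features_source, dtype=float)
    Xt = np.asarray(features_target, dtype=float)
    X = np.concatenate([Xs, Xt], axis=0)
    y = np.r_[np.zeros(len(Xs)), np.ones(len(Xt))]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(X))
    n_test = int(round(test_fraction * len(X)))
    test, train = perm[:n_test], perm[n_test:]
    clf = LogisticRegression(max_iter=2000)
    clf.fit(X[train], y[train])
    return float(clf.score(X[test], y[test]))
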