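"""Model/Results interface over the transfer-learning procedures.

``MaturityTransferModel`` is constructed from plot-sample frames and a
technique name; ``fit()`` runs the corresponding training procedure and
returns a ``MaturityTransferResults`` carrying the trained parameters,
scaler, per-epoch history and evaluation helpers, with ``summary()`` for a
human-readable report and ``save``/``load`` for checkpoints.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .data import FEATURE_COLUMNS
from .evaluation import evaluate_by_group, r2, rmse
from .networks import ArchitectureSpec, LinearParams, NetworkParams, Standardizer
from .training import (
    FitResult,
    TrainingConfig,
    finetune,
    pretrain,
    train_multi_source_da,
    train_single_source_da,
)

TECHNIQUES = ("pretrain", "finetune", "single_da", "multi_da")

CHECKPOINT_FORMAT_VERSION = 1


class MaturityTransferModel:
    """A relative-maturity-date predictor with a transfer-learning technique.

    Parameters
    ----------
    source : DataFrame or list of DataFrame
        Labelled source-domain samples.  For ``multi_da`` pass a list (one
        frame per source domain) or a single frame that will be grouped by
        ``domain_id``.
    target : DataFrame, optional
        Target-domain samples.  ``finetune`` reads their RMD labels;
        the adversarial techniques use only the feature columns.
    technique : {"pretrain", "finetune", "single_da", "multi_da"}
    arch, config : architecture and optimisation settings (defaults apply).
    """

    def __init__(self, source, target=None, technique: str = "finetune",
                 arch: ArchitectureSpec | None = None,
                 config: TrainingConfig | None = None):
        if technique not in TECHNIQUES:
            raise ValueError(f"technique must be one of {TECHNIQUES}")
        if technique != "pretrain" and target is None:
            raise ValueError(f"technique {technique!r} requires a target frame")
        self.source = source
        self.target = target
        self.technique = technique
        self.arch = arch or ArchitectureSpec()
        self.config = config or TrainingConfig()

    @classmethod
    def from_frames(cls, frame: pd.DataFrame, technique: str = "finetune",
                    **kwargs) -> "MaturityTransferModel":
        """Build from one combined table using its ``is_source`` flags."""
        source = frame.loc[frame["is_source"].astype(bool)]
        target = frame.loc[~frame["is_source"].astype(bool)]
        if technique == "multi_da":
            source = [g for _, g in source.groupby("domain_id", sort=True)]
        return cls(source, target if len(target) else None, technique, **kwargs)

    def fit(self, eval_sets=None) -> "MaturityTransferResults":
        source = self.source
        if self.technique == "multi_da":
            if isinstance(source, pd.DataFrame):
                source = [g for _, g in source.groupby("domain_id", sort=True)]
            fit = train_multi_source_da(source, self.target, self.arch, self.config,
                                        eval_sets=eval_sets)
            pre_history = None
        elif self.technique == "single_da":
            if isinstance(source, (list, tuple)):
                source = pd.concat(source, ignore_index=True)
            fit = train_single_source_da(source, self.target, self.arch, self.config,
                                         eval_sets=eval_sets)
            pre_history = None
        else:
            if isinstance(source, (list, tuple)):
                source = pd.concat(source, ignore_index=True)
            base = pretrain(source, self.arch, self.config, eval_sets=eval_sets)
            if self.technique == "pretrain":
                fit, pre_history = base, None
            else:
                fit = finetune(base, self.target, self.config, eval_sets=eval_sets)
                pre_history = base.history
        return MaturityTransferResults(self, fit, pre_history)


class MaturityTransferResults:
    """Fitted parameters, training history and evaluation helpers."""

    def __init__(self, model: MaturityTransferModel, fit: FitResult,
                 pretrain_history: pd.DataFrame | None = None):
        self.model = model
        self.fit = fit
        self.params: NetworkParams = fit.params
        self.scaler: Standardizer = fit.scaler
        self.history: pd.DataFrame = fit.history
        self.pretrain_history = pretrain_history

    def predict(self, data) -> np.ndarray:
        """Predicted RMD (days) for a feature table or (n, 7) array."""
        return self.fit.predict(data)

    def latent(self, data) -> np.ndarray:
        """Learned (extractor-output) features."""
        return self.fit.latent(data)

    def evaluate(self, samples: pd.DataFrame, by="flight_day",
                 bootstrap_ci: int = 0, seed: int = 0) -> pd.DataFrame:
        """Per-group and pooled R2/RMSE report for labelled samples.

        With ``bootstrap_ci`` > 0, pooled-RMSE percentile intervals from
        that many bootstrap resamples are attached to the report attrs.
        """
        pred = self.predict(samples)
        report = evaluate_by_group(samples, pred, by=by)
        if bootstrap_ci > 0:
            obs = samples["rmd"].to_numpy(dtype=float)
            rng = np.random.default_rng(seed)
            stats = [
                rmse(obs[idx], pred[idx])
                for idx in (rng.integers(0, len(obs), len(obs))
                            for _ in range(bootstrap_ci))
            ]
            report.attrs["rmse_ci"] = (
                float(np.percentile(stats, 2.5)),
                float(np.percentile(stats, 97.5)),
            )
        return report

    def summary(self, eval_sets=None) -> str:
        """Plain-text summary of the fitted model."""
        m = self.model
        a = m.arch
        lines = [
            "Maturity transfer model results",
            "=" * 34,
            f"technique:       {m.technique}",
            f"extractor:       {' -> '.join(map(str, a.extractor_widths))} ({a.activation})",
            f"predictor:       {' -> '.join(map(str, a.predictor_widths))}",
            f"classifiers:     {len(self.params.classifiers)} x "
            f"{' -> '.join(map(str, a.classifier_widths))}",
            f"grl lambda:      {a.grl_lambda}",
            f"seed:            {m.config.seed}",
        ]
        if len(self.history):
            last = self.history.iloc[-1]
            lines.append(f"epochs run:      {int(last['epoch'])}")
            lines.append(f"final loss_y:    {last['loss_y']:.4f}")
            if np.isfinite(last.get("loss_d", np.nan)):
                lines.append(f"final loss_d:    {last['loss_d']:.4f}")
        for name, frame in (eval_sets or {}).items():
            obs = frame["rmd"].to_numpy(dtype=float)
            pred = self.predict(frame)
            lines.append(
                f"{name:<12s} n={len(frame):<6d} R2={r2(obs, pred):6.3f} "
                f"RMSE={rmse(obs, pred):5.2f} days"
            )
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Serialise architecture, scaler and all parameters to one archive."""
        arrays = {}
        for i, layer in enumerate(self.params.extractor):
            arrays[f"extractor_{i}_W"], arrays[f"extractor_{i}_b"] = layer.W, layer.b
        for i, layer in enumerate(self.params.predictor):
            arrays[f"predictor_{i}_W"], arrays[f"predictor_{i}_b"] = layer.W, layer.b
        for j, clf in enumerate(self.params.classifiers):
            for i, layer in enumerate(clf):
                arrays[f"classifier_{j}_{i}_W"] = layer.W
                arrays[f"classifier_{j}_{i}_b"] = layer.b
        a = self.model.arch
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "technique": self.model.technique,
            "n_classifiers": len(self.params.classifiers),
            "arch": {
                "extractor_widths": list(a.extractor_widths),
                "predictor_widths": list(a.predictor_widths),
                "classifier_widths": list(a.classifier_widths),
                "activation": a.activation,
                "freeze_depth": a.freeze_depth,
                "grl_lambda": a.grl_lambda,
            },
            "scaler": {
                "mean": self.scaler.mean.tolist(),
                "scale": self.scaler.scale.tolist(),
            },
            "features": FEATURE_COLUMNS,
        }
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "MaturityTransferResults":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ValueError("unsupported checkpoint format version")
            arch = ArchitectureSpec(
                extractor_widths=tuple(meta["arch"]["extractor_widths"]),
                predictor_widths=tuple(meta["arch"]["predictor_widths"]),
                classifier_widths=tuple(meta["arch"]["classifier_widths"]),
                activation=meta["arch"]["activation"],
                freeze_depth=meta["arch"]["freeze_depth"],
                grl_lambda=meta["arch"]["grl_lambda"],
            )

            def layers(prefix, n):
                return [
                    LinearParams(archive[f"{prefix}_{i}_W"], archive[f"{prefix}_{i}_b"])
                    for i in range(n)
                ]

            params = NetworkParams(
                extractor=layers("extractor", len(arch.extractor_widths) - 1),
                predictor=layers("predictor", len(arch.predictor_widths) - 1),
                classifiers=[
                    layers(f"classifier_{j}", len(arch.classifier_widths) - 1)
                    for j in range(meta["n_classifiers"])
                ],
            )
            scaler = Standardizer(
                mean=np.array(meta["scaler"]["mean"]),
                scale=np.array(meta["scaler"]["scale"]),
            )
        model = MaturityTransferModel.__new__(MaturityTransferModel)
        model.source = None
        model.target = None
        model.technique = meta["technique"]
        model.arch = arch
        model.config = TrainingConfig()
        fit = FitResult(params, scaler, arch, model.config)
        return cls(model, fit)
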