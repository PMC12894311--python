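"""The three transfer-learning procedures.

(a) ``pretrain`` + ``finetune``: train extractor + predictor on labelled
    source data, then adapt to a small labelled target subset with the
    leading extractor layers frozen;
(b) ``train_single_source_da``: adversarial domain adaptation against one
    pooled source domain, using target features but never target labels;
(c) ``train_multi_source_da``: one domain classifier per source domain,
    each discriminating that source from the target, with the mean
    classification loss driving a shared extractor.

Every procedure is a pure function of (data, architecture, config, seed):
given identical inputs it returns bit-identical parameters.  Optimisation is
Adam on minibatches; for the adversarial procedures each epoch is driven by
the target set (each target sample appears exactly once; source rows are
drawn by reshuffled cycling so every paired batch has a full source batch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import FEATURE_COLUMNS, SourceCycler, paired_epoch_indices
from .networks import (
    ArchitectureSpec,
    NetworkParams,
    Standardizer,
    _mlp_backward,
    _mlp_forward,
    init_network,
    log_softmax,
    logsoftmax_backward,
    mse_loss,
    mse_loss_grad,
    nll_loss,
    nll_loss_grad,
)


@dataclass
class TrainingConfig:
    """Optimisation constants for all three procedures.

    Epoch defaults follow the study protocol: 50 pre-training epochs, 20
    fine-tuning epochs (the observed balance point between target gains and
    source degradation), 100 adversarial epochs with the target batch size
    fixed at 100.
    """

    epochs_pretrain: int = 50
    epochs_finetune: int = 20
    epochs_da: int = 100
    batch_size: int = 100        # pretrain / finetune minibatch
    batch_source: int = 100
    batch_target: int = 100
    lr_pretrain: float = 1e-3
    lr_finetune: float = 3e-4
    lr_da: float = 1e-3
    lr_classifier: float = 1e-2   # domain-classifier rate (stronger adversary)
    classifier_steps: int = 5     # classifier updates per paired batch
    grl_schedule: str = "constant"  # or "ramp"
    seed: int = 0
    eval_every: int = 1

    def __post_init__(self):
        for name in ("epochs_pretrain", "epochs_finetune", "epochs_da"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("batch_size", "batch_source", "batch_target", "eval_every"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("lr_pretrain", "lr_finetune", "lr_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lr_classifier <= 0:
            raise ValueError("lr_classifier must be > 0")
        if self.classifier_steps < 1:
            raise ValueError("classifier_steps must be >= 1")
        if self.grl_schedule not in ("constant", "ramp"):
            raise ValueError("grl_schedule must be 'constant' or 'ramp'")


class Adam:
    """Adam with bias correction; ``None`` gradients leave a parameter frozen."""

    def __init__(self, arrays, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.arrays = arrays
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for i, g in enumerate(grads):
            if g is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g**2
            self.arrays[i] -= (
                self.lr * (self.m[i] / b1c) / (np.sqrt(self.v[i] / b2c) + self.eps)
            )


@dataclass
class FitResult:
    """Trained parameters plus the scaler and per-epoch history."""

    params: NetworkParams
    scaler: Standardizer
    arch: ArchitectureSpec
    config: TrainingConfig
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict(self, data) -> np.ndarray:
        """Predicted RMD (days) for a feature table or (n, 7) array."""
        X = _features_of(data)
        latent, _ = _mlp_forward(self.scaler.transform(X), self.params.extractor,
                                 self.arch.activation)
        pred, _ = _mlp_forward(latent, self.params.predictor, self.arch.activation,
                               hidden_act_only=True)
        return pred[:, 0]

    def latent(self, data) -> np.ndarray:
        """Extractor outputs (learned features) for a feature table."""
        X = _features_of(data)
        out, _ = _mlp_forward(self.scaler.transform(X), self.params.extractor,
                              self.arch.activation)
        return out


def _features_of(data) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        return data[FEATURE_COLUMNS].to_numpy(dtype=float)
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_COLUMNS):
        raise ValueError("expected an (n, 7) feature array")
    return X


def _labels_of(data) -> np.ndarray:
    y = data["rmd"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing RMD labels in a labelled set")
    return y


def _metrics_row(fit_like, eval_sets) -> dict:
    from .evaluation import r2, rmse

    row = {}
    for name, frame in (eval_sets or {}).items():
        pred = fit_like.predict(frame)
        obs = frame["rmd"].to_numpy(dtype=float)
        row[f"r2_{name}"] = r2(obs, pred)
        row[f"rmse_{name}"] = rmse(obs, pred)
    return row


def _grl_lambda_at(arch, config, epoch, total_epochs) -> float:
    if config.grl_schedule == "constant" or total_epochs == 0:
        return arch.grl_lambda
    p = epoch / total_epochs
    return arch.grl_lambda * (2.0 / (1.0 + np.exp(-10.0 * p)) - 1.0)


def _supervised_step(X, y, params, arch, opt, frozen_extractor_layers=0):
    """One Adam step on the prediction loss; returns the batch loss."""
    latent, cache_f = _mlp_forward(X, params.extractor, arch.activation)
    pred, cache_y = _mlp_forward(latent, params.predictor, arch.activation,
                                 hidden_act_only=True)
    loss = mse_loss(pred[:, 0], y)
    g_pred = mse_loss_grad(pred[:, 0], y)[:, None]
    g_latent, grads_y = _mlp_backward(g_pred, params.predictor, cache_y,
                                      arch.activation, hidden_act_only=True)
    _, grads_f = _mlp_backward(g_latent, params.extractor, cache_f, arch.activation)
    flat_grads = []
    for i, g in enumerate(grads_f):
        if i < frozen_extractor_layers:
            flat_grads += [None, None]
        else:
            flat_grads += [g.W, g.b]
    for g in grads_y:
        flat_grads += [g.W, g.b]
    opt.step(flat_grads)
    return loss


def pretrain(source_train, arch=None, config=None, eval_sets=None) -> FitResult:
    """Train extractor + predictor from scratch on labelled source data."""
    arch = arch or ArchitectureSpec()
    config = config or TrainingConfig()
    if len(source_train) == 0:
        raise ValueError("empty source training set")
    X_raw = _features_of(source_train)
    y = _labels_of(source_train)
    scaler = Standardizer.fit(X_raw)
    X = scaler.transform(X_raw)

    ss = np.random.SeedSequence(config.seed)
    init_ss, shuffle_ss = ss.spawn(2)
    params = init_network(arch, np.random.default_rng(init_ss))
    params.classifiers = []
    fit = FitResult(params, scaler, arch, config)
    arrays = [a for layer in params.extractor + params.predictor for a in (layer.W, layer.b)]
    opt = Adam(arrays, lr=config.lr_pretrain)
    rng = np.random.default_rng(shuffle_ss)

    rows = []
    for epoch in range(1, config.epochs_pretrain + 1):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), config.batch_size):
            idx = order[start : start + config.batch_size]
            losses.append(_supervised_step(X[idx], y[idx], params, arch, opt))
        if epoch % config.eval_every == 0 or epoch == config.epochs_pretrain:
            row = {"epoch": epoch, "loss_y": float(np.mean(losses)), "loss_d": np.nan}
            row.update(_metrics_row(fit, eval_sets))
            rows.append(row)
    fit.history = pd.DataFrame(rows)
    return fit


def finetune(fit: FitResult, target_labeled, config=None, eval_sets=None) -> FitResult:
    """Adapt a pretrained model to labelled target samples.

    The first ``freeze_depth`` extractor layers are left exactly unchanged
    (their learned source representations are preserved); the remaining
    extractor layers and the predictor are updated at the fine-tuning
    learning rate.  The input scaler is inherited from pre-training.
    """
    config = config or fit.config
    arch = fit.arch
    if len(target_labeled) == 0:
        raise ValueError("empty fine-tuning set")
    y = _labels_of(target_labeled)
    X = fit.scaler.transform(_features_of(target_labeled))

    params = fit.params.copy()
    new_fit = FitResult(params, fit.scaler, arch, config)
    arrays = [a for layer in params.extractor + params.predictor for a in (layer.W, layer.b)]
    opt = Adam(arrays, lr=config.lr_finetune)
    ss = np.random.SeedSequence(config.seed)
    (shuffle_ss,) = ss.spawn(1)
    rng = np.random.default_rng(shuffle_ss)

    rows = []
    for epoch in range(1, config.epochs_finetune + 1):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), config.batch_size):
            idx = order[start : start + config.batch_size]
            losses.append(
                _supervised_step(X[idx], y[idx], params, arch, opt,
                                 frozen_extractor_layers=arch.freeze_depth)
            )
        if epoch % config.eval_every == 0 or epoch == config.epochs_finetune:
            row = {"epoch": epoch, "loss_y": float(np.mean(losses)), "loss_d": np.nan}
            row.update(_metrics_row(new_fit, eval_sets))
            rows.append(row)
    new_fit.history = pd.DataFrame(rows)
    return new_fit


def _da_train(sources, target_features, arch, config, eval_sets):
    """Shared adversarial training core; ``sources`` is a list of frames."""
    arch = arch or ArchitectureSpec()
    config = config or TrainingConfig()
    k = len(sources)
    if k == 0:
        raise ValueError("at least one source domain required")
    for s in sources:
        if len(s) == 0:
            raise ValueError("empty source domain")
    if len(target_features) == 0:
        raise ValueError("empty target domain")

    Xs_raw = [_features_of(s) for s in sources]
    ys = [_labels_of(s) for s in sources]
    scaler = Standardizer.fit(np.concatenate(Xs_raw, axis=0))
    Xs = [scaler.transform(x) for x in Xs_raw]
    Xt = scaler.transform(_features_of(target_features))

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 + k)
    params = init_network(arch, np.random.default_rng(children[0]), n_classifiers=k)
    fit = FitResult(params, scaler, arch, config)
    main_arrays = [a for layer in params.extractor + params.predictor
                   for a in (layer.W, layer.b)]
    clf_arrays = [a for clf in params.classifiers for layer in clf
                  for a in (layer.W, layer.b)]
    opt = Adam(main_arrays, lr=config.lr_da)
    opt_clf = Adam(clf_arrays, lr=config.lr_classifier)
    tgt_rng = np.random.default_rng(children[1])
    cyclers = [
        SourceCycler(len(x), np.random.default_rng(children[2 + j]))
        for j, x in enumerate(Xs)
    ]

    rows = []
    for epoch in range(1, config.epochs_da + 1):
        lam = _grl_lambda_at(arch, config, epoch, config.epochs_da)
        ly_epoch, ld_epoch = [], []
        for src_idx, tgt_idx in paired_epoch_indices(
            len(Xt), config.batch_target, cyclers, config.batch_source, tgt_rng
        ):
            xb = [Xs[j][src_idx[j]] for j in range(k)]
            yb = [ys[j][src_idx[j]] for j in range(k)]
            tb = Xt[tgt_idx]
            sizes = [len(x) for x in xb]
            offsets = np.concatenate([[0], np.cumsum(sizes)])
            n_src, n_tgt = offsets[-1], len(tb)
            X = np.concatenate(xb + [tb], axis=0)

            latent, cache_f = _mlp_forward(X, params.extractor, arch.activation)
            g_latent = np.zeros_like(latent)

            # extra classifier-only updates on the current latents keep the
            # adversary competitive with the drifting representation
            for _ in range(config.classifier_steps - 1):
                flat_d = []
                for j in range(k):
                    rows_j = np.r_[offsets[j] : offsets[j + 1], n_src : n_src + n_tgt]
                    logits, cache_d = _mlp_forward(latent[rows_j], params.classifiers[j],
                                                   arch.activation, hidden_act_only=True)
                    logp = log_softmax(logits)
                    labels = np.r_[np.zeros(sizes[j], dtype=int),
                                   np.ones(n_tgt, dtype=int)]
                    g_logits = logsoftmax_backward(nll_loss_grad(logp, labels) / k, logp)
                    _, gd = _mlp_backward(g_logits, params.classifiers[j], cache_d,
                                          arch.activation, hidden_act_only=True)
                    for g in gd:
                        flat_d += [g.W, g.b]
                opt_clf.step(flat_d)

            # prediction loss on all labelled source rows
            y = np.concatenate(yb)
            pred, cache_y = _mlp_forward(latent[:n_src], params.predictor,
                                         arch.activation, hidden_act_only=True)
            ly = mse_loss(pred[:, 0], y)
            g_pred = mse_loss_grad(pred[:, 0], y)[:, None]
            g_lat_src, grads_y = _mlp_backward(g_pred, params.predictor, cache_y,
                                               arch.activation, hidden_act_only=True)
            g_latent[:n_src] += g_lat_src

            # per-source domain classifiers on source_j + target rows,
            # aggregated as the mean loss; extractor gradients reversed
            grads_d = []
            ld_parts = []
            for j in range(k):
                rows_j = np.r_[offsets[j] : offsets[j + 1], n_src : n_src + n_tgt]
                lat_j = latent[rows_j]
                logits, cache_d = _mlp_forward(lat_j, params.classifiers[j],
                                               arch.activation, hidden_act_only=True)
                logp = log_softmax(logits)
                labels = np.r_[np.zeros(sizes[j], dtype=int), np.ones(n_tgt, dtype=int)]
                ld_parts.append(nll_loss(logp, labels))
                g_logp = nll_loss_grad(logp, labels) / k
                g_logits = logsoftmax_backward(g_logp, logp)
                g_lat_j, gd = _mlp_backward(g_logits, params.classifiers[j], cache_d,
                                            arch.activation, hidden_act_only=True)
                grads_d.append(gd)
                # gradient reversal: the extractor ascends the domain loss
                g_latent[rows_j] += -lam * g_lat_j

            _, grads_f = _mlp_backward(g_latent, params.extractor, cache_f,
                                       arch.activation)

            flat = []
            for g in grads_f + grads_y:
                flat += [g.W, g.b]
            opt.step(flat)
            flat_d = []
            for gd in grads_d:
                for g in gd:
                    flat_d += [g.W, g.b]
            opt_clf.step(flat_d)
            ly_epoch.append(ly)
            ld_epoch.append(float(np.mean(ld_parts)))

        if epoch % config.eval_every == 0 or epoch == config.epochs_da:
            row = {
                "epoch": epoch,
                "loss_y": float(np.mean(ly_epoch)),
                "loss_d": float(np.mean(ld_epoch)),
            }
            row.update(_metrics_row(fit, eval_sets))
            rows.append(row)
    fit.history = pd.DataFrame(rows)
    return fit


def train_single_source_da(source_labeled, target_unlabeled, arch=None, config=None,
                           eval_sets=None) -> FitResult:
    """Adversarial adaptation against one pooled source domain.

    Target rows contribute only to the domain-classification loss; their RMD
    labels (if present in the frame) are never read.
    """
    arch = arch or ArchitectureSpec()
    config = config or TrainingConfig()
    if len(source_labeled) == 0 or len(target_unlabeled) == 0:
        raise ValueError("source and target must both be non-empty")

    X_raw = _features_of(source_labeled)
    y = _labels_of(source_labeled)
    scaler = Standardizer.fit(X_raw)
    Xs = scaler.transform(X_raw)
    Xt = scaler.transform(_features_of(target_unlabeled))

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(3)
    params = init_network(arch, np.random.default_rng(children[0]), n_classifiers=1)
    fit = FitResult(params, scaler, arch, config)
    main_arrays = [a for layer in params.extractor + params.predictor
                   for a in (layer.W, layer.b)]
    clf_arrays = [a for layer in params.classifiers[0] for a in (layer.W, layer.b)]
    opt = Adam(main_arrays, lr=config.lr_da)
    opt_clf = Adam(clf_arrays, lr=config.lr_classifier)
    tgt_rng = np.random.default_rng(children[1])
    cycler = SourceCycler(len(Xs), np.random.default_rng(children[2]))

    history_rows = []
    for epoch in range(1, config.epochs_da + 1):
        lam = _grl_lambda_at(arch, config, epoch, config.epochs_da)
        ly_epoch, ld_epoch = [], []
        for src_idx, tgt_idx in paired_epoch_indices(
            len(Xt), config.batch_target, [cycler], config.batch_source, tgt_rng
        ):
            xb, tb = Xs[src_idx[0]], Xt[tgt_idx]
            ns, nt = len(xb), len(tb)
            X = np.concatenate([xb, tb], axis=0)

            latent, cache_f = _mlp_forward(X, params.extractor, arch.activation)
            labels = np.r_[np.zeros(ns, dtype=int), np.ones(nt, dtype=int)]

            # extra classifier-only updates on the current latents keep the
            # adversary competitive with the drifting representation
            for _ in range(config.classifier_steps - 1):
                logits, cache_d = _mlp_forward(latent, params.classifiers[0],
                                               arch.activation, hidden_act_only=True)
                logp = log_softmax(logits)
                g_logits = logsoftmax_backward(nll_loss_grad(logp, labels), logp)
                _, gd = _mlp_backward(g_logits, params.classifiers[0], cache_d,
                                      arch.activation, hidden_act_only=True)
                opt_clf.step([a for g in gd for a in (g.W, g.b)])

            pred, cache_y = _mlp_forward(latent[:ns], params.predictor,
                                         arch.activation, hidden_act_only=True)
            ly = mse_loss(pred[:, 0], y[src_idx[0]])
            g_pred = mse_loss_grad(pred[:, 0], y[src_idx[0]])[:, None]
            g_lat_src, grads_y = _mlp_backward(g_pred, params.predictor, cache_y,
                                               arch.activation, hidden_act_only=True)

            logits, cache_d = _mlp_forward(latent, params.classifiers[0],
                                           arch.activation, hidden_act_only=True)
            logp = log_softmax(logits)
            ld = nll_loss(logp, labels)
            g_logits = logsoftmax_backward(nll_loss_grad(logp, labels), logp)
            g_lat_all, grads_d = _mlp_backward(g_logits, params.classifiers[0], cache_d,
                                               arch.activation, hidden_act_only=True)

            g_latent = -lam * g_lat_all
            g_latent[:ns] += g_lat_src
            _, grads_f = _mlp_backward(g_latent, params.extractor, cache_f,
                                       arch.activation)

            flat = []
            for g in grads_f + grads_y:
                flat += [g.W, g.b]
            opt.step(flat)
            opt_clf.step([a for g in grads_d for a in (g.W, g.b)])
            ly_epoch.append(ly)
            ld_epoch.append(ld)

        if epoch % config.eval_every == 0 or epoch == config.epochs_da:
            row = {
                "epoch": epoch,
                "loss_y": float(np.mean(ly_epoch)),
                "loss_d": float(np.mean(ld_epoch)),
            }
            row.update(_metrics_row(fit, eval_sets))
            history_rows.append(row)
    fit.history = pd.DataFrame(history_rows)
    return fit


def train_multi_source_da(source_domains, target_unlabeled, arch=None, config=None,
                          eval_sets=None) -> FitResult:
    """Adversarial adaptation with one domain classifier per source domain.

    Each classifier discriminates its source from the target; the aggregate
    classification loss is the unweighted mean over classifiers.  With a
    single source domain this reproduces single-source adaptation step for
    step at equal seed and config.
    """
    if not isinstance(source_domains, (list, tuple)):
        raise TypeError("source_domains must be a list of frames")
    return _da_train(list(source_domains), target_unlabeled, arch, config, eval_sets)
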