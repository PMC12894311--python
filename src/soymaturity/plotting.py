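"""Basic figures: predicted-vs-visual scatter and epoch curves."""

from __future__ import annotations

import numpy as np

from .evaluation import detect_turning_point, smooth_forward


def plot_predictions(samples, predicted, ax=None, by="flight_day"):
    """Scatter of predicted vs visually scored RMD, coloured by flight."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    obs = samples["rmd"].to_numpy(dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    for key, grp in samples.reset_index(drop=True).groupby(by, sort=True):
        idx = grp.index.to_numpy()
        ax.scatter(obs[idx], predicted[idx], s=8, alpha=0.5, label=f"{by}={key}")
    lims = [min(obs.min(), predicted.min()) - 1, max(obs.max(), predicted.max()) + 1]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("visual RMD (days)")
    ax.set_ylabel("predicted RMD (days)")
    ax.legend(fontsize=8)
    return ax


def plot_epoch_curves(history, metric="r2", ax=None, window=10, patience=3,
                      mark_turning_point=True):
    """Source/target accuracy along epochs, with the turning point starred."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    epochs = history["epoch"].to_numpy()
    for split, style in (("source", "-"), ("target", "-.")):
        col = f"{metric}_{split}"
        if col not in history:
            continue
        ax.plot(epochs, history[col], style, label=f"{split} testing")
        if split == "target" and mark_turning_point:
            curve = smooth_forward(history[col].to_numpy(), window)
            tp = detect_turning_point(curve, patience=patience)
            if tp is not None:
                ax.plot(epochs[tp], history[col].iloc[tp], "k*", ms=12)
    ax.set_xlabel("epoch")
    ax.set_ylabel(metric)
    ax.legend(fontsize=8)
    return ax
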