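"""Label construction, filtering, splitting and paired-batch iteration.

All day-valued fields are integers counted from September 1 = day 1.  The
relative maturity date (RMD) of a plot on an imaging day is

    rmd = imaging_day - maturity_day

so negative values mean the plot matures after imaging and positive values
mean it had already matured.  Samples with RMD <= -15 or >= 20 fall outside
the window the flights can resolve and are excluded before modelling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the seven model features, in canonical column order
FEATURE_COLUMNS = ["CCCI", "MTVI2", "BNDVI", "GLI", "CI", "H", "V"]

#: full plot-sample CSV schema
SAMPLE_COLUMNS = [
    "domain_id",
    "trial",
    "year",
    "plot_id",
    "flight_day",
    "dap",
    "maturity_day",
    "rmd",
    "is_check",
    "is_source",
] + FEATURE_COLUMNS


def compute_rmd(maturity_day, imaging_day):
    """Relative maturity date: imaging day minus maturity day, in days."""
    return imaging_day - maturity_day


def filter_by_rmd(samples: pd.DataFrame, lo: int = -15, hi: int = 20) -> pd.DataFrame:
    """Retain samples with lo < rmd < hi (both bounds excluded)."""
    keep = (samples["rmd"] > lo) & (samples["rmd"] < hi)
    out = samples.loc[keep]
    logger.info("RMD filter retained %d of %d samples", len(out), len(samples))
    return out


@dataclass
class SplitResult:
    train: pd.DataFrame
    test: pd.DataFrame
    ratio: float
    seed: int


def split_train_test(samples: pd.DataFrame, ratio: float = 0.8, seed: int = 0) -> SplitResult:
    """Random row-level split; |train| = round-half-even(ratio * n)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n = len(samples)
    if n == 0:
        raise ValueError("cannot split an empty table")
    n_train = int(round(ratio * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return SplitResult(
        train=samples.iloc[perm[:n_train]],
        test=samples.iloc[perm[n_train:]],
        ratio=ratio,
        seed=seed,
    )


def split_by_plot(samples: pd.DataFrame, ratio: float = 0.8, seed: int = 0) -> SplitResult:
    """Plot-grouped split: a plot's flights never straddle train and test."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    plots = samples["plot_id"].unique()
    if len(plots) == 0:
        raise ValueError("cannot split an empty table")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(plots))
    n_train = int(round(ratio * len(plots)))
    train_plots = set(plots[perm[:n_train]])
    in_train = samples["plot_id"].isin(train_plots)
    return SplitResult(
        train=samples.loc[in_train], test=samples.loc[~in_train], ratio=ratio, seed=seed
    )


def split_checks(samples: pd.DataFrame):
    """Partition by the check flag -> (check set, breeding set)."""
    checks = samples.loc[samples["is_check"].astype(bool)]
    breeding = samples.loc[~samples["is_check"].astype(bool)]
    if len(checks) == 0:
        warnings.warn("no check samples in table", stacklevel=2)
    return checks, breeding


class SourceCycler:
    """Reshuffled cycling over source row indices.

    Each call to :meth:`take` returns the next ``k`` indices of a shuffled
    stream; when the stream is exhausted it is reshuffled, so every paired
    batch receives a full source batch regardless of the source set size.
    """

    def __init__(self, n: int, rng: np.random.Generator):
        if n < 1:
            raise ValueError("empty source domain")
        self.n = n
        self.rng = rng
        self._order = rng.permutation(n)
        self._pos = 0

    def take(self, k: int) -> np.ndarray:
        out = np.empty(k, dtype=int)
        filled = 0
        while filled < k:
            avail = self.n - self._pos
            grab = min(avail, k - filled)
            out[filled : filled + grab] = self._order[self._pos : self._pos + grab]
            self._pos += grab
            filled += grab
            if self._pos == self.n:
                self._order = self.rng.permutation(self.n)
                self._pos = 0
        return out


def n_batches_per_epoch(n_target: int, batch_target: int) -> int:
    return int(np.ceil(n_target / batch_target))


def paired_epoch_indices(
    n_target: int,
    batch_target: int,
    cyclers: list,
    batch_source: int,
    rng: np.random.Generator,
):
    """Index-level paired batches for one epoch.

    The epoch is driven by the target set: the target rows are shuffled and
    chunked so each appears exactly once (last chunk may be short); every
    chunk is paired with a full ``batch_source`` draw from each source cycler.
    Yields ``(source_index_list, target_indices)``.
    """
    order = rng.permutation(n_target)
    for start in range(0, n_target, batch_target):
        tgt = order[start : start + batch_target]
        srcs = [c.take(batch_source) for c in cyclers]
        yield srcs, tgt


def make_da_batches(
    source: pd.DataFrame,
    target: pd.DataFrame,
    batch_source: int,
    batch_target: int = 100,
    seed: int = 0,
):
    """One epoch of paired (source batch, target batch) DataFrames.

    The number of batches is ceil(n_target / batch_target); target samples
    each appear exactly once per epoch while source rows are drawn by
    reshuffled cycling.
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("source and target must both be non-empty")
    if batch_source < 1 or batch_target < 1:
        raise ValueError("batch sizes must be >= 1")
    ss = np.random.SeedSequence(seed)
    tgt_rng, src_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    cycler = SourceCycler(len(source), src_rng)
    pairs = []
    for srcs, tgt in paired_epoch_indices(
        len(target), batch_target, [cycler], batch_source, tgt_rng
    ):
        pairs.append((source.iloc[srcs[0]], target.iloc[tgt]))
    return pairs


def write_plot_table(samples: pd.DataFrame, path) -> None:
    """Write the plot-sample table in the canonical CSV schema."""
    samples.to_csv(path, index=False, columns=SAMPLE_COLUMNS)


def read_plot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plot table missing columns: {sorted(missing)}")
    return df
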