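"""Metrics, the leave-one-subject-out protocol and model comparison.

Two complementary metrics are reported per channel:

* nRMSE — root-mean-square error divided by the range of the ground-truth
  series.  The range is taken per evaluated trial, then nRMSE is averaged
  over trials; this makes kinematic and kinetic channels comparable but is
  sensitive to offsets and punishes the small-range non-sagittal channels.
* Pearson r — shape agreement, blind to offset and scale; aggregated by the
  median over trials.

The leave-one-subject-out (LOSO) protocol folds over the subjects that have
measured-IMU trials: each fold trains on every other subject's simulated and
measured samples (scalers refitted inside the fold on its training partition
only) and tests on the held-out subject's measured trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
import warnings

import numpy as np
import pandas as pd

from .dataset import build_samples, split_by_subject
from .models import (
    FAMILY_LAYOUT,
    JointPredictionModel,
    NetSpec,
)
from .preprocess import (
    apply_scalers,
    assemble_flat,
    assemble_image,
    assemble_sequence,
    fit_scalers,
)
from .syngait import CHANNELS, StudyBundle


def nrmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """RMSE normalised to the range of the ground-truth series (fraction)."""
    pred = np.asarray(pred, float).ravel()
    truth = np.asarray(truth, float).ravel()
    if pred.shape != truth.shape or len(truth) < 2:
        raise ValueError("pred and truth must be equal-length series (>= 2)")
    rng = truth.max() - truth.min()
    if rng == 0:
        return np.nan  # undefined for constant truth; caller excludes
    return float(np.sqrt(np.mean((pred - truth) ** 2)) / rng)


def pearson_r(pred: np.ndarray, truth: np.ndarray) -> float:
    """Sample Pearson correlation coefficient."""
    pred = np.asarray(pred, float).ravel()
    truth = np.asarray(truth, float).ravel()
    if pred.shape != truth.shape or len(truth) < 2:
        raise ValueError("pred and truth must be equal-length series (>= 2)")
    if pred.std() == 0 or truth.std() == 0:
        return np.nan  # undefined under zero variance; caller excludes
    return float(np.corrcoef(pred, truth)[0, 1])


def channel_metrics(pred: np.ndarray, truth: np.ndarray,
                    model: str = "", subject: str = "") -> pd.DataFrame:
    """Per-channel metrics over a batch of (n, 18, T) curves.

    nRMSE uses the per-trial truth range and is averaged over trials; r is
    the median over trials.  Channels whose metric is undefined (constant
    truth) come back as NaN.
    """
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth shape mismatch")
    rows = []
    for c in range(pred.shape[1]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            es = [nrmse(pred[i, c], truth[i, c]) for i in range(pred.shape[0])]
            rs = [pearson_r(pred[i, c], truth[i, c]) for i in range(pred.shape[0])]
        rows.append(
            {
                "model": model,
                "subject": subject,
                "channel": CHANNELS[c] if c < len(CHANNELS) else str(c),
                "nrmse": float(np.nanmean(es)) if not np.all(np.isnan(es)) else np.nan,
                "r": float(np.nanmedian(rs)) if not np.all(np.isnan(rs)) else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MetricTable:
    """Tidy per-(model, subject, channel) metric table with aggregation
    helpers."""

    df: pd.DataFrame

    def mean_nrmse(self) -> pd.Series:
        """Per-channel nRMSE, mean over folds."""
        return self.df.groupby("channel", sort=False)["nrmse"].mean()

    def median_r(self) -> pd.Series:
        """Per-channel correlation, median over folds."""
        return self.df.groupby("channel", sort=False)["r"].median()

    def overall_mean_r(self) -> float:
        return float(self.df["r"].mean())

    def plot_violin(self, metric: str = "r", ax=None):
        """Violin plot of a metric's per-fold distribution per channel."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(12, 4))
        channels = list(dict.fromkeys(self.df["channel"]))
        data = [self.df.loc[self.df.channel == ch, metric].dropna()
                for ch in channels]
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(channels) + 1), channels, rotation=90,
                      fontsize=7)
        ax.set_ylabel(metric)
        return ax

    def to_csv(self, path) -> None:
        tidy = self.df.copy()
        parts = tidy["channel"].str.rsplit("_", n=1)
        tidy["joint"] = parts.str[0]
        tidy["component"] = parts.str[1]
        tidy.melt(
            id_vars=["model", "subject", "joint", "component", "channel"],
            value_vars=["nrmse", "r"],
            var_name="metric",
            value_name="value",
        ).to_csv(path, index=False)


def _assemble(samples, layout, image_side, train_scaler=None):
    if layout == "flat":
        return assemble_flat(samples)
    if layout == "sequence":
        return assemble_sequence(samples)
    if layout == "image":
        return assemble_image(samples, side=image_side, scaler=train_scaler)
    raise ValueError(f"unknown layout {layout!r}")


def loso_run(
    bundle: StudyBundle,
    spec: NetSpec,
    layout: str | None = None,
    target: str = "angles",
    image_side: int = 32,
    seed: int = 0,
    verbose: bool = False,
) -> MetricTable:
    """Leave-one-subject-out evaluation of one network family.

    One fold per subject with measured-IMU trials.  The fold's training set
    is every sample whose motion subject differs from the held-out subject —
    all placement-augmented simulated trials plus the other subjects'
    measured trials; the test set is the held-out subject's measured trials.
    Scalers and (for images) the min–max encoder are fitted per fold on the
    training partition only.  Folds are independent; the fold seed derives
    from ``seed``.
    """
    layout = layout or FAMILY_LAYOUT[spec.family]
    samples = build_samples(bundle, target=target)
    fold_subjects = sorted({sid for (sid, _) in bundle.measured_imu})
    if len(fold_subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects with measured IMU")
    frames = []
    for k, held_out in enumerate(fold_subjects):
        test = [s for s in samples
                if s.index[0] == held_out and s.index[2] == "measured"]
        if not test:
            warnings.warn(f"subject {held_out} has no measured trials; skipped")
            continue
        train, _ = split_by_subject(samples, {held_out})
        fold_spec = dc_replace(spec, seed=spec.seed + 1000 * k + seed)
        train_t = _assemble(train, layout, image_side)
        test_t = _assemble(test, layout, image_side,
                           train_scaler=train_t.x_scaler)
        truth = np.stack([s.y for s in test])
        train_s = fit_scalers(train_t)
        test_s = apply_scalers(test_t, train_s)
        res = JointPredictionModel(train_s, train_s, fold_spec).fit()
        pred = res.predict(test_s)
        frames.append(channel_metrics(pred, truth, model=spec.family,
                                      subject=held_out))
        if verbose:
            print(f"fold {held_out}: mean r = {frames[-1]['r'].mean():.3f}")
    return MetricTable(pd.concat(frames, ignore_index=True))


def improvement_table(base: MetricTable, other: MetricTable) -> pd.Series:
    """Per-channel relative nRMSE difference, percent.

    ``100 · (nRMSE_base − nRMSE_other) / nRMSE_base`` on fold-mean nRMSE;
    positive values mean ``other`` improves on ``base``.
    """
    b = base.mean_nrmse()
    o = other.mean_nrmse()
    if set(b.index) != set(o.index):
        raise ValueError("metric tables cover different channels")
    return 100.0 * (b - o.reindex(b.index)) / b
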