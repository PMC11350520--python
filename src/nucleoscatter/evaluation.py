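"""Cross-validated evaluation: 60/20/20 splits under k-fold CV, MAPE,
per-true-value distribution summaries, and the end-to-end experiment driver
(including the SNR-controlled noise stress test).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cnn_regressor as cnn
from . import forward_scattering as fs
from . import nucleus_models as nm
from . import signal_processing as sp
from .errors import DataError, ParameterError
from .signal_processing import ProcessedSignal

__all__ = [
    "CVPlan",
    "EvaluationSummary",
    "make_cv_partitions",
    "mean_absolute_percent_error",
    "summarize_predictions",
    "ProcessedDataset",
    "generate_processed_dataset",
    "run_cv_regression",
    "run_full_experiment",
]

ROLE_TRAIN, ROLE_VAL, ROLE_TEST = "train", "val", "test"


@dataclass
class CVPlan:
    """Fold assignments and within-fold train/val/test roles."""

    n_samples: int
    n_folds: int
    seed: int
    fold_assignments: np.ndarray  # test-fold index per sample
    roles: list[np.ndarray]       # per fold: per-sample role strings

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        r = self.roles[fold]
        return (
            np.flatnonzero(r == ROLE_TRAIN),
            np.flatnonzero(r == ROLE_VAL),
            np.flatnonzero(r == ROLE_TEST),
        )


def make_cv_partitions(n_samples: int, n_folds: int = 5, seed: int = 0) -> CVPlan:
    """Shuffle samples and deal them into near-equal test folds (sizes differ
    by <= 1); within each fold the remaining samples split 75/25 into
    train/val, i.e. roughly 60/20/20 of the total."""
    if n_folds < 2:
        raise ParameterError("n_folds must be >= 2")
    if n_samples < n_folds:
        raise ParameterError("n_samples must be >= n_folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_samples)
    base, extra = divmod(n_samples, n_folds)
    fold_assignments = np.empty(n_samples, dtype=int)
    start = 0
    test_sets = []
    for fold in range(n_folds):
        size = base + (1 if fold < extra else 0)
        idx = order[start:start + size]
        fold_assignments[idx] = fold
        test_sets.append(idx)
        start += size
    roles: list[np.ndarray] = []
    for fold in range(n_folds):
        role = np.full(n_samples, ROLE_TRAIN, dtype=object)
        role[test_sets[fold]] = ROLE_TEST
        remainder = np.setdiff1d(np.arange(n_samples), test_sets[fold])
        remainder = rng.permutation(remainder)
        n_val = max(1, int(round(0.25 * len(remainder))))  # never an empty val set
        role[remainder[:n_val]] = ROLE_VAL
        roles.append(np.asarray(role))
    return CVPlan(n_samples=n_samples, n_folds=n_folds, seed=seed,
                  fold_assignments=fold_assignments, roles=roles)


def mean_absolute_percent_error(true_values: Sequence[float],
                                predictions: Sequence[float]) -> float:
    """``100 * mean(|true - pred| / true)``; requires strictly positive truths."""
    t = np.asarray(true_values, dtype=np.float64)
    p = np.asarray(predictions, dtype=np.float64)
    if t.shape != p.shape or t.ndim != 1 or t.size < 1:
        raise DataError("true values and predictions must be equal-length 1D")
    if np.any(t <= 0):
        raise ParameterError("MAPE requires all true values > 0")
    return float(100.0 * np.mean(np.abs(t - p) / t))


def _t_confidence_interval(values: np.ndarray, level: float = 0.95):
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return mean, mean
    sem = float(np.std(values, ddof=1) / np.sqrt(n))
    half = float(stats.t.ppf(0.5 + level / 2.0, n - 1) * sem)
    return mean - half, mean + half


def summarize_predictions(true_values: Sequence[float],
                          predictions: Sequence[float]) -> dict[float, dict]:
    """Box-plot statistics of the predictions grouped by distinct true value.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the most extreme points within 1.5*IQR of the box edges; the
    mean carries a t-based 95% confidence interval.
    """
    t = np.asarray(true_values, dtype=np.float64)
    p = np.asarray(predictions, dtype=np.float64)
    if t.shape != p.shape or t.size < 1:
        raise DataError("true values and predictions must be equal-length, non-empty")
    out: dict[float, dict] = {}
    for value in np.unique(t):
        group = p[t == value]
        q25, med, q75 = np.percentile(group, [25, 50, 75])
        iqr = q75 - q25
        lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
        inliers = group[(group >= lo_fence) & (group <= hi_fence)]
        outliers = group[(group < lo_fence) | (group > hi_fence)]
        ci_low, ci_high = _t_confidence_interval(group)
        out[float(value)] = dict(
            n=int(group.size),
            median=float(med),
            q25=float(q25),
            q75=float(q75),
            whisker_low=float(inliers.min()),
            whisker_high=float(inliers.max()),
            outliers=[float(v) for v in outliers],
            mean=float(group.mean()),
            ci_low=ci_low,
            ci_high=ci_high,
        )
    return out


# ---------------------------------------------------------------------------
# end-to-end experiment
# ---------------------------------------------------------------------------

@dataclass
class ProcessedDataset:
    """Stretched signals for a full spec list, ready for regression."""

    processed: np.ndarray          # (n, 181, 361) float32, values in [0, 255]
    meta: pd.DataFrame             # shape, corr_length_um, fluct_std, seed
    specs: list[nm.NucleusSpec]


@dataclass
class EvaluationSummary:
    """Pooled cross-validated predictions and derived statistics per target."""

    targets: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.targets, indent=2, sort_keys=True)


_LABEL_COLUMN = {
    cnn.TARGET_CORR_LENGTH: "corr_length_um",
    cnn.TARGET_FLUCT_STD: "fluct_std",
}


def generate_processed_dataset(config) -> ProcessedDataset:
    """Phantoms -> Born far fields -> contrast-stretched maps for every spec."""
    ds = config.dataset
    specs = nm.enumerate_dataset(
        shapes=list(ds.shapes),
        corr_lengths_um=ds.corr_lengths_um,
        fluct_stds=ds.fluct_stds,
        pairs=ds.pairs,
        replicates=ds.replicates,
        base_seed=ds.base_seed,
        radius_um=ds.radius_um,
        semiaxes_um=tuple(ds.semiaxes_um),
        n_mean=ds.n_mean,
        n_cyto=ds.n_cyto,
        voxel_um=ds.voxel_um,
        padding_um=ds.padding_um,
    )
    processed = np.empty((len(specs), fs.N_THETA, fs.N_PHI), dtype=np.float32)
    rows = []
    for i, spec in enumerate(specs):
        volume = nm.build_ri_volume(spec)
        signal = fs.born_far_field(volume, config.forward.wavelength_nm,
                                   config.forward.pad_factor)
        processed[i] = sp.log_contrast_stretch(signal).values
        rows.append(dict(sample=i, shape=spec.shape,
                         corr_length_um=spec.corr_length_um,
                         fluct_std=spec.fluct_std, seed=spec.seed))
    return ProcessedDataset(processed=processed, meta=pd.DataFrame(rows), specs=specs)


def _network_inputs(processed: np.ndarray, crop) -> np.ndarray:
    """Optionally crop the polar range, then scale to [0, 1]."""
    if crop is not None:
        tmin, tmax = crop
        processed = processed[:, tmin:tmax + 1, :]
    return (processed / np.float32(255.0)).astype(np.float32)


def run_cv_regression(
    dataset: ProcessedDataset,
    config,
    targets: Sequence[str] | None = None,
    permute_labels_seed: int | None = None,
) -> EvaluationSummary:
    """Train one network per (target, fold); pool test-fold predictions.

    ``permute_labels_seed`` activates the shuffled-label baseline: labels are
    randomly permuted across samples before the identical pipeline runs.
    When noise SNRs are configured, each fold's clean-trained model is also
    applied to noise-degraded test signals (no retraining).
    """
    targets = list(targets or config.targets)
    n = len(dataset.processed)
    plan = make_cv_partitions(n, config.cv.n_folds, config.cv.seed)
    noise_snrs = list(config.preprocess.noise_snr_db or [])

    summary = EvaluationSummary()
    for target in targets:
        crop = config.preprocess.crop_for(target)
        x = _network_inputs(dataset.processed, crop)
        input_shape = x.shape[1:]
        labels = dataset.meta[_LABEL_COLUMN[target]].to_numpy(dtype=np.float64)
        if permute_labels_seed is not None:
            perm = np.random.default_rng(
                nm.derive_seed(permute_labels_seed, "permute", target))
            labels = labels[perm.permutation(n)]
        pooled_true = np.empty(n)
        pooled_pred = np.empty(n)
        pooled_fold = np.empty(n, dtype=int)
        noisy_pred: dict[float, np.ndarray] = {s: np.empty(n) for s in noise_snrs}
        histories = []
        for fold in range(plan.n_folds):
            tr, va, te = plan.fold_indices(fold)
            reg_cfg = cnn.RegressorConfig(
                target=target,
                epochs=config.regressor.epochs_for(target),
                batch_size=config.regressor.batch_size,
                learning_rate=config.regressor.learning_rate,
                dropout_rate=config.regressor.dropout_rate,
                seed=nm.derive_seed(config.cv.seed, target, fold,
                                    permute_labels_seed),
                input_shape=input_shape,
            )
            model = cnn.build_architecture(reg_cfg)
            trained = cnn.train_regressor(model, (x[tr], labels[tr]),
                                          (x[va], labels[va]), reg_cfg)
            pooled_pred[te] = cnn.predict_parameters(trained, x[te])
            pooled_true[te] = labels[te]
            pooled_fold[te] = fold
            histories.append(dict(best_epoch=trained.best_epoch,
                                  best_val_loss=min(trained.history["val_loss"])))
            for snr in noise_snrs:
                noisy = np.empty((len(te), fs.N_THETA, fs.N_PHI), dtype=np.float32)
                for j, sample in enumerate(te):
                    ps = ProcessedSignal(values=dataset.processed[sample])
                    noise_seed = nm.derive_seed(config.cv.seed, "noise", snr,
                                                int(sample))
                    noisy[j] = sp.add_white_gaussian_noise(ps, snr, noise_seed).values
                noisy_pred[snr][te] = cnn.predict_parameters(
                    trained, _network_inputs(noisy, crop))

        rho = stats.spearmanr(pooled_true, pooled_pred).statistic
        entry = dict(
            true_values=pooled_true.tolist(),
            predictions=pooled_pred.tolist(),
            folds=pooled_fold.tolist(),
            mape=mean_absolute_percent_error(pooled_true, pooled_pred),
            spearman_rho=float(rho),
            groups=summarize_predictions(pooled_true, pooled_pred),
            fold_histories=histories,
        )
        if noise_snrs:
            entry["noise"] = {
                str(snr): dict(
                    mape=mean_absolute_percent_error(pooled_true, noisy_pred[snr]),
                    predictions=noisy_pred[snr].tolist(),
                )
                for snr in noise_snrs
            }
        summary.targets[target] = entry
    return summary


def _save_figures(summary: EvaluationSummary, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for target, entry in summary.targets.items():
        truths = np.asarray(entry["true_values"])
        preds = np.asarray(entry["predictions"])
        uniq = np.unique(truths)
        fig, ax = plt.subplots(figsize=(5, 4))
        data = [preds[truths == u] for u in uniq]
        width = 0.6 * (uniq.min() if len(uniq) == 1 else np.diff(uniq).min())
        ax.boxplot(data, positions=uniq, widths=width, manage_ticks=False)
        means = [d.mean() for d in data]
        cis = [_t_confidence_interval(d) for d in data]
        yerr = np.array([[m - lo for m, (lo, _) in zip(means, cis)],
                         [hi - m for m, (_, hi) in zip(means, cis)]])
        ax.errorbar(uniq, means, yerr=yerr, fmt="o", ms=4, capsize=3, lw=1)
        lims = [min(uniq.min(), preds.min()), max(uniq.max(), preds.max())]
        ax.plot(lims, lims, ":", color="gray", lw=1)
        ax.set_xlabel(f"true {target}")
        ax.set_ylabel(f"predicted {target}")
        ax.set_title(f"{target}: MAPE = {entry['mape']:.1f}%")
        fig.tight_layout()
        fig.savefig(out_dir / f"recovery_{target}.png", dpi=150)
        plt.close(fig)


def run_full_experiment(config, output_dir: str | Path) -> EvaluationSummary:
    """Generate -> scatter -> preprocess -> CV-train -> summarize; write artifacts.

    Writes ``manifest.csv``, ``predictions.csv``, ``summary.json`` and one
    recovery figure per target into ``output_dir``.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = generate_processed_dataset(config)
    dataset.meta.to_csv(out / "manifest.csv", index=False)
    summary = run_cv_regression(dataset, config)

    rows = []
    for target, entry in summary.targets.items():
        for i, (t, p, f) in enumerate(zip(entry["true_values"],
                                          entry["predictions"], entry["folds"])):
            rows.append(dict(sample=i, shape=dataset.meta.loc[i, "shape"],
                             target=target, fold=f, true=t, predicted=p))
    pd.DataFrame(rows).to_csv(out / "predictions.csv", index=False)

    payload = dict(config_hash=config.config_hash(), summary=summary.targets)
    (out / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    _save_figures(summary, out)
    return summary
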