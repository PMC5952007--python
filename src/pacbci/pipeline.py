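"""End-to-end orchestration of the flashing-image (6-class) pipeline.

``pac_feature_table`` turns an epoch set into a trials x (band-pair x
channel) PAC feature matrix plus per-channel alpha1 relative power;
``run_pipeline`` then selects features, gates attended trials on alpha1
power, trains a one-vs-rest linear SVM on the training sessions and
reports holdout accuracy and the Wolpaw information transfer rate.
"""

from __future__ import annotations

import json
import logging

import numpy as np

from . import __version__
from .core import EpochSet, PipelineConfig, ValidationError, CANONICAL_BANDS
from .cfc import comodulogram, relative_power
from .evaluation import CvScheme, accuracy, confusion_matrix, itr, make_folds
from .select_classify import (FeatureTable, knn_attend, mcfs_select,
                              svm_predict, svm_train)

log = logging.getLogger(__name__)

__all__ = ["pac_feature_table", "run_pipeline"]


def pac_feature_table(
    epochs: EpochSet,
    config: PipelineConfig | None = None,
    channels: list[str] | None = None,
) -> tuple[FeatureTable, np.ndarray]:
    """Compute PAC comodulogram features and alpha1 relative power per trial.

    Returns the feature table (one column per band pair per channel, named
    like ``delta-theta@PZ``) and a ``trials x channels`` alpha1 RSP matrix.
    """
    config = config or PipelineConfig()
    channels = channels or (list(config.channel_set) if config.channel_set
                            else list(epochs.channels))
    bands = tuple(config.bands)
    ch_idx = [epochs.channel_index(c) for c in channels]
    alpha_pos = next(i for i, b in enumerate(bands) if b.name == "alpha1")

    names, cols = [], []
    alpha_rsp = np.zeros((epochs.n_trials, len(channels)))
    feats = None
    for trial in range(epochs.n_trials):
        row = []
        for k, ci in enumerate(ch_idx):
            x = epochs.data[trial, ci]
            com = comodulogram(x, bands, epochs.fs, config.estimator)
            for (lf, hf), v in com.pairs():
                if trial == 0:
                    names.append(f"{lf.name}-{hf.name}@{channels[k]}")
                row.append(v)
            alpha_rsp[trial, k] = relative_power(x, bands, epochs.fs).rsp[alpha_pos]
        if feats is None:
            feats = np.empty((epochs.n_trials, len(row)))
        feats[trial] = row
    table = FeatureTable(feats, names, epochs.class_label, epochs.attend)
    log.info("feature table: %d trials x %d features (estimator=%s)",
             feats.shape[0], feats.shape[1], config.estimator)
    return table, alpha_rsp


def run_pipeline(config: PipelineConfig, epochs: EpochSet,
                 scheme: CvScheme | None = None,
                 n_select: int = 1, gate: bool = True) -> dict:
    """Run the full classification pipeline; returns a JSON-serialisable report.

    Deterministic given ``config.seed``: feature selection, gating, SVM and
    fold construction all derive their randomness from it.
    """
    if epochs.n_classes < 2:
        raise ValidationError("need at least 2 classes")
    scheme = scheme or CvScheme("session_holdout")
    n_classes = epochs.n_classes
    table, alpha_rsp = pac_feature_table(epochs, config)

    fold_reports = []
    accs = []
    for fold_no, (tr, te) in enumerate(make_folds(epochs, scheme)):
        sel, scores = mcfs_select(table.subset(rows=tr), n_clusters=n_classes,
                                  n_select=n_select)
        train_tab = table.subset(rows=tr, cols=sel)
        test_tab = table.subset(rows=te, cols=sel)

        if gate and epochs.attend.any() and not epochs.attend.all():
            pred_att = knn_attend(alpha_rsp[tr].mean(axis=1),
                                  epochs.attend[tr],
                                  alpha_rsp[te].mean(axis=1))
        else:
            pred_att = np.ones(len(te), bool)

        model = svm_train(train_tab)
        pred = svm_predict(model, test_tab)
        true = epochs.class_label[te]
        # gated accuracy: trials flagged non-attended count as abstentions
        # and are scored only among the attended predictions
        att_true = epochs.attend[te]
        scored = pred_att & att_true if gate else np.ones(len(te), bool)
        if not scored.any():
            scored = np.ones(len(te), bool)
        acc = accuracy(true[scored], pred[scored])
        accs.append(acc)
        fold_reports.append({
            "fold": fold_no,
            "n_train": int(len(tr)),
            "n_test": int(len(te)),
            "selected_features": [table.names[i] for i in sel],
            "selection_scores": [float(s) for s in scores],
            "accuracy": acc,
            "confusion": confusion_matrix(true[scored], pred[scored],
                                          n_classes).tolist(),
        })

    mean_acc = float(np.mean(accs))
    rate = itr(n_classes, mean_acc, config.selection_time)
    report = {
        "software": {"package": "pacbci", "version": __version__},
        "config": {
            "estimator": config.estimator,
            "bands": [[b.name, b.f_lo, b.f_hi] for b in config.bands],
            "window": config.window,
            "step": config.step,
            "selection_time": config.selection_time,
            "seed": config.seed,
        },
        "scheme": scheme.kind,
        "n_classes": n_classes,
        "accuracy": mean_acc,
        "bits_per_selection": rate.bits_per_selection,
        "itr_bits_per_min": rate.bits_per_min,
        "folds": fold_reports,
    }
    return report


def report_to_json(report: dict) -> str:
    """Canonical (byte-stable) JSON serialisation of a pipeline report."""
    return json.dumps(report, sort_keys=True, indent=2)


def run_symbolic_pipeline(
    epochs: EpochSet,
    lf=None,
    hf=None,
    pac_window: int = 25,
    pac_step: int = 4,
    method: str = "iplv",
    symbol_window: int = 25,
    symbol_step: int = 5,
    codebook_k: int = 32,
    max_test_windows: int = 64,
    gamma: float = 0.05,
    n_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Matrix-speller pipeline: LCMV denoising, sliding-window PAC
    trajectory, per-class neural-gas code waves, Wald-Wolfowitz similarity
    classification, stratified k-fold CV.

    Per fold, a rank-1 LCMV beamformer is fit on the training epochs (grand-
    average template, pooled shrunk covariance) and applied to every trial;
    each trial's dominant component yields a PAC trajectory whose sliding
    windows are quantised per class into ``codebook_k`` prototypes.  A test
    trial is assigned to the class whose prototypes its windows intermix
    with most (largest runs-test z over the Euclidean minimum spanning
    tree).  Test windows are decimated evenly to ``max_test_windows`` to
    keep the two samples comparable in size.
    """
    from sklearn.model_selection import StratifiedKFold

    from .encode import neural_gas_fit, sliding_windows, ww_classify
    from .spatial import estimate_covariance, lcmv_fit, lcmv_apply

    lf = lf or CANONICAL_BANDS[0]
    hf = hf or CANONICAL_BANDS[1]
    from .cfc import pac_timeseries

    if epochs.n_classes < 2:
        raise ValidationError("need at least 2 classes")
    classes = np.unique(epochs.class_label)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_reports, accs = [], []
    for fold_no, (tr, te) in enumerate(
            skf.split(np.zeros(epochs.n_trials), epochs.class_label)):
        train = epochs.subset_trials(tr)
        template = np.mean(train.data, axis=0)
        cov = estimate_covariance(train, gamma)
        model = lcmv_fit(template, cov, rank=1, gamma=gamma)

        def trajectory(i):
            trace = lcmv_apply(model, epochs.data[i])[0]
            return pac_timeseries(trace, lf, hf, epochs.fs,
                                  pac_window, pac_step, method).values

        prototypes = {}
        for c in classes:
            wins = np.vstack([
                sliding_windows(trajectory(i), symbol_window, symbol_step)
                for i in tr[epochs.class_label[tr] == c]])
            prototypes[int(c)] = neural_gas_fit(
                wins, k=codebook_k, seed=seed).prototypes

        preds = []
        for i in te:
            w = sliding_windows(trajectory(i), symbol_window, symbol_step)
            if len(w) > max_test_windows:
                pick = np.linspace(0, len(w) - 1, max_test_windows).astype(int)
                w = w[pick]
            pred, _ = ww_classify(w, prototypes)
            preds.append(pred)
        acc = accuracy(epochs.class_label[te], np.array(preds))
        accs.append(acc)
        fold_reports.append({"fold": fold_no, "n_train": int(len(tr)),
                             "n_test": int(len(te)), "accuracy": acc})
    return {
        "software": {"package": "pacbci", "version": __version__},
        "method": method,
        "lf_band": lf.name,
        "hf_band": hf.name,
        "n_classes": int(len(classes)),
        "accuracy": float(np.mean(accs)),
        "folds": fold_reports,
        "seed": seed,
    }
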