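"""Synthetic-data augmentation experiment for condition classifiers.

Can generated cells substitute for scarce real ones?  A logistic-regression
classifier predicts the culture condition from shape coefficients alone
(scalar biology and one-hot columns are excluded, and pose/position were
already removed by alignment upstream).  Schemes compared on one fixed,
held-out real test split:

    real100            all real training cells
    real50             a stratified half of them
    real50+synthXm     the same half plus m times as many VAE-generated
                       cells, the VAE trained only on that half

Performance is the area under the ROC curve; the ROC/AUC construction here
is self-contained (threshold sweep with tied-score grouping, trapezoidal
area) and is cross-checked against pair counting in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .generative import VAEConfig, generate, train_vae
from .harmonize import CellTable

__all__ = ["AugmentationPlan", "ROCResult", "roc_curve", "run_experiment"]


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class AugmentationPlan:
    synthetic_multipliers: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0)
    test_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")
        if any(m <= 0 for m in self.synthetic_multipliers):
            raise ValueError("synthetic multipliers must be positive")


def roc_curve(scores, labels) -> ROCResult:
    """ROC over all score thresholds; AUC by the trapezoidal rule.

    Equal scores are grouped into a single threshold so ties contribute
    diagonal segments (equivalently, the AUC equals the Mann-Whitney pair
    count with ties worth 1/2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # indices where the score changes: one operating point per distinct score
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[cut]
    fp = np.cumsum(1 - y)[cut]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = np.concatenate([[np.inf], s[cut]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def _coefficient_columns(table: CellTable) -> list[str]:
    # shape coefficients only: numeric block minus the scalar biology column
    return [c for c in table.numeric_columns if c != table.scalar_column]


def _fit_eval(X_train, y_train, X_test, y_test, seed: int) -> float:
    # C=inf: unregularized fit (regularization is an option, not the default)
    clf = LogisticRegression(C=np.inf, max_iter=2000, random_state=seed)
    clf.fit(X_train, y_train)
    return roc_curve(clf.decision_function(X_test), y_test).auc


def run_experiment(
    table: CellTable,
    plan: AugmentationPlan | None = None,
    vae_config: VAEConfig | None = None,
) -> pd.DataFrame:
    """Run every scheme and tabulate (scheme, auc, n_train_real, n_train_synth).

    The test split is real-only, stratified by condition, and identical for
    every scheme.  Synthetic cells are generated by a VAE trained exclusively
    on the 50% real training subset, so no scheme ever sees test cells,
    directly or through a generator.
    """
    plan = plan or AugmentationPlan()
    vae_config = vae_config or VAEConfig(seed=plan.seed)
    if len(set(table.conditions)) < 2:
        raise ValueError("training data must contain both conditions")

    coef_cols = _coefficient_columns(table)
    X = table.frame[coef_cols].to_numpy(dtype=float)
    y = table.onehot[:, -1].astype(int)  # second category is the positive class

    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=plan.test_fraction, stratify=y,
        random_state=plan.seed)
    X_test, y_test = X[test_idx], y[test_idx]

    rows = []
    rows.append({
        "scheme": "real100",
        "auc": _fit_eval(X[train_idx], y[train_idx], X_test, y_test,
                         plan.seed),
        "n_train_real": len(train_idx), "n_train_synth": 0,
    })

    half_idx, _ = train_test_split(
        train_idx, train_size=0.5, stratify=y[train_idx],
        random_state=plan.seed)
    X_half, y_half = X[half_idx], y[half_idx]
    rows.append({
        "scheme": "real50",
        "auc": _fit_eval(X_half, y_half, X_test, y_test, plan.seed),
        "n_train_real": len(half_idx), "n_train_synth": 0,
    })

    # one VAE on the 50% subset serves all multipliers
    sub = CellTable(
        frame=table.frame.iloc[half_idx],
        numeric_columns=table.numeric_columns,
        onehot_columns=table.onehot_columns,
        scalar_column=table.scalar_column,
    )
    model, _ = train_vae(sub, vae_config)
    max_n = int(np.ceil(max(plan.synthetic_multipliers) * len(half_idx)))
    synth = generate(model, max_n, seed=plan.seed + 1)
    X_synth_all = synth[coef_cols].to_numpy(dtype=float)
    y_synth_all = synth[table.onehot_columns].to_numpy()[:, -1].astype(int)

    for mult in plan.synthetic_multipliers:
        n_synth = int(round(mult * len(half_idx)))
        Xs = np.vstack([X_half, X_synth_all[:n_synth]])
        ys = np.concatenate([y_half, y_synth_all[:n_synth]])
        if len(set(ys)) < 2:
            raise ValueError("augmented training set lost a class")
        rows.append({
            "scheme": f"real50+synth{mult:g}x",
            "auc": _fit_eval(Xs, ys, X_test, y_test, plan.seed),
            "n_train_real": len(half_idx), "n_train_synth": n_synth,
        })
    return pd.DataFrame(rows)
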