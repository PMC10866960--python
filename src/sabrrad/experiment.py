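"""Bootstrapped random-forest evaluation engine.

The experiment draws B bootstrap training multisets of size n (sampling with
replacement from the full cohort), tests on the unique out-of-sample cases,
and aggregates per-iteration test AUCs, the pooled ROC, and sensitivity /
specificity at each iteration's out-of-bag (OOB) upper-left-corner operating
point. Optional training-set filters: an inter-feature correlation filter
(|Pearson r| > 0.80 between a feature pair removes the member less correlated
with the outcome) and a volume filter (features with a significant Pearson
correlation > 0.5 with ROI volume are removed).

Usage follows the model/results convention::

    model = BootstrapForestExperiment.from_dataframe(df, label_col="label")
    result = model.fit()
    print(result.summary())
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from .stats import aggregate_importance, upper_left_operating_point

__all__ = [
    "ExperimentConfig",
    "BootstrapForestExperiment",
    "ExperimentResult",
    "bootstrap_split",
    "inter_corr_filter",
    "volume_corr_filter",
    "train_rf",
    "oob_operating_point",
    "decimate_test",
    "DEFAULT_RF_GRID",
]

log = logging.getLogger(__name__)

# hyperparameter grid searched per iteration by OOB AUC
DEFAULT_RF_GRID = {
    "n_estimators": (100, 300),
    "min_samples_leaf": (1, 5),
    "max_features": ("sqrt",),
}


@dataclass
class ExperimentConfig:
    n_iterations: int = 500
    inter_corr_filter: bool = True
    inter_corr_threshold: float = 0.80
    volume_filter: bool = False
    volume_r_threshold: float = 0.5
    volume_alpha: float = 0.05
    rf_grid: dict = field(default_factory=lambda: dict(DEFAULT_RF_GRID))
    decimate_to_prevalence: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 2:
            raise ValueError(f"n_iterations must be >= 2, got {self.n_iterations}")
        for name in ("inter_corr_threshold", "volume_r_threshold", "volume_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.decimate_to_prevalence is not None and not 0.0 < self.decimate_to_prevalence < 1.0:
            raise ValueError("decimate_to_prevalence must be in (0, 1)")


def bootstrap_split(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One bootstrap resample: train multiset of size n, test = indices never drawn.

    Redraws (logged) in the vanishingly rare event that every index is drawn.
    """
    if n < 2:
        raise ValueError(f"bootstrap_split needs n >= 2, got {n}")
    while True:
        train = rng.integers(0, n, size=n)
        test = np.setdiff1d(np.arange(n), train)
        if test.size:
            return train, test
        log.warning("bootstrap_split: empty test set, redrawing")


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with constant inputs defined as r=0 (p=1), logged."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.info("constant input to Pearson correlation; r defined as 0")
        return 0.0, 1.0
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def inter_corr_filter(X: np.ndarray, y: np.ndarray, threshold: float = 0.80) -> np.ndarray:
    """Keep-mask after removing one member of every highly correlated pair.

    Pairs with |Pearson r| > threshold are processed in descending |r|
    (skipping already-removed features); the member with the smaller absolute
    point-biserial correlation to the outcome is removed; ties keep the lower
    column index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    if p < 2:
        raise ValueError("inter_corr_filter needs at least two features")
    sd = X.std(axis=0)
    const = sd == 0
    Z = np.where(const[None, :], 0.0, (X - X.mean(axis=0)) / np.where(const, 1.0, sd)[None, :])
    corr = Z.T @ Z / X.shape[0]
    corr[const, :] = 0.0
    corr[:, const] = 0.0
    np.fill_diagonal(corr, 0.0)
    label_r = np.array([_safe_pearson(X[:, j], y)[0] for j in range(p)])
    iu = np.triu_indices(p, k=1)
    order = np.argsort(-np.abs(corr[iu]), kind="stable")
    keep = np.ones(p, dtype=bool)
    for k in order:
        i, j = iu[0][k], iu[1][k]
        if abs(corr[i, j]) <= threshold:
            break
        if not (keep[i] and keep[j]):
            continue
        if abs(label_r[i]) > abs(label_r[j]):
            keep[j] = False
        elif abs(label_r[j]) > abs(label_r[i]):
            keep[i] = False
        else:
            keep[max(i, j)] = False
    return keep


def volume_corr_filter(
    X: np.ndarray, volumes: np.ndarray, r_threshold: float = 0.5, alpha: float = 0.05
) -> np.ndarray:
    """Keep-mask removing features with a significant |Pearson r| > r_threshold
    against ROI volume on the training set."""
    X = np.asarray(X, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    keep = np.ones(X.shape[1], dtype=bool)
    for j in range(X.shape[1]):
        r, p = _safe_pearson(X[:, j], volumes)
        if p < alpha and abs(r) > r_threshold:
            keep[j] = False
    return keep


def train_rf(X, y, grid: dict | None = None, random_state: int = 0):
    """Grid search by OOB AUC; returns (model, oob_probabilities, importances).

    Importances are the forest's impurity-based scores (non-negative, sum 1).
    """
    grid = grid or DEFAULT_RF_GRID
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    best = (-np.inf, None, None)
    combos = [
        (ne, ml, mf)
        for ne in grid["n_estimators"]
        for ml in grid["min_samples_leaf"]
        for mf in grid["max_features"]
    ]
    for ne, ml, mf in combos:
        rf = RandomForestClassifier(
            n_estimators=int(ne),
            min_samples_leaf=int(ml),
            max_features=mf,
            oob_score=True,
            bootstrap=True,
            random_state=random_state,
            n_jobs=1,
        )
        rf.fit(X, y)
        oob = rf.oob_decision_function_[:, 1]
        missing = ~np.isfinite(oob)
        if missing.any():
            log.info("train_rf: %d samples without OOB votes set to 0.5", missing.sum())
            oob = np.where(missing, 0.5, oob)
        score = roc_auc_score(y, oob)
        if score > best[0]:
            best = (score, rf, oob)
    _, rf, oob = best
    return rf, oob, rf.feature_importances_


def oob_operating_point(oob_probs, y) -> float:
    """Probability threshold at the upper-left corner of the OOB ROC.

    Degenerate probability sets fall back to 0.5 (logged).
    """
    y = np.asarray(y).astype(int)
    oob_probs = np.asarray(oob_probs, dtype=float)
    if len(np.unique(y)) < 2 or np.ptp(oob_probs) == 0:
        log.info("oob_operating_point: degenerate inputs, falling back to 0.5")
        return 0.5
    fpr, tpr, thr = roc_curve(y, oob_probs)
    t, _, _ = upper_left_operating_point(fpr, tpr, thr)
    return float(min(max(t, 0.0), 1.0))


def decimate_test(
    test_idx: np.ndarray, labels: np.ndarray, target_prevalence: float, rng: np.random.Generator
) -> np.ndarray:
    """Randomly drop positives until their fraction is closest to the target.

    At least one positive is always kept; if the current prevalence is already
    at or below the target the set is unchanged.
    """
    test_idx = np.asarray(test_idx)
    lab = np.asarray(labels)[test_idx].astype(int)
    pos = test_idx[lab == 1]
    neg = test_idx[lab == 0]
    if neg.size == 0:
        raise ValueError("decimation requires at least one negative in the test set")
    if pos.size == 0:
        log.info("decimate_test: no positives, test set unchanged")
        return test_idx
    if pos.size / test_idx.size <= target_prevalence:
        return test_idx
    ks = np.arange(1, pos.size + 1)
    frac = ks / (ks + neg.size)
    k = int(ks[np.argmin(np.abs(frac - target_prevalence))])
    kept = rng.choice(pos, size=k, replace=False)
    return np.sort(np.concatenate([kept, neg]))


@dataclass
class ExperimentResult:
    """Aggregated results of a bootstrap experiment (the `Results` object)."""

    config: ExperimentConfig
    feature_names: list[str]
    n_cases: int
    n_completed: int
    auc_mean: float
    auc_ci: tuple[float, float]
    sensitivity_mean: float
    sensitivity_ci: tuple[float, float]
    specificity_mean: float
    specificity_ci: tuple[float, float]
    per_iteration_auc: np.ndarray
    per_iteration_sensitivity: np.ndarray
    per_iteration_specificity: np.ndarray
    importances: np.ndarray  # (B, p) raw impurity importances, 0 where filtered
    kept_masks: np.ndarray  # (B, p) bool
    importance_scores: np.ndarray  # (p,) double-normalized
    top_feature_mask: np.ndarray  # importance_scores > 0.80
    pooled_roc: tuple[np.ndarray, np.ndarray]
    pooled_auc: float
    oob_thresholds: np.ndarray
    train_indices: np.ndarray  # (B, n) bootstrap multisets
    test_indices: list  # list of arrays (after any decimation)
    test_probabilities: list  # list of arrays

    def top_features(self) -> list[tuple[str, float]]:
        order = np.argsort(-self.importance_scores)
        return [
            (self.feature_names[k], float(self.importance_scores[k]))
            for k in order
            if self.top_feature_mask[k]
        ]

    def summary(self) -> str:
        lines = [
            "Bootstrap random-forest experiment",
            "=" * 50,
            f"cases: {self.n_cases}   iterations: {self.n_completed}/{self.config.n_iterations}",
            f"inter-corr filter: {self.config.inter_corr_filter}   "
            f"volume filter: {self.config.volume_filter}",
            f"AUC           {self.auc_mean:.2f} [{self.auc_ci[0]:.2f}, {self.auc_ci[1]:.2f}]",
            f"Sensitivity   {100 * self.sensitivity_mean:.0f}% "
            f"[{100 * self.sensitivity_ci[0]:.0f}%, {100 * self.sensitivity_ci[1]:.0f}%]",
            f"Specificity   {100 * self.specificity_mean:.0f}% "
            f"[{100 * self.specificity_ci[0]:.0f}%, {100 * self.specificity_ci[1]:.0f}%]",
        ]
        top = self.top_features()
        if top:
            lines.append("top features (importance > 0.80):")
            for name, score in top:
                lines.append(f"  {score:5.2f}  {name}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "n_cases": self.n_cases,
            "n_completed": self.n_completed,
            "auc_mean": self.auc_mean,
            "auc_ci": list(self.auc_ci),
            "sensitivity_mean": self.sensitivity_mean,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity_mean": self.specificity_mean,
            "specificity_ci": list(self.specificity_ci),
            "pooled_auc": self.pooled_auc,
            "top_features": self.top_features(),
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
                if k != "rf_grid"
            },
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(payload, indent=2))

    def plot_roc(self, ax=None):
        """Pooled ROC curve; requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fpr, tpr = self.pooled_roc
        ax.plot(fpr, tpr, label=f"pooled ROC (AUC {self.pooled_auc:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax


def _normal_ci(values: np.ndarray) -> tuple[float, float, float]:
    m = float(np.mean(values))
    half = 1.96 * float(np.std(values, ddof=1)) / np.sqrt(len(values)) if len(values) > 1 else 0.0
    return m, m - half, m + half


class BootstrapForestExperiment:
    """Model object: a feature table with outcomes, ready to run the experiment.

    Parameters
    ----------
    features : DataFrame or ndarray, shape (n_cases, n_features)
    labels : binary array (1 = recurrence)
    volumes : per-case ROI volume (mm^3), required when the volume filter is on
    config : :class:`ExperimentConfig`
    """

    def __init__(self, features, labels, volumes=None, config: ExperimentConfig | None = None):
        if isinstance(features, pd.DataFrame):
            self.feature_names = list(features.columns)
            self.X = features.to_numpy(dtype=float)
        else:
            self.X = np.asarray(features, dtype=float)
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        self.y = np.asarray(labels).astype(int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("features and labels disagree on the number of cases")
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        self.volumes = None if volumes is None else np.asarray(volumes, dtype=float)
        self.config = config or ExperimentConfig()
        if self.config.volume_filter and self.volumes is None:
            raise ValueError("volume filter requested but no volumes provided")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        volume_col: str | None = "roi_volume_mm3",
        config: ExperimentConfig | None = None,
        positive_label="recurrence",
    ) -> "BootstrapForestExperiment":
        drop = [label_col]
        volumes = None
        if volume_col is not None and volume_col in df.columns:
            volumes = df[volume_col].to_numpy(dtype=float)
            drop.append(volume_col)
        labels = (df[label_col] == positive_label).astype(int).to_numpy()
        return cls(df.drop(columns=drop), labels, volumes, config)

    def fit(self, seed: int | None = None) -> ExperimentResult:
        """Run the full bootstrap experiment and aggregate the results.

        Iteration seeds derive only from the experiment seed, so two model
        variants run with the same seed share their bootstrap splits exactly
        (paired comparisons across filter settings).
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        n, p = self.X.shape
        B = cfg.n_iterations
        split_seeds = np.random.SeedSequence(seed).spawn(B)

        aucs, senss, specs, thrs = [], [], [], []
        imps = np.zeros((B, p))
        kept_all = np.ones((B, p), dtype=bool)
        train_all = np.zeros((B, n), dtype=np.int64)
        test_idx_all, test_prob_all, test_lab_all = [], [], []
        completed = np.zeros(B, dtype=bool)

        for b in range(B):
            rng = np.random.default_rng(split_seeds[b])
            rf_seed = int(rng.integers(0, 2**31 - 1))
            train, test = bootstrap_split(n, rng)
            train_all[b] = train
            assert np.intersect1d(np.unique(train), test).size == 0, "train/test leak"
            y_tr = self.y[train]
            if len(np.unique(y_tr)) < 2:
                log.warning("iteration %d skipped: single-class training set", b)
                continue
            keep = np.ones(p, dtype=bool)
            if cfg.inter_corr_filter:
                keep &= inter_corr_filter(self.X[train], y_tr, cfg.inter_corr_threshold)
            if cfg.volume_filter:
                keep &= volume_corr_filter(
                    self.X[train], self.volumes[train], cfg.volume_r_threshold, cfg.volume_alpha
                )
            if not keep.any():
                log.warning("iteration %d skipped: filters removed every feature", b)
                continue
            kept_all[b] = keep

            rf, oob, imp = train_rf(self.X[train][:, keep], y_tr, cfg.rf_grid, rf_seed)
            imps[b, keep] = imp
            thr = oob_operating_point(oob, y_tr)

            if cfg.decimate_to_prevalence is not None:
                test = decimate_test(test, self.y, cfg.decimate_to_prevalence, rng)
            y_te = self.y[test]
            probs = rf.predict_proba(self.X[test][:, keep])[:, 1]
            if len(np.unique(y_te)) < 2:
                log.warning("iteration %d skipped: single-class test set", b)
                continue
            aucs.append(roc_auc_score(y_te, probs))
            pred = probs >= thr
            senss.append(float(pred[y_te == 1].mean()))
            specs.append(float((~pred[y_te == 0]).mean()))
            thrs.append(thr)
            test_idx_all.append(test)
            test_prob_all.append(probs)
            test_lab_all.append(y_te)
            completed[b] = True

        if completed.sum() < 2:
            raise RuntimeError("fewer than two bootstrap iterations completed")

        aucs = np.asarray(aucs)
        senss = np.asarray(senss)
        specs = np.asarray(specs)
        def clip01(lo, hi):
            return max(0.0, lo), min(1.0, hi)

        auc_m, auc_lo, auc_hi = _normal_ci(aucs)
        se_m, se_lo, se_hi = _normal_ci(senss)
        sp_m, sp_lo, sp_hi = _normal_ci(specs)
        (auc_lo, auc_hi), (se_lo, se_hi), (sp_lo, sp_hi) = (
            clip01(auc_lo, auc_hi),
            clip01(se_lo, se_hi),
            clip01(sp_lo, sp_hi),
        )

        pooled_y = np.concatenate(test_lab_all)
        pooled_p = np.concatenate(test_prob_all)
        fpr, tpr, _ = roc_curve(pooled_y, pooled_p)
        pooled_auc = float(roc_auc_score(pooled_y, pooled_p))

        scores, top = aggregate_importance(
            imps[completed], kept_all[completed], threshold=0.80
        )

        return ExperimentResult(
            config=cfg,
            feature_names=self.feature_names,
            n_cases=n,
            n_completed=int(completed.sum()),
            auc_mean=auc_m,
            auc_ci=(auc_lo, auc_hi),
            sensitivity_mean=se_m,
            sensitivity_ci=(se_lo, se_hi),
            specificity_mean=sp_m,
            specificity_ci=(sp_lo, sp_hi),
            per_iteration_auc=aucs,
            per_iteration_sensitivity=senss,
            per_iteration_specificity=specs,
            importances=imps[completed],
            kept_masks=kept_all[completed],
            importance_scores=scores,
            top_feature_mask=top,
            pooled_roc=(fpr, tpr),
            pooled_auc=pooled_auc,
            oob_thresholds=np.asarray(thrs),
            train_indices=train_all[completed],
            test_indices=test_idx_all,
            test_probabilities=test_prob_all,
        )
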