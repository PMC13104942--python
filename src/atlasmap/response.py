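"""Sample-level compositional features and response-prediction evaluation.

Cell annotations are aggregated to per-sample cell-state proportion vectors
(cohort labels, atlas labels including NA, or their granular intersection).
Because proportions sum to one, the design is exactly collinear; the logistic
model drops rank-deficient columns deterministically before unpenalized
maximum-likelihood fitting. Discrimination of responders (outcome 1) versus
non-responders (outcome 0) is evaluated by ROC AUC under pair-based
cross-validation (every responder/non-responder pair held out once), repeated
stratified k-fold with feature subsampling, and a per-principal-component
information-gain decomposition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from .consensus import NA_LABEL, CellAnnotation

log = logging.getLogger(__name__)


@dataclass
class SampleFeatureTable:
    """Per-sample compositional state proportions plus the binary outcome."""

    sample_ids: list[str]
    feature_names: list[str]
    proportions: np.ndarray
    outcome: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=int)
        n, f = self.proportions.shape
        if n != len(self.sample_ids) or f != len(self.feature_names):
            raise ValueError("proportions shape does not match ids/feature names")
        if self.outcome.shape[0] != n:
            raise ValueError("outcome length mismatch")
        if np.any(self.proportions < 0):
            raise ValueError("negative proportions")
        if n and not np.allclose(self.proportions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("sample proportions must sum to 1 within 1e-9")
        if not set(np.unique(self.outcome)) <= {0, 1}:
            raise ValueError("outcome must be coded Responder=1, Non-Responder=0")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.proportions, index=self.sample_ids, columns=self.feature_names)
        df.insert(0, "outcome", self.outcome)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleFeatureTable":
        if "outcome" not in df.columns:
            raise ValueError("feature frame lacks an 'outcome' column")
        feats = [c for c in df.columns if c != "outcome"]
        return cls(
            [str(i) for i in df.index],
            feats,
            df[feats].to_numpy(dtype=float),
            df["outcome"].to_numpy(dtype=int),
        )


def _annotation_frame(anns) -> pd.DataFrame:
    if isinstance(anns, pd.DataFrame):
        df = anns[["cell_id", "assigned_label"]].copy()
        df["assigned_label"] = df["assigned_label"].fillna(NA_LABEL)
        return df
    return pd.DataFrame(
        {
            "cell_id": [a.cell_id for a in anns],
            "assigned_label": [
                a.assigned_label if a.assigned_label is not None else NA_LABEL for a in anns
            ],
        }
    )


def aggregate_features(
    anns: Sequence[CellAnnotation] | pd.DataFrame,
    cells: pd.DataFrame,
    samples: pd.DataFrame,
    scheme: str = "atlas",
) -> SampleFeatureTable:
    """Build per-sample state-proportion features under a labelling scheme.

    ``cohort`` uses the original cohort cluster labels, ``atlas`` the
    transferred labels (NA included as its own category), ``granular`` the
    observed (cohort, atlas) intersections named ``cohort|atlas``. Feature
    values are cell counts divided by the sample's total mapped cells;
    unknown-response samples are dropped before modelling.
    """
    if scheme not in ("cohort", "atlas", "granular"):
        raise ValueError(f"unknown scheme {scheme!r}")
    ann_df = _annotation_frame(anns)
    df = ann_df.merge(cells[["cell_id", "sample_id", "cohort_label"]], on="cell_id", how="left")
    if df["sample_id"].isna().any():
        missing = df.loc[df["sample_id"].isna(), "cell_id"].head().tolist()
        raise ValueError(f"cells without sample metadata, e.g. {missing}")
    if scheme == "cohort":
        df["feature"] = df["cohort_label"]
    elif scheme == "atlas":
        df["feature"] = df["assigned_label"]
    else:
        df["feature"] = df["cohort_label"] + "|" + df["assigned_label"]

    resp = dict(zip(samples["sample_id"], samples["response"]))
    keep_samples = [s for s in samples["sample_id"] if resp[s] in ("R", "NR")]
    n_unknown = samples.shape[0] - len(keep_samples)
    if n_unknown:
        log.info("dropping %d sample(s) with unknown response", n_unknown)
    counts = pd.crosstab(df["sample_id"], df["feature"])
    empty = [s for s in keep_samples if s not in counts.index]
    if empty:
        log.warning("sample(s) with 0 mapped cells dropped: %s", empty)
    keep_samples = [s for s in keep_samples if s in counts.index]
    if not keep_samples:
        raise ValueError("no R/NR samples with mapped cells")
    counts = counts.loc[keep_samples]
    counts = counts.loc[:, sorted(counts.columns)]
    props = counts.to_numpy(dtype=float)
    props /= props.sum(axis=1, keepdims=True)
    outcome = np.asarray([1 if resp[s] == "R" else 0 for s in keep_samples])
    return SampleFeatureTable(list(counts.index), [str(c) for c in counts.columns], props, outcome)


@dataclass
class FitReport:
    """Outcome of one compositional logistic fit."""

    kept_features: list[str]
    dropped_features: list[str]
    coefficients: dict[str, float]
    fitted_probabilities: np.ndarray
    converged: bool


class CompositionalLogisticRegression(BaseEstimator):
    """Unpenalized logistic regression with deterministic collinear dropping.

    The design (intercept first, then features left to right) is reduced to a
    full-rank basis by greedy Gram-Schmidt rank detection (tolerance
    ``collinear_tol``), preferring earlier columns — on a full compositional
    design this necessarily drops at least one proportion column. Fitting is
    iteratively reweighted least squares capped at ``max_iter`` iterations; on
    complete separation the cap is reached and ``converged_`` is False, but
    fitted probabilities are still produced.
    """

    def __init__(self, collinear_tol: float = 1e-10, max_iter: int = 100, tol: float = 1e-8):
        self.collinear_tol = collinear_tol
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if len(np.unique(y)) < 2:
            raise ValueError("need at least one sample of each outcome")
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(p)]
        design = np.column_stack([np.ones(n), X])

        kept = _greedy_full_rank(design, self.collinear_tol)
        self.kept_idx_ = [j - 1 for j in kept if j > 0]  # feature indices, intercept removed
        self.kept_features_ = [feature_names[j] for j in self.kept_idx_]
        self.dropped_features_ = [
            feature_names[j] for j in range(p) if j not in set(self.kept_idx_)
        ]

        Xk = design[:, kept]
        beta = np.zeros(Xk.shape[1])
        converged = False
        for _ in range(self.max_iter):
            eta = np.clip(Xk @ beta, -30.0, 30.0)
            mu = expit(eta)
            w = np.maximum(mu * (1.0 - mu), 1e-10)
            z = eta + (y - mu) / w
            sw = np.sqrt(w)
            beta_new, *_ = np.linalg.lstsq(Xk * sw[:, None], z * sw, rcond=None)
            if np.max(np.abs(beta_new - beta)) < self.tol:
                beta = beta_new
                converged = True
                break
            beta = beta_new
        self.converged_ = converged
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.fitted_prob_ = expit(np.clip(Xk @ beta, -30.0, 30.0))
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X[:, self.kept_idx_] @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        p1 = expit(np.clip(self.decision_function(X), -30.0, 30.0))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def _greedy_full_rank(design: np.ndarray, tol: float) -> list[int]:
    """Left-to-right greedy selection of a full-rank column subset."""
    kept: list[int] = []
    basis: list[np.ndarray] = []
    for j in range(design.shape[1]):
        c = design[:, j].astype(float)
        r = c.copy()
        for q in basis:
            r -= (q @ r) * q
        norm = np.linalg.norm(r)
        if norm > tol * max(1.0, np.linalg.norm(c)):
            kept.append(j)
            basis.append(r / norm)
    return kept


def fit_logistic(ft: SampleFeatureTable) -> FitReport:
    """Fit the compositional logistic model and report kept/dropped features."""
    model = CompositionalLogisticRegression().fit(
        ft.proportions, ft.outcome, feature_names=ft.feature_names
    )
    coefs = {"intercept": model.intercept_}
    coefs.update(dict(zip(model.kept_features_, map(float, model.coef_))))
    return FitReport(
        kept_features=model.kept_features_,
        dropped_features=model.dropped_features_,
        coefficients=coefs,
        fitted_probabilities=model.fitted_prob_,
        converged=model.converged_,
    )


def roc_auc(scores, outcome) -> float:
    """Rank-based ROC AUC: (concordant + 0.5 * tied pairs) / (n1 * n0)."""
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    n1 = int((outcome == 1).sum())
    n0 = int((outcome == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(scores)
    return float((ranks[outcome == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class CVResult:
    """Cross-validation outcome: fold definitions and per-fold AUCs."""

    scheme: str
    fold_assignments: list
    per_fold_auc: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.per_fold_auc = np.asarray(self.per_fold_auc, dtype=float)

    @property
    def mean_auc(self) -> float:
        return float(self.per_fold_auc.mean())


def pair_cv(ft: SampleFeatureTable) -> CVResult:
    """Leave-one-pair-out CV over all responder / non-responder pairs.

    Each fold holds out one (R, NR) sample pair, fits on the rest and scores
    the pair: fold AUC is 1 if the responder's predicted probability exceeds
    the non-responder's, 0.5 on a tie and 0 otherwise. Deterministic given the
    table.
    """
    r_idx = np.flatnonzero(ft.outcome == 1)
    n_idx = np.flatnonzero(ft.outcome == 0)
    if r_idx.size < 2 or n_idx.size < 2:
        raise ValueError("pair CV needs at least 2 responders and 2 non-responders")
    folds, aucs = [], []
    for i in r_idx:
        for j in n_idx:
            train = np.setdiff1d(np.arange(ft.n_samples), [i, j])
            model = CompositionalLogisticRegression().fit(
                ft.proportions[train], ft.outcome[train]
            )
            p = model.predict_proba(ft.proportions[[i, j]])[:, 1]
            folds.append((ft.sample_ids[i], ft.sample_ids[j]))
            aucs.append(1.0 if p[0] > p[1] else 0.5 if p[0] == p[1] else 0.0)
    return CVResult("pair", folds, np.asarray(aucs))


def kfold_cv(ft: SampleFeatureTable, folds: int = 5, seed: int = 0,
             feature_idx: np.ndarray | None = None) -> CVResult:
    """Stratified k-fold CV; per-fold held-out AUCs are averaged, not pooled.

    The fold count is reduced to the smaller outcome-class count when
    necessary (with a warning) so every test fold contains both classes.
    """
    X = ft.proportions if feature_idx is None else ft.proportions[:, feature_idx]
    y = ft.outcome
    n_min = int(min((y == 1).sum(), (y == 0).sum()))
    n_splits = min(folds, n_min)
    if n_splits < folds:
        log.warning("reducing folds from %d to %d (class counts)", folds, n_splits)
    if n_splits < 2:
        raise ValueError("need at least 2 samples per class for k-fold CV")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    assignments, aucs = [], []
    for train, test in skf.split(X, y):
        model = CompositionalLogisticRegression().fit(X[train], y[train])
        p = model.predict_proba(X[test])[:, 1]
        assignments.append([ft.sample_ids[t] for t in test])
        aucs.append(roc_auc(p, y[test]))
    return CVResult("kfold", assignments, np.asarray(aucs), seed=seed)


@dataclass
class SubsampleResult:
    """Feature-subsampling stability grid: (proportion x iteration) mean AUCs."""

    grid: pd.DataFrame
    mean_by_proportion: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.mean_by_proportion = self.grid.mean(axis=1)


def subsample_stability(
    ft: SampleFeatureTable,
    proportions: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
    iters: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> SubsampleResult:
    """Model stability across feature-inclusion proportions.

    For each (proportion, iteration): sample ceil(p * F) features without
    replacement, run stratified k-fold CV and record the mean held-out AUC.
    Bit-identical across runs for a fixed seed.
    """
    if len(ft.feature_names) < 2:
        raise ValueError("need at least 2 features")
    rng = np.random.default_rng(seed)
    n_feat = len(ft.feature_names)
    grid = np.empty((len(proportions), iters))
    for pi, p in enumerate(proportions):
        n_take = min(n_feat, math.ceil(p * n_feat))
        for it in range(iters):
            feat_idx = np.sort(rng.choice(n_feat, size=n_take, replace=False))
            fold_seed = int(rng.integers(0, 2**31 - 1))
            grid[pi, it] = kfold_cv(ft, folds=folds, seed=fold_seed,
                                    feature_idx=feat_idx).mean_auc
    df = pd.DataFrame(
        grid,
        index=pd.Index([float(p) for p in proportions], name="proportion"),
        columns=pd.Index(range(1, iters + 1), name="iteration"),
    )
    return SubsampleResult(df)


def _logistic_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def pc_information(ft: SampleFeatureTable) -> pd.DataFrame:
    """Per-principal-component predictive information gain.

    Features are centered and decomposed by SVD; for each of the first
    min(samples - 1, features) components a univariate logistic model of the
    outcome on the component score is fitted, and the information gain is
    (null deviance - model deviance) / 2, i.e. the log-likelihood improvement
    in nats. Explained-variance fractions are reported alongside.
    """
    if ft.n_samples < 3:
        raise ValueError("need at least 3 samples")
    X = ft.proportions - ft.proportions.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    n_comp = min(ft.n_samples - 1, len(ft.feature_names))
    scores = u[:, :n_comp] * s[:n_comp]
    total_var = float((s**2).sum())
    y = ft.outcome.astype(float)

    p_bar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    null_ll = _logistic_loglik(np.full(y.size, np.log(p_bar / (1 - p_bar))), y)

    rows = []
    for j in range(n_comp):
        model = CompositionalLogisticRegression().fit(scores[:, [j]], ft.outcome)
        ll = _logistic_loglik(np.clip(model.decision_function(scores[:, [j]]), -30, 30), y)
        rows.append(
            {
                "component": j + 1,
                "explained_var": float(s[j] ** 2 / total_var) if total_var > 0 else 0.0,
                "info_gain": ll - null_ll,
            }
        )
    return pd.DataFrame(rows)
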