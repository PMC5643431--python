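"""Surrogate gene-signature derivation and elastic-net risk models.

From the selected vascular features (VFs) the signature is built in three
steps: (1) every gene is ranked by Pearson correlation of its
``log2(RPKM + 1)`` expression with each VF across shared cases; (2) the
top fraction (default 0.05%) of positively and negatively correlated genes
per VF form the candidate pool; (3) candidates are filtered by the
information-gain ratio of their MDL-discretized expression with respect to
the binary risk-group assignment — only genes whose split passes the
Fayyad-Irani MDL acceptance criterion with positive gain ratio survive.

Two binomial elastic-net models over the final genes are supported: one
trained on the VF-derived risk groups and one on 24-month disease-free
status ground truth (cases censored before 24 months without an event are
excluded).  The penalty strength is chosen by cross-validated deviance
with the one-standard-error rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from . import prognosis

__all__ = [
    "GeneSelectionResult",
    "RiskModel",
    "correlate_genes",
    "select_candidates",
    "mdl_split",
    "information_gain_filter",
    "ground_truth_24mo_labels",
    "train_risk_model",
    "predict_risk",
    "evaluate_risk_model",
]


def _log_transform(expr: pd.DataFrame) -> pd.DataFrame:
    return np.log2(expr + 1.0)


def correlate_genes(
    expr: pd.DataFrame,
    vf_table: pd.DataFrame,
    vf_names: list[str],
    log_transform: bool = True,
) -> dict[str, pd.Series]:
    """Pearson correlation of every gene with each vascular feature.

    ``expr`` is genes x cases; ``vf_table`` cases x features.  Expression
    is ``log2(x + 1)``-transformed first (RPKM-like input).  Only cases
    shared by both tables are used (>= 3 required); constant genes get
    r = 0.  Returns {vf_name: Series of r indexed by gene}.
    """
    shared = expr.columns.intersection(vf_table.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared cases between expression and VFs")
    x = expr[shared].to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    xc = x - x.mean(axis=1, keepdims=True)
    xsd = xc.std(axis=1)
    out: dict[str, pd.Series] = {}
    for vf in vf_names:
        v = vf_table.loc[shared, vf].to_numpy(dtype=float)
        vc = v - v.mean()
        vsd = vc.std()
        if vsd == 0:
            r = np.zeros(len(expr))
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (xc @ vc) / (len(shared) * xsd * vsd)
            r = np.where(xsd == 0, 0.0, r)
        out[vf] = pd.Series(r, index=expr.index, name=vf)
    return out


def select_candidates(
    rankings: dict[str, pd.Series], fraction: float = 0.0005
) -> list[str]:
    """Union of the top ``fraction`` positively and negatively correlated
    genes per vascular feature.

    The slice size per direction is ``ceil(fraction * n_genes)``; boundary
    ties are broken by gene-id lexicographic order.  Returns a sorted gene
    list.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    chosen: set[str] = set()
    for vf, r in rankings.items():
        n_slice = int(np.ceil(fraction * len(r)))
        if n_slice == 0:
            warnings.warn(f"empty candidate slice for {vf!r}", stacklevel=2)
            continue
        # sort by (r, gene id) for a deterministic boundary
        srt = r.sort_index().sort_values(kind="stable")
        chosen.update(srt.index[:n_slice])  # most negative
        chosen.update(srt.index[-n_slice:])  # most positive
    return sorted(chosen)


# ---------------------------------------------------------------------------
# MDL discretization and information gain


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mdl_split(values: np.ndarray, labels: np.ndarray) -> tuple[float, float] | None:
    """Best binary split of ``values`` against ``labels`` under the
    Fayyad-Irani MDL acceptance criterion.

    Returns ``(threshold, gain_ratio)`` for the accepted cut maximizing
    information gain, or None when no cut passes the criterion.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n = len(values)
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = labels[order]
    h_s = _entropy(y)
    k = len(np.unique(y))
    best = None
    distinct = np.nonzero(np.diff(v) > 0)[0]
    for i in distinct:
        thr = (v[i] + v[i + 1]) / 2.0
        left, right = y[: i + 1], y[i + 1 :]
        n1, n2 = len(left), len(right)
        h1, h2 = _entropy(left), _entropy(right)
        gain = h_s - (n1 / n) * h1 - (n2 / n) * h2
        if best is None or gain > best[1]:
            best = (thr, gain, h1, h2, n1, n2, left, right)
    if best is None:
        return None
    thr, gain, h1, h2, n1, n2, left, right = best
    k1 = len(np.unique(left))
    k2 = len(np.unique(right))
    delta = np.log2(3.0**k - 2.0) - (k * h_s - k1 * h1 - k2 * h2)
    if gain <= (np.log2(n - 1) + delta) / n:
        return None
    p1, p2 = n1 / n, n2 / n
    split_info = -(p1 * np.log2(p1) + p2 * np.log2(p2))
    if split_info <= 0:
        return None
    return thr, float(gain / split_info)


@dataclass
class GeneSelectionResult:
    per_vf_rankings: dict[str, pd.Series]
    candidates: list[str]
    gain: dict[str, float]
    final: list[str]
    thresholds: dict[str, float] = field(default_factory=dict)


def information_gain_filter(
    expr: pd.DataFrame,
    candidates: list[str],
    risk_labels: pd.Series,
    binning: str = "mdl",
    rankings: dict[str, pd.Series] | None = None,
) -> GeneSelectionResult:
    """Filter candidate genes by information-gain ratio against risk labels.

    With ``binning='mdl'`` each candidate's ``log2(x + 1)`` expression is
    discretized by the best MDL-accepted binary cut; candidates with no
    accepted cut are rejected (gain 0).  ``binning='median'`` always splits
    at the median (fallback criterion).  The final set holds the genes
    with positive gain ratio.
    """
    y = risk_labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("risk labels must contain both classes")
    shared = expr.columns.intersection(risk_labels.index)
    y = risk_labels.loc[shared].to_numpy()
    gains: dict[str, float] = {}
    thresholds: dict[str, float] = {}
    for gene in candidates:
        if gene not in expr.index:
            raise KeyError(f"candidate gene {gene!r} not in expression matrix")
        v = np.log2(expr.loc[gene, shared].to_numpy(dtype=float) + 1.0)
        if binning == "mdl":
            res = mdl_split(v, y)
            if res is None:
                gains[gene] = 0.0
                continue
            thr, ratio = res
        elif binning == "median":
            thr = float(np.median(v))
            bins = (v > thr).astype(int)
            if bins.min() == bins.max():
                gains[gene] = 0.0
                continue
            h_s = _entropy(y)
            n = len(y)
            g = h_s - sum(
                (bins == b).sum() / n * _entropy(y[bins == b]) for b in (0, 1)
            )
            p = np.bincount(bins) / n
            si = -(p[p > 0] * np.log2(p[p > 0])).sum()
            ratio = g / si if si > 0 else 0.0
        else:
            raise ValueError(f"unknown binning {binning!r}")
        gains[gene] = float(ratio)
        thresholds[gene] = float(thr)
    final = sorted(g for g, v in gains.items() if v > 0)
    return GeneSelectionResult(
        per_vf_rankings=rankings or {},
        candidates=list(candidates),
        gain=gains,
        final=final,
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# Elastic-net risk models


@dataclass
class RiskModel:
    coefficients: dict[str, float]
    intercept: float
    alpha: float  # elastic-net mixing (1 = lasso, 0 = ridge)
    lambda_path: np.ndarray
    chosen_lambda: float
    training_target: str  # 'vf_risk' | 'ground_truth_24mo'
    n_folds: int
    seed: int
    gene_means: dict[str, float] = field(default_factory=dict)
    gene_sds: dict[str, float] = field(default_factory=dict)
    cv_deviance: dict[float, tuple[float, float]] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.coefficients)


def ground_truth_24mo_labels(
    survival: pd.DataFrame, horizon: float = 24.0
) -> pd.Series:
    """Binary 24-month disease-free-status labels.

    1 = event within the horizon (poor outcome); 0 = event-free with at
    least ``horizon`` months of follow-up.  Cases censored before the
    horizon without an event are dropped (status unknowable).
    """
    t = survival["dfs_months"].to_numpy(dtype=float)
    e = survival["event"].to_numpy(dtype=int)
    poor = (e == 1) & (t <= horizon)
    good = t >= horizon
    keep = poor | good
    labels = pd.Series(
        poor[keep].astype(int), index=survival.index[keep], name="gt_24mo"
    )
    return labels


def _fit_enet(x, y, lam, alpha, seed) -> LogisticRegression:
    n = len(y)
    model = LogisticRegression(
        penalty="elasticnet",
        solver="saga",
        l1_ratio=alpha,
        C=1.0 / (lam * n),
        max_iter=2000,
        tol=1e-5,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # weakly penalized fits can hit max_iter; the CV deviance already
        # penalizes any resulting misfit, so the search stays well-defined
        warnings.simplefilter("ignore")
        model.fit(x, y)
    return model


def train_risk_model(
    expr: pd.DataFrame,
    gene_set: list[str],
    labels: pd.Series,
    alpha: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    lambda_path: np.ndarray | None = None,
    training_target: str = "vf_risk",
    lambda_rule: str = "1se",
) -> RiskModel:
    """Train a binomial elastic-net risk model on a gene set.

    Expression is ``log2(x + 1)``-transformed and z-scored on the training
    statistics.  The penalty ``lambda`` is chosen from ``lambda_path`` by
    ``n_folds``-fold cross-validated binomial deviance with the one-
    standard-error rule (largest lambda whose mean deviance is within one
    SE of the minimum).
    """
    if not gene_set:
        raise ValueError("empty gene set")
    shared = expr.columns.intersection(labels.index)
    y = labels.loc[shared].to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    x = np.log2(expr.loc[gene_set, shared].to_numpy(dtype=float).T + 1.0)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xz = (x - mu) / sd

    if lambda_path is None:
        lambda_path = np.logspace(-3, 0.5, 20)
    lambda_path = np.sort(np.asarray(lambda_path, dtype=float))[::-1]

    n_folds_eff = min(n_folds, int(np.bincount(y).min()))
    n_folds_eff = max(n_folds_eff, 2)
    cv = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    folds = list(cv.split(xz, y))
    dev = np.zeros((len(lambda_path), len(folds)))
    for li, lam in enumerate(lambda_path):
        for fi, (tr, te) in enumerate(folds):
            m = _fit_enet(xz[tr], y[tr], lam, alpha, seed)
            p = m.predict_proba(xz[te])[:, 1]
            dev[li, fi] = 2.0 * log_loss(
                y[te], p, labels=[0, 1], normalize=True
            )
    mean_dev = dev.mean(axis=1)
    se_dev = dev.std(axis=1, ddof=1) / np.sqrt(len(folds))
    i_min = int(np.argmin(mean_dev))
    if lambda_rule == "min":
        lam = float(lambda_path[i_min])
    elif lambda_rule == "1se":
        limit = mean_dev[i_min] + se_dev[i_min]
        # lambda_path is descending: first index within 1 SE = largest lambda
        i_1se = int(np.nonzero(mean_dev <= limit)[0][0])
        lam = float(lambda_path[i_1se])
    else:
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")

    final = _fit_enet(xz, y, lam, alpha, seed)
    coefs = {g: float(c) for g, c in zip(gene_set, final.coef_.ravel())}
    return RiskModel(
        coefficients=coefs,
        intercept=float(final.intercept_[0]),
        alpha=alpha,
        lambda_path=lambda_path,
        chosen_lambda=lam,
        training_target=training_target,
        n_folds=n_folds_eff,
        seed=seed,
        gene_means={g: float(m) for g, m in zip(gene_set, mu)},
        gene_sds={g: float(s) for g, s in zip(gene_set, sd)},
        cv_deviance={
            float(l): (float(m), float(s))
            for l, m, s in zip(lambda_path, mean_dev, se_dev)
        },
    )


def predict_risk(model: RiskModel, expr: pd.DataFrame) -> pd.Series:
    """Predicted high-risk probability per case."""
    genes = model.genes
    x = np.log2(expr.loc[genes].to_numpy(dtype=float).T + 1.0)
    mu = np.array([model.gene_means[g] for g in genes])
    sd = np.array([model.gene_sds[g] for g in genes])
    xz = (x - mu) / sd
    beta = np.array([model.coefficients[g] for g in genes])
    eta = xz @ beta + model.intercept
    return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=expr.columns, name="risk")


def evaluate_risk_model(
    model: RiskModel,
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    covariate_sets: dict[str, list[str]] | None = None,
    threshold: float = 0.5,
) -> dict:
    """Evaluate a risk model against survival outcomes.

    Predicts risk groups, computes the Kaplan-Meier curves, log-rank p,
    univariate Cox hazard ratio of the predicted group, multivariate Cox
    models for each covariate set (columns of ``survival`` plus ``risk``),
    and Harrell's C-index per set.  When the model was trained on 24-month
    ground truth, evaluation first applies the same 24-month rule: cases
    censored earlier without an event are dropped and follow-up is
    administratively censored at 24 months.
    """
    shared = expr.columns.intersection(survival.index)
    if len(shared) < 10:
        raise ValueError("need >= 10 shared cases for evaluation")
    surv = survival.loc[shared].copy()
    if model.training_target == "ground_truth_24mo":
        keep = ground_truth_24mo_labels(surv).index
        surv = surv.loc[keep]
        capped = np.minimum(surv["dfs_months"], 24.0)
        surv["event"] = ((surv["event"] == 1) & (surv["dfs_months"] <= 24.0)).astype(int)
        surv["dfs_months"] = capped
    proba = predict_risk(model, expr[surv.index])
    group = (proba >= threshold).astype(int)
    report: dict = {
        "risk_probability": proba,
        "risk_group": group,
        "n": len(surv),
        "threshold_used": float(threshold),
    }
    if group.nunique() < 2:
        # shrunken models can place every probability on one side of 0.5;
        # fall back to the conventional median risk-score split
        if proba.nunique() > 1:
            med = float(proba.median())
            group = (proba > med).astype(int)
            report["risk_group"] = group
            report["threshold_used"] = med
            report["flag"] = "median risk-score split (all probabilities on one side of threshold)"
        if group.nunique() < 2:
            report["flag"] = "single predicted risk group"
            return report

    stat, p = prognosis.logrank_test(
        surv["dfs_months"], surv["event"], group
    )
    report["logrank_stat"] = stat
    report["logrank_p"] = p
    report["km"] = {
        int(g): prognosis.km_curve(
            surv.loc[group == g, "dfs_months"], surv.loc[group == g, "event"]
        )
        for g in (0, 1)
    }
    uni = prognosis.cox_fit(
        surv["dfs_months"], surv["event"], pd.DataFrame({"risk": group})
    )
    report["hazard_ratio"] = uni.hazard_ratios.get("risk", float("nan"))
    report["hazard_ratio_ci"] = (
        uni.ci_lower.get("risk", float("nan")),
        uni.ci_upper.get("risk", float("nan")),
    )
    if covariate_sets is None:
        covariate_sets = {
            "stage": ["stage_high"],
            "stage+risk": ["stage_high", "risk"],
        }
    cindex = {}
    multivariate = {}
    covs_all = surv.assign(risk=group)
    for name, cols in covariate_sets.items():
        res = prognosis.cox_fit(
            surv["dfs_months"], surv["event"], covs_all[cols]
        )
        cindex[name] = res.c_index
        multivariate[name] = res
    report["c_index"] = cindex
    report["multivariate"] = multivariate
    return report
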