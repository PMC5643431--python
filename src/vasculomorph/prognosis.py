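"""Survival-driven vascular-feature selection and risk-group statistics.

The prognostic workflow mirrors the discovery-cohort analysis: coefficient-
of-variation filtering of the 88 vascular features, a stochastic backward
feature search minimizing the two-group log-rank p-value of a Ward
clustering, consensus clustering to confirm the number of risk groups,
Kaplan-Meier / Cox quantification of the separation, and a one-way ANOVA
F-test comparing intra-case to inter-case feature variance.

The two-group log-rank statistic is computed directly (vectorized
hypergeometric moments) because the backward search evaluates it tens of
thousands of times; Cox models, Kaplan-Meier estimates and the concordance
index are delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index
from scipy import stats
from scipy.cluster.hierarchy import cut_tree, linkage
from sklearn.metrics import silhouette_score

__all__ = [
    "FeatureSelectionResult",
    "variance_filter",
    "logrank_test",
    "km_curve",
    "cluster_risk_groups",
    "stochastic_backward_selection",
    "consensus_cluster_k",
    "cox_fit",
    "intra_inter_variance_ftest",
]


@dataclass
class FeatureSelectionResult:
    selected: list[str]
    frequency: dict[str, float]
    n_iter: int
    seed: int
    final_logrank_p: float


@dataclass
class CoxResult:
    hazard_ratios: dict[str, float]
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    p_values: dict[str, float]
    c_index: float
    converged: bool = True
    log_likelihood: float = float("nan")


def variance_filter(
    profiles: pd.DataFrame, cv_threshold: float = 0.3
) -> list[str]:
    """Keep features whose coefficient of variation |std/mean| across cases
    is at least ``cv_threshold`` (raw scale).

    Features with mean exactly 0 are retained iff their std is positive
    (CV undefined; logged via warning).  NaN entries are ignored per
    feature.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 cases")
    kept = []
    for col in profiles.columns:
        v = profiles[col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 2:
            continue
        sd = v.std(ddof=1)
        mean = v.mean()
        if sd == 0:  # constant features carry no information at any threshold
            continue
        if mean == 0:
            if sd > 0:
                warnings.warn(
                    f"feature {col!r}: zero mean, retained on std > 0",
                    stacklevel=2,
                )
                kept.append(col)
            continue
        if abs(sd / mean) >= cv_threshold:
            kept.append(col)
    return kept


def logrank_test(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test.

    Returns ``(chi-square statistic, p)`` with p from the chi-square
    distribution with 1 degree of freedom.  The statistic accumulates
    observed minus expected events in group 1 under the shared-hazard
    null, with hypergeometric variance terms.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("logrank_test requires exactly 2 non-empty groups")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    g1 = groups == labels[1]

    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    in1 = g1[order]

    event_times = np.unique(t[e == 1])
    n = len(t)
    n1 = in1.sum()
    o_minus_e = 0.0
    var = 0.0
    # walk event times; at-risk counts via searchsorted on the sorted times
    for et in event_times:
        first = np.searchsorted(t, et, side="left")
        at_risk = n - first
        at_risk1 = in1[first:].sum()
        sel = (t == et) & (e == 1)
        d = int(sel.sum())
        d1 = int((sel & in1).sum())
        if at_risk <= 1:
            continue
        frac = at_risk1 / at_risk
        o_minus_e += d1 - d * frac
        var += d * frac * (1 - frac) * (at_risk - d) / (at_risk - 1)
    if var <= 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def km_curve(
    times: np.ndarray, events: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit estimate.

    Returns ``(timeline, survival)`` with S(0) = 1 and survival evaluated
    just after each observed time.
    """
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, np.asarray(events).astype(int))
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def _km_at(times, events, t_eval) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events).astype(int))
    return float(kmf.predict(t_eval))


def cluster_risk_groups(
    profiles: pd.DataFrame,
    feature_subset: list[str],
    k: int = 2,
    survival: pd.DataFrame | None = None,
) -> pd.Series:
    """Ward-linkage clustering of cases into ``k`` risk groups.

    Features are z-scored across cases first.  With a survival table the
    group with the worse Kaplan-Meier curve at the median follow-up time
    is labeled 1 (high risk); without one, labels are arbitrary cluster
    indices.
    """
    if len(feature_subset) < 1:
        raise ValueError("feature_subset must not be empty")
    if k > len(profiles):
        raise ValueError("k exceeds number of cases")
    x = profiles[list(feature_subset)].to_numpy(dtype=float)
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    z = np.nan_to_num(z)
    if k == 1:
        return pd.Series(0, index=profiles.index, name="risk_group")
    lab = cut_tree(linkage(z, method="ward"), n_clusters=k).ravel()
    labels = pd.Series(lab, index=profiles.index, name="risk_group")
    if survival is not None and k == 2:
        surv = survival.loc[labels.index]
        t_med = float(np.median(surv["dfs_months"]))
        s_at = {}
        for g in (0, 1):
            m = labels == g
            if m.sum() == 0:
                return labels
            s_at[g] = _km_at(
                surv.loc[m, "dfs_months"], surv.loc[m, "event"], t_med
            )
        if s_at[0] < s_at[1]:  # group 0 has the worse curve -> relabel
            labels = 1 - labels
    return labels


def _clustered_logrank_p(
    z: np.ndarray,
    feat_idx: list[int],
    times: np.ndarray,
    events: np.ndarray,
    min_group_frac: float = 0.1,
) -> float:
    """log-rank p of the 2-group Ward clustering on a feature subset
    (z-scored matrix).

    Returns 1.0 when the clustering is degenerate, including when one
    group holds fewer than ``min_group_frac`` of the cases: risk groups
    are cohort fractions, and chance splits that peel off a few outlier
    cases would otherwise dominate a p-minimizing search.
    """
    sub = z[:, feat_idx]
    lab = cut_tree(linkage(sub, method="ward"), n_clusters=2).ravel()
    n1 = lab.sum()
    floor = max(3, int(min_group_frac * len(lab)))
    if n1 < floor or len(lab) - n1 < floor:
        return 1.0
    try:
        return logrank_test(times, events, lab)[1]
    except ValueError:
        return 1.0


def stochastic_backward_selection(
    profiles: pd.DataFrame,
    survival: pd.DataFrame,
    n_iter: int = 1500,
    subsample_frac: float = 0.8,
    seed: int = 0,
    frequency_threshold: float | None = None,
) -> FeatureSelectionResult:
    """Stochastic backward search for survival-separating features.

    Each iteration subsamples ``subsample_frac`` of the cases (its own RNG
    stream spawned from ``seed``) and runs a full greedy backward
    elimination: starting from all features, the feature whose removal
    yields the lowest log-rank p-value of the two-group Ward clustering is
    removed at every step until one feature remains; the iteration's best
    set is the subset with the smallest p along that path (ties resolved
    toward fewer features).  Selection frequencies are aggregated over
    iterations; the final set is every feature above
    ``frequency_threshold`` (default: the knee — largest drop — of the
    sorted frequency curve, falling back to 0.5 when the curve is flat).
    """
    feats = list(profiles.columns)
    if len(feats) < 2:
        raise ValueError("need at least 2 candidate features")
    if len(profiles) < 10:
        raise ValueError("need at least 10 cases")
    surv = survival.loc[profiles.index]
    times_all = surv["dfs_months"].to_numpy(dtype=float)
    events_all = surv["event"].to_numpy(dtype=int)
    x = profiles.to_numpy(dtype=float)
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    sd[sd == 0] = 1.0
    z_all = np.nan_to_num((x - mu) / sd)

    counts = np.zeros(len(feats))
    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(n_iter)]
    n_sub = max(10, int(round(subsample_frac * len(profiles))))
    n_sub = min(n_sub, len(profiles))
    for rng in streams:
        idx = rng.choice(len(profiles), size=n_sub, replace=False)
        z = z_all[idx]
        times = times_all[idx]
        events = events_all[idx]
        if events.sum() == 0:
            continue
        current = list(range(len(feats)))
        best_set = list(current)
        best_p = _clustered_logrank_p(z, current, times, events)
        while len(current) > 1:
            step_p, step_j = np.inf, current[0]
            for j in current:
                trial = [f for f in current if f != j]
                p = _clustered_logrank_p(z, trial, times, events)
                if p < step_p:
                    step_p, step_j = p, j
            current.remove(step_j)
            if step_p <= best_p:  # ties resolve toward the smaller set
                best_p = step_p
                best_set = list(current)
        counts[best_set] += 1

    freq = counts / max(n_iter, 1)
    if frequency_threshold is None:
        srt = np.sort(freq)[::-1]
        drops = srt[:-1] - srt[1:]
        if len(drops) and drops.max() > 0:
            knee = int(np.argmax(drops))
            frequency_threshold = (srt[knee] + srt[knee + 1]) / 2.0
        else:
            frequency_threshold = 0.5
    selected = [f for f, q in zip(feats, freq) if q > frequency_threshold]
    if not selected:
        selected = [feats[int(np.argmax(freq))]]

    sel_idx = [feats.index(f) for f in selected]
    final_p = _clustered_logrank_p(z_all, sel_idx, times_all, events_all)
    return FeatureSelectionResult(
        selected=selected,
        frequency={f: float(q) for f, q in zip(feats, freq)},
        n_iter=n_iter,
        seed=seed,
        final_logrank_p=final_p,
    )


def consensus_cluster_k(
    profiles: pd.DataFrame,
    feature_subset: list[str],
    k_range: tuple[int, ...] = (2, 3, 4),
    n_resamples: int = 50,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> tuple[int, dict[int, np.ndarray], dict[int, float]]:
    """Consensus clustering over case subsamples; picks k by silhouette.

    For each k, cases are repeatedly subsampled and Ward-clustered; the
    consensus matrix holds the fraction of co-subsampled pairs that were
    co-clustered.  The partition for each k comes from Ward clustering of
    the consensus distance (1 - consensus); the selected k maximizes the
    average silhouette width on that distance.
    """
    x = profiles[list(feature_subset)].to_numpy(dtype=float)
    sd = x.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("degenerate profiles: all cases identical")
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    n = len(z)
    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(subsample_frac * n)))

    matrices: dict[int, np.ndarray] = {}
    silhouettes: dict[int, float] = {}
    from scipy.spatial.distance import squareform

    for k in k_range:
        if k < 2 or k > n:
            continue
        co = np.zeros((n, n))
        tog = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, size=n_sub, replace=False)
            lab = cut_tree(linkage(z[idx], method="ward"), n_clusters=k).ravel()
            tog[np.ix_(idx, idx)] += 1
            for c in range(k):
                members = idx[lab == c]
                co[np.ix_(members, members)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(tog > 0, co / np.maximum(tog, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        cons = (cons + cons.T) / 2
        matrices[k] = cons
        dist = 1.0 - cons
        np.fill_diagonal(dist, 0.0)
        part = cut_tree(
            linkage(squareform(dist, checks=False), method="average"),
            n_clusters=k,
        ).ravel()
        if len(np.unique(part)) < 2:
            silhouettes[k] = -1.0
        else:
            silhouettes[k] = float(
                silhouette_score(dist, part, metric="precomputed")
            )
    if not silhouettes:
        raise ValueError("no valid k in k_range")
    best_k = max(silhouettes, key=silhouettes.get)
    return best_k, matrices, silhouettes


def cox_fit(
    times: np.ndarray,
    events: np.ndarray,
    covariates: pd.DataFrame,
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) with Wald CIs and
    Harrell's C-index of the fitted risk score.

    Constant covariates or non-convergence yield a flagged result
    (``converged=False``) rather than an exception.
    """
    df = covariates.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events).astype(int)
    if df["_event"].sum() < 1:
        raise ValueError("need at least one event")
    bad = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if bad:
        warnings.warn(f"constant covariates, HR undefined: {bad}", stacklevel=2)
        return CoxResult({}, {}, {}, {}, c_index=0.5, converged=False)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # separation / convergence failure
        warnings.warn(f"Cox fit failed: {exc}", stacklevel=2)
        return CoxResult({}, {}, {}, {}, c_index=0.5, converged=False)
    s = cph.summary
    risk = cph.predict_partial_hazard(covariates).to_numpy().ravel()
    ci = concordance_index(df["_time"], -risk, df["_event"])
    return CoxResult(
        hazard_ratios={c: float(np.exp(cph.params_[c])) for c in covariates},
        ci_lower={c: float(s.loc[c, "exp(coef) lower 95%"]) for c in covariates},
        ci_upper={c: float(s.loc[c, "exp(coef) upper 95%"]) for c in covariates},
        p_values={c: float(s.loc[c, "p"]) for c in covariates},
        c_index=float(ci),
        converged=True,
        log_likelihood=float(cph.log_likelihood_),
    )


def intra_inter_variance_ftest(
    tile_values: pd.DataFrame, feature: str | None = None
) -> tuple[float, float]:
    """One-way ANOVA F-test of inter-case versus intra-case variance.

    ``tile_values`` is a long table with columns ``case_id`` and ``value``
    (optionally pre-filtered to one feature via the ``feature`` column).
    F = between-case mean square / within-case mean square; small p means
    intra-case variance is significantly below inter-case variance.
    Returns ``(inf, nan)`` sentinel when the within-case variance is 0.
    """
    df = tile_values
    if feature is not None:
        df = df[df["feature"] == feature]
    groups = [g["value"].to_numpy(dtype=float) for _, g in df.groupby("case_id")]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 cases with >= 2 tiles each")
    within = np.concatenate([g - g.mean() for g in groups])
    if np.allclose(within, 0):
        return float("inf"), float("nan")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
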