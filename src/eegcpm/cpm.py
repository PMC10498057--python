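"""Connectome-based predictive modeling (CPM) with LOOCV and permutation tests.

CPM predicts a behavioral score from functional-connectivity edges:

1. leave-one-out cross-validation splits the cohort;
2. within each training set, every edge is correlated with behavior and
   edges passing ``p < threshold`` are kept, split by correlation sign into
   a positive and a negative network;
3. each subject's selected edges are summed into network strengths
   (combined = positive sum - negative sum);
4. a one-predictor linear regression of behavior on strength is fit on the
   training set and applied to the held-out subject;
5. after all folds, Pearson's r between predicted and observed scores
   evaluates the model, separately for the positive, negative and combined
   networks;
6. significance comes from re-running the whole LOOCV on behavior scores
   shuffled across subjects: p_perm = #(permuted r > observed r) / n_perm.

Edge selection, model coefficients and the empty-mask fallback are computed
strictly within each training fold — the held-out subject never influences
them. Folds whose selection is empty predict the training mean; a network
empty in every fold carries no prediction (r is NaN, mirroring the dashes
of published CPM tables).

An optional covariate (age) is controlled two ways at once, both on by
default when a covariate is supplied: partial correlation at the edge
selection step, and residualizing the covariate out of the training scores
before the strength model is fit (the covariate component is added back to
the held-out prediction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .connectivity import Connectome

__all__ = [
    "CPMResult",
    "CPMRun",
    "NETWORKS",
    "vectorize_connectomes",
    "edge_behavior_correlation",
    "select_edges",
    "network_strength",
    "cpm_loocv",
    "permutation_test",
]

NETWORKS = ("positive", "negative", "combined")


def vectorize_connectomes(connectomes: list[Connectome]) -> np.ndarray:
    """Stack subjects' strict-upper-triangle (row-major) edge vectors."""
    return np.vstack([c.edge_vector() for c in connectomes])


def _residualize(x: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Residuals of x (last axis = observations) after regressing on [1, c]."""
    c = covariate - covariate.mean()
    denom = float(c @ c)
    if denom == 0:
        return x - np.mean(x, axis=-1, keepdims=True)
    xc = x - np.mean(x, axis=-1, keepdims=True)
    beta = (xc @ c) / denom
    return xc - np.outer(beta, c) if x.ndim == 2 else xc - beta * c


def _pearson_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of X with y; constant columns give 0."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Xc.T @ yc) / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def _r_to_p(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p for Pearson r with the given error df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df / np.maximum(1.0 - r**2, 0.0))
    p = 2.0 * sps.t.sf(t, df)
    return np.where(np.isfinite(t), p, 0.0)


def edge_behavior_correlation(
    edges: np.ndarray, y: np.ndarray, covariate: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge Pearson (or partial Pearson) correlation with behavior.

    Returns (r, p). With a covariate, both edges and behavior are
    residualized on it and the error df drops by one. Constant edges get
    r = 0, p = 1 and are therefore never selected.
    """
    edges = np.asarray(edges, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(y) == 0:
        raise ValueError("behavior scores are constant")
    if covariate is not None:
        covariate = np.asarray(covariate, dtype=float)
        X = _residualize(edges.T, covariate).T
        yr = _residualize(y, covariate)
        df = n - 3
    else:
        X, yr = edges, y
        df = n - 2
    r = _pearson_columns(X, yr)
    p = _r_to_p(r, df)
    constant = np.ptp(edges, axis=0) == 0
    p = np.where(constant, 1.0, p)
    return r, p


def select_edges(
    r: np.ndarray, p: np.ndarray, threshold: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of positively / negatively behavior-linked edges.

    positive = {p < threshold and r > 0}; negative = {p < threshold and
    r < 0}. The masks are disjoint; both may be empty.
    """
    sig = np.asarray(p) < threshold
    return sig & (np.asarray(r) > 0), sig & (np.asarray(r) < 0)


def network_strength(
    edge_vector: np.ndarray, pos_mask: np.ndarray, neg_mask: np.ndarray
) -> tuple[float, float, float]:
    """(positive sum, negative sum, combined = positive - negative)."""
    pos = float(np.asarray(edge_vector)[pos_mask].sum())
    neg = float(np.asarray(edge_vector)[neg_mask].sum())
    return pos, neg, pos - neg


@dataclass
class CPMResult:
    """Outcome for one network sign."""

    network: str
    r: float  # NaN marks "no prediction" (masks empty in every fold)
    p: float
    predicted: np.ndarray
    observed: np.ndarray
    p_perm: float | None = None

    @property
    def no_prediction(self) -> bool:
        return not np.isfinite(self.r)


@dataclass
class CPMRun:
    """Full LOOCV outcome: per-fold masks plus one result per network."""

    threshold: float
    pos_masks: np.ndarray = field(repr=False)  # folds x edges, bool
    neg_masks: np.ndarray = field(repr=False)
    results: dict[str, CPMResult] = field(repr=False)

    def __getitem__(self, network: str) -> CPMResult:
        return self.results[network]


def _critical_r(threshold: float, df: int) -> float:
    t_crit = sps.t.isf(threshold / 2.0, df)
    return float(t_crit / np.sqrt(t_crit**2 + df))


def _loocv_predict(
    X: np.ndarray,
    y: np.ndarray,
    threshold: float,
    covariate: np.ndarray | None,
    keep_masks: bool,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray | None, np.ndarray | None]:
    """One full LOOCV pass.

    Returns (predictions per network, fold-had-selection flags per network,
    pos_masks, neg_masks). The no-covariate path updates the per-edge
    correlation sufficient statistics by removing one subject per fold,
    which makes the permutation loop O(n x E) per replicate.
    """
    n, n_edges = X.shape
    preds = {net: np.empty(n) for net in NETWORKS}
    used = {net: np.zeros(n, dtype=bool) for net in NETWORKS}
    pos_masks = np.zeros((n, n_edges), dtype=bool) if keep_masks else None
    neg_masks = np.zeros((n, n_edges), dtype=bool) if keep_masks else None

    if covariate is None:
        df = n - 1 - 2
        r_crit = _critical_r(threshold, df)
        sx = X.sum(axis=0)
        sxx = (X * X).sum(axis=0)
        sxy = (X * y[:, None]).sum(axis=0)
        sy = float(y.sum())
        syy = float(y @ y)

    for s in range(n):
        train = np.ones(n, dtype=bool)
        train[s] = False
        y_tr = y[train]
        if covariate is None:
            m = n - 1
            sx_ = sx - X[s]
            sxx_ = sxx - X[s] ** 2
            sxy_ = sxy - X[s] * y[s]
            sy_ = sy - y[s]
            syy_ = syy - y[s] ** 2
            cov = sxy_ - sx_ * sy_ / m
            vx = np.maximum(sxx_ - sx_**2 / m, 0.0)
            vy = max(syy_ - sy_**2 / m, 0.0)
            denom = np.sqrt(vx * vy)
            with np.errstate(invalid="ignore", divide="ignore"):
                r_tr = np.where(denom > 1e-12, cov / denom, 0.0)
            pos = r_tr > r_crit
            neg = r_tr < -r_crit
        else:
            r_tr, p_tr = edge_behavior_correlation(X[train], y_tr, covariate[train])
            pos, neg = select_edges(r_tr, p_tr, threshold)

        if keep_masks:
            pos_masks[s] = pos
            neg_masks[s] = neg

        if covariate is not None:
            # residualize training scores on age; predictions add the age
            # component back so observed raw scores remain the target
            c_tr = covariate[train]
            c_mean = c_tr.mean()
            cc = c_tr - c_mean
            cden = float(cc @ cc)
            b_age = float(cc @ (y_tr - y_tr.mean())) / cden if cden > 0 else 0.0
            a_age = y_tr.mean() - b_age * c_mean
            y_fit = y_tr - (a_age + b_age * c_tr)
            age_term = a_age + b_age * covariate[s]
        else:
            y_fit = y_tr
            age_term = 0.0

        for net, mask_vec in (
            ("positive", pos.astype(float)),
            ("negative", neg.astype(float)),
            ("combined", pos.astype(float) - neg.astype(float)),
        ):
            has_edges = pos.any() if net == "positive" else neg.any() if net == "negative" else (pos.any() or neg.any())
            if not has_edges:
                preds[net][s] = y_fit.mean() + age_term
                continue
            st = X @ mask_vec
            st_tr = st[train]
            var = float(np.var(st_tr))
            if var <= 1e-24:
                preds[net][s] = y_fit.mean() + age_term
                used[net][s] = True
                continue
            slope = float(np.cov(st_tr, y_fit, bias=True)[0, 1]) / var
            intercept = float(y_fit.mean() - slope * st_tr.mean())
            preds[net][s] = slope * st[s] + intercept + age_term
            used[net][s] = True

    return preds, used, pos_masks, neg_masks


def cpm_loocv(
    edges: np.ndarray | list[Connectome],
    y: np.ndarray,
    threshold: float = 0.05,
    covariate: np.ndarray | None = None,
) -> CPMRun:
    """Run the full LOOCV protocol and score each network.

    ``edges`` is a subjects x edges matrix (or a list of connectomes, which
    is vectorized first). Returns a :class:`CPMRun`; each network's ``r`` is
    the Pearson correlation of LOOCV predictions with observed scores, with
    its parametric two-sided p. Networks with no selected edge in any fold
    report NaN.
    """
    if not isinstance(edges, np.ndarray):
        edges = vectorize_connectomes(edges)
    X = np.asarray(edges, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if X.shape[0] != n:
        raise ValueError("edge matrix and scores disagree on subject count")
    if n < 5:
        raise ValueError("LOOCV needs at least 5 subjects")
    if np.ptp(y) == 0:
        raise ValueError("behavior scores are constant")
    if covariate is not None:
        covariate = np.asarray(covariate, dtype=float)

    preds, used, pos_masks, neg_masks = _loocv_predict(X, y, threshold, covariate, keep_masks=True)
    results = {}
    for net in NETWORKS:
        results[net] = _score_network(net, preds[net], used[net], y)
    return CPMRun(threshold=threshold, pos_masks=pos_masks, neg_masks=neg_masks, results=results)


def _score_network(net: str, predicted: np.ndarray, used: np.ndarray, y: np.ndarray) -> CPMResult:
    if not used.any() or np.ptp(predicted) == 0:
        return CPMResult(network=net, r=np.nan, p=np.nan, predicted=predicted, observed=y)
    r, p = sps.pearsonr(predicted, y)
    return CPMResult(network=net, r=float(r), p=float(p), predicted=predicted, observed=y)


def permutation_test(
    edges: np.ndarray,
    y: np.ndarray,
    run: CPMRun,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    covariate: np.ndarray | None = None,
    plus_one: bool = False,
) -> dict[str, float]:
    """Permutation significance for each network of a completed run.

    Behavior scores are shuffled across subjects and the entire LOOCV is
    repeated per permutation. Default estimator follows the strict
    convention p = #(permuted r > observed r) / n_perm, so 0 is attainable;
    ``plus_one=True`` switches to the (b + 1) / (m + 1) estimator.
    Permutations whose network yields no prediction count as not exceeding.
    The resulting p values are stored on ``run`` and returned.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    X = np.asarray(edges, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = {net: 0 for net in NETWORKS}
    observed = {net: run[net].r for net in NETWORKS}
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        preds, used, _, _ = _loocv_predict(X, y_perm, run.threshold, covariate, keep_masks=False)
        for net in NETWORKS:
            if not np.isfinite(observed[net]):
                continue
            if not used[net].any() or np.ptp(preds[net]) == 0:
                continue
            r_perm = np.corrcoef(preds[net], y_perm)[0, 1]
            if np.isfinite(r_perm) and r_perm > observed[net]:
                exceed[net] += 1
    out = {}
    for net in NETWORKS:
        if not np.isfinite(observed[net]):
            out[net] = float("nan")
        elif plus_one:
            out[net] = (exceed[net] + 1) / (n_perm + 1)
        else:
            out[net] = exceed[net] / n_perm
        run[net].p_perm = out[net]
    return out
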