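"""State decoding from nonperformance variables with bagged trees.

The classifier protocol: the per-mouse table of eight smoothed
nonperformance variables is row-shuffled in 25-trial blocks (breaking
the 50-trial smoothing autocorrelation while keeping trial rows intact),
split 1:1 into two halves, and a bagged ensemble of 30 fully grown
decision trees is trained on each half to score the other; the held-out
scores are recombined into chronological order so every trial is scored
exactly once.  Accuracy is quantified with one-vs-rest ROC curves pooled
over groups of iterations that draw random predictor pools of size 1–8,
and the AUC-vs-pool-size curve is summarized by a nonlinear
least-squares fit of the asymptotic exponential y = a − b·exp(−k·x).

Controls: cross-mouse prediction, trial-order (row) shuffling,
full shuffling (rows plus each predictor column independently),
physiologic/neurophysiologic predictor subsets, forced
inclusion/exclusion of one variable, and leave-one-predictor-out
GLM/multinomial-regression t-statistic distributions compared against
shuffled-response runs with Friedman tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm_api
from scipy import optimize, stats
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.tree import DecisionTreeClassifier

from . import config as cfg

STATE_ORDER = list(cfg.STATES)


# ---------------------------------------------------------------------------
# block shuffling and splitting
# ---------------------------------------------------------------------------

def block_shuffle_indices(n: int, block: int = cfg.SHUFFLE_BLOCK,
                          rng: int | np.random.Generator = 0) -> np.ndarray:
    """Permutation of 0..n-1 that permutes consecutive ``block``-sized
    blocks while preserving within-block order (last block may be short)."""
    if block < 1:
        raise ValueError("block must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    blocks = [np.arange(i, min(i + block, n)) for i in range(0, n, block)]
    order = rng.permutation(len(blocks))
    return np.concatenate([blocks[i] for i in order]) if blocks else \
        np.empty(0, dtype=int)


def block_shuffle(table: pd.DataFrame, block: int = cfg.SHUFFLE_BLOCK,
                  rng: int | np.random.Generator = 0) -> pd.DataFrame:
    """Row-shuffle a table in blocks (columns untouched)."""
    idx = block_shuffle_indices(len(table), block, rng)
    return table.iloc[idx].reset_index(drop=True)


def _split_halves(y: np.ndarray, block: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Block-shuffled 1:1 split; falls back to a stratified block split
    when a state is missing from either half."""
    n = y.size
    idx = block_shuffle_indices(n, block, rng)
    half_a, half_b = idx[: n // 2], idx[n // 2:]
    classes = np.unique(y)
    if (np.isin(classes, y[half_a]).all()
            and np.isin(classes, y[half_b]).all()):
        return half_a, half_b
    warnings.warn("state missing from a half; using stratified block split")
    blocks = [np.arange(i, min(i + block, n)) for i in range(0, n, block)]
    order = rng.permutation(len(blocks))
    # deal blocks alternately within each majority-label group
    majority = [pd.Series(y[blocks[i]]).mode().iloc[0] for i in order]
    a_parts, b_parts = [], []
    for lab in np.unique(majority):
        members = [order[j] for j in range(len(order)) if majority[j] == lab]
        for k, bi in enumerate(members):
            (a_parts if k % 2 == 0 else b_parts).append(blocks[bi])
    half_a = np.concatenate(a_parts) if a_parts else np.empty(0, int)
    half_b = np.concatenate(b_parts) if b_parts else np.empty(0, int)
    return half_a, half_b


# ---------------------------------------------------------------------------
# bagged-tree runs
# ---------------------------------------------------------------------------

@dataclass
class PredictionRun:
    """Held-out class scores for every trial, in chronological order."""

    scores: pd.DataFrame          # columns = states present, rows = trials
    predicted: np.ndarray
    variable_pool: List[str]
    seed: int


def _fit_score(X_train, y_train, X_test, classes, n_trees, rs):
    clf = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=rs),
        n_estimators=n_trees, random_state=rs)
    clf.fit(X_train, y_train)
    proba = clf.predict_proba(X_test)           # vote fractions of grown trees
    out = np.zeros((X_test.shape[0], len(classes)))
    for j, c in enumerate(clf.classes_):
        out[:, classes.index(c)] = proba[:, j]
    return out


def train_predict(features: pd.DataFrame, labels: Sequence,
                  variable_pool: Optional[Sequence[str]] = None,
                  seed: int = 0, block: int = cfg.SHUFFLE_BLOCK,
                  n_trees: int = cfg.N_TREES) -> PredictionRun:
    """One swapped-halves bagged-tree run; every trial scored once."""
    pool = list(cfg.NONPERFORMANCE_VARS if variable_pool is None
                else variable_pool)
    if not pool:
        raise ValueError("variable pool is empty")
    rng = np.random.default_rng(seed)
    X = features[pool].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=object)
    classes = [s for s in STATE_ORDER if s in set(y)]
    half_a, half_b = _split_halves(y, block, rng)
    scores = np.zeros((len(y), len(classes)))
    rs = int(rng.integers(2 ** 31 - 1))
    scores[half_b] = _fit_score(X[half_a], y[half_a], X[half_b],
                                classes, n_trees, rs)
    scores[half_a] = _fit_score(X[half_b], y[half_b], X[half_a],
                                classes, n_trees, rs + 1)
    sdf = pd.DataFrame(scores, columns=classes)
    predicted = np.asarray(classes, dtype=object)[scores.argmax(axis=1)]
    return PredictionRun(sdf, predicted, pool, seed)


# ---------------------------------------------------------------------------
# ROC pooling
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    state: str
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pooled: int
    flagged: bool = False


def pooled_roc(runs: Sequence[PredictionRun], labels: Sequence,
               state: str) -> RocCurve:
    """One-vs-rest ROC from (score, label) pairs pooled across iterations."""
    y = np.asarray(labels, dtype=object)
    ys, ss = [], []
    for run in runs:
        if state not in run.scores.columns:
            continue
        ys.append(y == state)
        ss.append(run.scores[state].to_numpy())
    if not ys:
        return RocCurve(state, np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                        np.nan, 0, flagged=True)
    yy = np.concatenate(ys)
    if yy.sum() == 0 or yy.sum() == yy.size:
        return RocCurve(state, np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                        np.nan, len(ys), flagged=True)
    fpr, tpr, _ = roc_curve(yy, np.concatenate(ss))
    return RocCurve(state, fpr, tpr, float(sk_auc(fpr, tpr)), len(ys))


# ---------------------------------------------------------------------------
# asymptotic exponential fit
# ---------------------------------------------------------------------------

@dataclass
class AsymptoticFit:
    a: float
    b: float
    k: float
    r_squared: float
    p_k: Optional[float]
    flagged: bool = False

    def predict(self, x) -> np.ndarray:
        return self.a - self.b * np.exp(-self.k * np.asarray(x, dtype=float))


def fit_asymptotic(x: np.ndarray, y: np.ndarray) -> AsymptoticFit:
    """Nonlinear least squares for y = a − b·exp(−k·x), multi-start.

    The p-value for the rate k uses the asymptotic normal approximation
    from the Jacobian-based parameter covariance.  Non-identifiable fits
    (flat curves, non-convergence, unstable covariance) are flagged with
    no p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 4:
        return AsymptoticFit(np.nan, np.nan, np.nan, np.nan, None, True)

    def model(xx, a, b, k):
        return a - b * np.exp(-k * xx)

    span = float(y.max() - y.min())
    if span < 1e-12:
        return AsymptoticFit(float(y.mean()), 0.0, np.nan, 0.0, None, True)
    best = None
    for k0 in (0.1, 0.3, 0.8, 2.0):
        try:
            popt, pcov = optimize.curve_fit(
                model, x, y, p0=[y.max(), span, k0], maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((y - model(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        return AsymptoticFit(np.nan, np.nan, np.nan, np.nan, None, True)
    sse, popt, pcov = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    se_k = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
    if not np.isfinite(se_k) or se_k <= 0:
        return AsymptoticFit(*popt, r2, None, True)
    z = popt[2] / se_k
    p_k = float(2.0 * stats.norm.sf(abs(z)))
    return AsymptoticFit(float(popt[0]), float(popt[1]), float(popt[2]),
                         r2, p_k)


# ---------------------------------------------------------------------------
# AUC vs pool size
# ---------------------------------------------------------------------------

def run_iterations(features: pd.DataFrame, labels: Sequence,
                   pools: Sequence[Sequence[str]], seed: int = 0,
                   block: int = cfg.SHUFFLE_BLOCK,
                   n_trees: int = cfg.N_TREES) -> List[PredictionRun]:
    rng = np.random.default_rng(seed)
    return [train_predict(features, labels, pool,
                          seed=int(rng.integers(2 ** 31 - 1)),
                          block=block, n_trees=n_trees)
            for pool in pools]


def auc_vs_pool_size(features: pd.DataFrame, labels: Sequence,
                     pool_sizes: Sequence[int] = cfg.POOL_SIZES,
                     n_iterations: int = cfg.N_ITERATIONS,
                     variables: Sequence[str] = cfg.NONPERFORMANCE_VARS,
                     seed: int = 0, mode: str = "pooled",
                     n_trees: int = cfg.N_TREES) -> tuple[
                         pd.DataFrame, Dict[str, AsymptoticFit]]:
    """AUC per (state, pool size) from groups of iterations with random
    variable pools, plus the asymptotic-exponential fit per state.

    ``mode``: "pooled" aggregates (score, label) pairs over the group's
    iterations into one ROC (default); "averaged" averages per-iteration
    AUCs instead.
    """
    rng = np.random.default_rng(seed)
    variables = list(variables)
    rows = []
    for m in pool_sizes:
        pools = [list(rng.choice(variables, size=m, replace=False))
                 for _ in range(n_iterations)]
        runs = run_iterations(features, labels, pools,
                              seed=int(rng.integers(2 ** 31 - 1)),
                              n_trees=n_trees)
        for state in STATE_ORDER:
            if mode == "pooled":
                a = pooled_roc(runs, labels, state).auc
            else:
                aucs = [pooled_roc([r], labels, state).auc for r in runs]
                a = float(np.nanmean(aucs))
            rows.append({"state": state, "pool_size": m, "auc": a})
    table = pd.DataFrame(rows)
    fits = {}
    for state in STATE_ORDER:
        g = table[table["state"] == state].dropna(subset=["auc"])
        fits[state] = fit_asymptotic(g["pool_size"].to_numpy(),
                                     g["auc"].to_numpy())
    return table, fits


def single_variable_rank(features: pd.DataFrame, labels: Sequence,
                         n_iterations: int = cfg.N_ITERATIONS,
                         variables: Sequence[str] = cfg.NONPERFORMANCE_VARS,
                         seed: int = 0,
                         n_trees: int = cfg.N_TREES) -> pd.DataFrame:
    """Fixed single-variable iterations; variables ranked by mean AUC
    across states (rank 1 = most predictive)."""
    rng = np.random.default_rng(seed)
    rows = []
    for var in variables:
        runs = run_iterations(features, labels, [[var]] * n_iterations,
                              seed=int(rng.integers(2 ** 31 - 1)),
                              n_trees=n_trees)
        row = {"variable": var}
        for state in STATE_ORDER:
            row[f"auc_{state}"] = pooled_roc(runs, labels, state).auc
        rows.append(row)
    table = pd.DataFrame(rows)
    table["mean_auc"] = table[[f"auc_{s}" for s in STATE_ORDER]].mean(axis=1)
    table = table.sort_values("mean_auc", ascending=False,
                              ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    if table["mean_auc"].max() < 0.55:
        warnings.warn("all single-variable AUCs near chance; ranking is "
                      "arbitrary")
    return table


# ---------------------------------------------------------------------------
# shuffle and subset controls
# ---------------------------------------------------------------------------

def full_shuffle(features: pd.DataFrame, variables: Sequence[str],
                 rng: int | np.random.Generator = 0) -> pd.DataFrame:
    """Permute trial order and every predictor column independently,
    destroying both autocorrelation and variable-state coupling."""
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    out = features.iloc[rng.permutation(len(features))].reset_index(drop=True)
    for var in variables:
        out[var] = rng.permutation(out[var].to_numpy())
    return out


def row_shuffle(features: pd.DataFrame, labels: Sequence,
                rng: int | np.random.Generator = 0) -> tuple[
                    pd.DataFrame, np.ndarray]:
    """Permute trial order only (rows stay intact, labels travel along)."""
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    perm = rng.permutation(len(features))
    return (features.iloc[perm].reset_index(drop=True),
            np.asarray(labels, dtype=object)[perm])


def cross_mouse_auc(per_mouse: Dict[str, tuple[pd.DataFrame, Sequence]],
                    variables: Sequence[str] = cfg.NONPERFORMANCE_VARS,
                    n_iterations: int = 10, seed: int = 0,
                    block: int = cfg.SHUFFLE_BLOCK,
                    n_trees: int = cfg.N_TREES) -> pd.DataFrame:
    """AUC for every ordered predictor-mouse -> predicted-mouse pair.

    The diagonal reproduces the within-mouse protocol; off-diagonal pairs
    train on half of one mouse's shuffled table and score a size-matched
    held-out set from the other mouse.
    """
    if len(per_mouse) < 2:
        raise ValueError("cross-mouse control needs >= 2 mice")
    rng = np.random.default_rng(seed)
    variables = list(variables)
    rows = []
    for m_train, (Xa, ya) in per_mouse.items():
        for m_test, (Xb, yb) in per_mouse.items():
            ys_all = {s: [] for s in STATE_ORDER}
            ss_all = {s: [] for s in STATE_ORDER}
            for _ in range(n_iterations):
                if m_train == m_test:
                    run = train_predict(
                        Xa, ya, variables,
                        seed=int(rng.integers(2 ** 31 - 1)),
                        block=block, n_trees=n_trees)
                    for s in run.scores.columns:
                        ys_all[s].append(np.asarray(ya, dtype=object) == s)
                        ss_all[s].append(run.scores[s].to_numpy())
                    continue
                ia = block_shuffle_indices(len(Xa), block, rng)
                ib = block_shuffle_indices(len(Xb), block, rng)
                n_half = min(len(ia) // 2, len(ib) // 2)
                tr, te = ia[:n_half], ib[:n_half]
                ya_np = np.asarray(ya, dtype=object)
                yb_np = np.asarray(yb, dtype=object)
                classes = [s for s in STATE_ORDER if s in set(ya_np[tr])]
                sc = _fit_score(Xa[variables].to_numpy()[tr], ya_np[tr],
                                Xb[variables].to_numpy()[te], classes,
                                n_trees, int(rng.integers(2 ** 31 - 1)))
                for j, s in enumerate(classes):
                    ys_all[s].append(yb_np[te] == s)
                    ss_all[s].append(sc[:, j])
            for s in STATE_ORDER:
                if not ys_all[s]:
                    continue
                yy = np.concatenate(ys_all[s])
                if 0 < yy.sum() < yy.size:
                    fpr, tpr, _ = roc_curve(yy, np.concatenate(ss_all[s]))
                    rows.append({"train": m_train, "test": m_test,
                                 "state": s, "auc": float(sk_auc(fpr, tpr)),
                                 "within": m_train == m_test})
    return pd.DataFrame(rows)


def control_predictions(mode: str, features: pd.DataFrame = None,
                        labels: Sequence = None,
                        per_mouse: Dict = None, seed: int = 0,
                        n_iterations: int = 20,
                        variable: str = "prestim_lick_rate",
                        n_trees: int = cfg.N_TREES, **kw) -> pd.DataFrame:
    """Dispatch for the control analyses; returns AUC tables."""
    rng = np.random.default_rng(seed)
    if mode == "cross_mouse":
        return cross_mouse_auc(per_mouse, seed=seed,
                               n_iterations=n_iterations, n_trees=n_trees,
                               **kw)
    if mode in ("row_shuffle", "full_shuffle"):
        ys, runs = [], []
        for _ in range(n_iterations):
            if mode == "row_shuffle":
                Xs, yb = row_shuffle(features, labels, rng)
            else:
                Xs = full_shuffle(features, cfg.NONPERFORMANCE_VARS, rng)
                yb = np.asarray(labels, dtype=object)
            run = train_predict(Xs, yb, cfg.NONPERFORMANCE_VARS,
                                seed=int(rng.integers(2 ** 31 - 1)),
                                n_trees=n_trees)
            runs.append((run, yb))
        rows = []
        for state in STATE_ORDER:
            yy = np.concatenate([y == state for _, y in runs])
            ss = np.concatenate([r.scores[state].to_numpy()
                                 if state in r.scores.columns
                                 else np.zeros(len(y))
                                 for r, y in runs])
            if 0 < yy.sum() < yy.size:
                fpr, tpr, _ = roc_curve(yy, ss)
                rows.append({"state": state, "auc": float(sk_auc(fpr, tpr)),
                             "mode": mode})
        return pd.DataFrame(rows)
    if mode in ("subset_physio", "subset_neuro"):
        vars_ = list(cfg.PHYSIO_VARS if mode == "subset_physio"
                     else cfg.NEURO_VARS)
        table, _ = auc_vs_pool_size(
            features, labels, pool_sizes=range(1, len(vars_) + 1),
            n_iterations=n_iterations, variables=vars_, seed=seed,
            n_trees=n_trees)
        table["mode"] = mode
        return table
    if mode in ("always_include_var", "always_exclude_var"):
        include = mode == "always_include_var"
        others = [v for v in cfg.NONPERFORMANCE_VARS if v != variable]
        rows = []
        sizes = range(1, 9) if include else range(1, 8)
        for m in sizes:
            pools = []
            for _ in range(n_iterations):
                if include:
                    extra = list(rng.choice(others, size=m - 1,
                                            replace=False)) if m > 1 else []
                    pools.append([variable] + extra)
                else:
                    pools.append(list(rng.choice(others, size=m,
                                                 replace=False)))
            runs = run_iterations(features, labels, pools,
                                  seed=int(rng.integers(2 ** 31 - 1)),
                                  n_trees=n_trees)
            for state in STATE_ORDER:
                rows.append({"state": state, "pool_size": m,
                             "auc": pooled_roc(runs, labels, state).auc,
                             "mode": mode, "variable": variable})
        return pd.DataFrame(rows)
    raise ValueError(f"unknown control mode: {mode}")


# ---------------------------------------------------------------------------
# regression controls (GLM / multinomial)
# ---------------------------------------------------------------------------

@dataclass
class RegressionControlResult:
    t_real: pd.DataFrame          # one row per (iteration, predictor[, state])
    t_shuffled: pd.DataFrame
    friedman: pd.DataFrame        # scope, statistic, p
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def friedman_p(self) -> float:
        return float(self.friedman["p"].min())


def _loo_glm_t(X: np.ndarray, names: List[str], response: np.ndarray
               ) -> pd.DataFrame:
    """Leave-one-predictor-out OLS t-statistics (intercept removed)."""
    rows = []
    for omit in range(len(names)):
        keep = [j for j in range(len(names)) if j != omit]
        res = sm_api.OLS(response, X[:, keep]).fit()
        for j, t in zip(keep, res.tvalues):
            rows.append({"omitted": names[omit], "predictor": names[j],
                         "t": float(t)})
    return pd.DataFrame(rows)


def _loo_mnr_t(X: np.ndarray, names: List[str], states: np.ndarray
               ) -> pd.DataFrame:
    """Leave-one-out multinomial-regression t-statistics, parsed by state.

    Each of the three states serves as the reference category in turn;
    coefficients are attributed to their (non-reference) state.
    """
    rows = []
    present = [s for s in STATE_ORDER if s in set(states)]
    for ref in present:
        cats = [ref] + [s for s in present if s != ref]
        codes = pd.Categorical(states, categories=cats).codes
        for omit in range(len(names)):
            keep = [j for j in range(len(names)) if j != omit]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm_api.MNLogit(codes, X[:, keep]).fit(
                    disp=0, maxiter=200)
            tv = np.asarray(res.tvalues)          # (k_keep, n_cats-1)
            for col, state in enumerate(cats[1:]):
                for r, j in enumerate(keep):
                    rows.append({"reference": ref, "state": state,
                                 "omitted": names[omit],
                                 "predictor": names[j],
                                 "t": float(tv[r, col])})
    return pd.DataFrame(rows)


def regression_controls(features: pd.DataFrame, labels: Sequence,
                        response: str = "correctness",
                        correctness: Optional[np.ndarray] = None,
                        seed: int = 0) -> RegressionControlResult:
    """GLM (response = smoothed correctness) or MNR (response = states)
    leave-one-predictor-out t-statistics, real vs shuffled response, with
    a Friedman test across the per-predictor t distributions."""
    rng = np.random.default_rng(seed)
    names = list(cfg.NONPERFORMANCE_VARS)
    X = features[names].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0,
                                        X.std(axis=0))
    if response == "correctness":
        if correctness is None:
            raise ValueError("GLM branch needs the smoothed correctness")
        resp = np.asarray(correctness, dtype=float)
        t_real = _loo_glm_t(X, names, resp)
        t_shuf = _loo_glm_t(X, names, rng.permutation(resp))
    elif response == "states":
        y = np.asarray(labels, dtype=object)
        t_real = _loo_mnr_t(X, names, y)
        t_shuf = _loo_mnr_t(X, names, rng.permutation(y))
    else:
        raise ValueError(f"unknown response: {response}")

    # Friedman across treatments (predictor x {real, shuffled}) with the
    # leave-one-out iterations as blocks; the multinomial branch is parsed
    # per state, since coefficients mirror across reference rotations
    def _compare(tr: pd.DataFrame, ts: pd.DataFrame, scope: str,
                 fr_rows: list, post_rows: list) -> None:
        groups = []
        for name in names:
            groups.append(tr.loc[tr["predictor"] == name, "t"].to_numpy())
            groups.append(ts.loc[ts["predictor"] == name, "t"].to_numpy())
        n_min = min(len(g) for g in groups)
        groups = [g[:n_min] for g in groups]
        stat, p = stats.friedmanchisquare(*groups)
        fr_rows.append({"scope": scope, "statistic": float(stat),
                        "p": float(p)})
        res = stats.tukey_hsd(*groups)
        for i, name in enumerate(names):
            post_rows.append({
                "scope": scope, "predictor": name,
                "p_real_vs_shuffled": float(res.pvalue[2 * i, 2 * i + 1])})

    fr_rows: list = []
    post_rows: list = []
    if "state" in t_real.columns:
        for state in sorted(set(t_real["state"])):
            _compare(t_real[t_real["state"] == state],
                     t_shuf[t_shuf["state"] == state],
                     state, fr_rows, post_rows)
    else:
        _compare(t_real, t_shuf, "overall", fr_rows, post_rows)
    return RegressionControlResult(t_real, t_shuf, pd.DataFrame(fr_rows),
                                   pd.DataFrame(post_rows))
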