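"""Reporter-response analysis: time-course standardization, response
variables, clustering, regression and classification harnesses with
permutation validation, feature importance, per-variant significance, and
the EC200 detection threshold.

The luminescence readout of each variant is a pair of time courses
(with and without the inducer); their difference curve is interpolated
onto a common grid and summarized into four response variables (maximum
difference, average difference, maximum slope, time to maximum). Those
variables are predicted from sequence features by three regression
harnesses (forward-selected linear, L1-penalized linear, forward-selected
gradient-boosted trees) over repeated random splits, and a three-class
label (tertiles of control-relative maximum difference) by an RBF-kernel
SVM and boosted trees, validated against 100 label permutations.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.linear_model import LassoCV, LinearRegression
from sklearn.metrics import davies_bouldin_score, silhouette_score
from sklearn.svm import SVC
import xgboost as xgb

from .features import FeatureTable

logger = logging.getLogger("pforge")


@dataclasses.dataclass
class LuminescenceSeries:
    """One variant's paired luminescence time course (one replicate)."""

    variant_id: str
    time: np.ndarray  # hours, strictly increasing
    lum_dnt: np.ndarray
    lum_ctrl: np.ndarray
    replicate: int = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.lum_dnt = np.asarray(self.lum_dnt, dtype=float)
        self.lum_ctrl = np.asarray(self.lum_ctrl, dtype=float)
        if not (self.time.shape == self.lum_dnt.shape == self.lum_ctrl.shape):
            raise ValueError(f"{self.variant_id}: unequal series lengths")
        if len(self.time) > 1 and not (np.diff(self.time) > 0).all():
            raise ValueError(f"{self.variant_id}: time not strictly increasing")

    @property
    def delta(self) -> np.ndarray:
        return self.lum_dnt - self.lum_ctrl


@dataclasses.dataclass
class ResponseVariables:
    max_diff: float
    avg_diff: float
    max_slope: float
    time_to_max: float


@dataclasses.dataclass
class ModelReport:
    """Per-model cross-validation record.

    ``val_scores`` holds one validation correlation (regression) or
    accuracy (classification) per repeat; ``selected`` the feature list
    chosen in each repeat; ``null_scores`` the label-permutation
    distribution (classification only).
    """

    model: str
    val_scores: list[float]
    selected: list[list[str]]
    hyperparams: dict
    null_scores: list[float] | None = None

    def summary(self) -> pd.DataFrame:
        rows = {
            "model": self.model,
            "repeats": len(self.val_scores),
            "median_val_score": float(np.median(self.val_scores)),
            "mean_val_score": float(np.mean(self.val_scores)),
        }
        if self.null_scores is not None:
            rows["null_mean"] = float(np.mean(self.null_scores))
            rows["null_max"] = float(np.max(self.null_scores))
        return pd.DataFrame([rows])


def standardize_timegrid(
    series: list[LuminescenceSeries], grid: np.ndarray
) -> pd.DataFrame:
    """Difference curves interpolated onto a common time grid.

    Linear interpolation inside the measured span; beyond it the boundary
    value is held constant. Rows are (variant, replicate) pairs.
    """
    grid = np.asarray(grid, dtype=float)
    rows = {}
    for s in series:
        if len(s.time) < 2:
            raise ValueError(f"{s.variant_id}: need at least two time points")
        rows[(s.variant_id, s.replicate)] = np.interp(grid, s.time, s.delta)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(grid))
    df.index = pd.MultiIndex.from_tuples(df.index, names=["variant_id", "replicate"])
    return df


def response_variables(delta: np.ndarray, t: np.ndarray) -> ResponseVariables:
    """Summaries of one difference curve (first maximum breaks ties)."""
    delta = np.asarray(delta, dtype=float)
    t = np.asarray(t, dtype=float)
    if delta.shape != t.shape:
        raise ValueError("delta and time lengths differ")
    if len(delta) > 1:
        slopes = np.diff(delta) / np.diff(t)
        max_slope = float(slopes.max())
    else:
        max_slope = 0.0
    imax = int(np.argmax(delta))
    return ResponseVariables(
        max_diff=float(delta.max()),
        avg_diff=float(delta.mean()),
        max_slope=max_slope,
        time_to_max=float(t[imax]),
    )


def cluster_responses(
    delta_matrix: np.ndarray,
    k_candidates: tuple[int, ...] = (2, 3, 4, 5),
    seed: int = 0,
) -> tuple[np.ndarray, int, pd.DataFrame]:
    """K-means on difference profiles with correlation distance.

    Profiles are standardized row-wise (zero mean, unit norm), under which
    squared Euclidean distance is proportional to 1 - Pearson correlation,
    so ordinary K-means optimizes the correlation criterion. K is chosen
    by the silhouette score (computed with correlation distance); if the
    Davies-Bouldin index prefers a different K the silhouette wins and the
    disagreement is logged. Returns (labels, chosen K, diagnostics table).
    """
    X = np.asarray(delta_matrix, dtype=float)
    if X.shape[0] < 2 * max(k_candidates):
        raise ValueError("too few profiles for the requested K values")
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    flat = norms[:, 0] == 0
    if flat.any():
        logger.warning("%d constant profiles assigned by Euclidean fallback", int(flat.sum()))
        norms[flat] = 1.0
    Z = centered / norms
    records = []
    results = {}
    for k in k_candidates:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(Z)
        sil = silhouette_score(Z, labels, metric="correlation") if len(set(labels)) > 1 else -1.0
        db = davies_bouldin_score(Z, labels)
        records.append({"K": k, "silhouette": sil, "davies_bouldin": db})
        results[k] = labels
    diag = pd.DataFrame(records)
    k_sil = int(diag.loc[diag["silhouette"].idxmax(), "K"])
    k_db = int(diag.loc[diag["davies_bouldin"].idxmin(), "K"])
    if k_sil != k_db:
        logger.info("silhouette prefers K=%d, Davies-Bouldin K=%d; using silhouette", k_sil, k_db)
    return results[k_sil], k_sil, diag


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = float(np.corrcoef(a, b)[0, 1])
    return r if np.isfinite(r) else 0.0


def _screen(X: np.ndarray, y: np.ndarray, rows: np.ndarray, top: int) -> list[int]:
    """Top features by |Pearson r| with the target on the given rows —
    the candidate pool for forward selection."""
    Xr = X[rows]
    yr = y[rows]
    xc = Xr - Xr.mean(axis=0)
    yc = yr - yr.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs((xc * yc[:, None]).sum(axis=0) / denom)
    r[~np.isfinite(r)] = 0.0
    top = min(top, X.shape[1])
    return sorted(np.argsort(-r, kind="stable")[:top].tolist())


def _forward_select(candidates, fit_score, max_features: int = 20):
    """Greedy forward selection maximizing a held-out objective.

    ``fit_score(cols) -> score`` fits on the training rows restricted to
    ``cols`` and returns the test-set objective. The accepted objective is
    non-decreasing across steps.
    """
    selected: list[int] = []
    best_score = -np.inf
    remaining = list(candidates)
    while remaining and len(selected) < max_features:
        scores = [(fit_score(selected + [j]), j) for j in remaining]
        step_best, j_best = max(scores, key=lambda t: (t[0], -t[1]))
        if step_best <= best_score:
            break
        best_score = step_best
        selected.append(j_best)
        remaining.remove(j_best)
    return selected, best_score


_XGB_SPACE = {
    "n_estimators": (30, 300),
    "max_depth": (2, 8),
    "learning_rate": (0.01, 0.3),
    "subsample": (0.5, 1.0),
    "colsample_bytree": (0.5, 1.0),
    "reg_lambda": (0.1, 10.0),
}


def _sample_xgb_params(rng: np.random.Generator) -> dict:
    p = {}
    for k, (lo, hi) in _XGB_SPACE.items():
        if isinstance(lo, int):
            p[k] = int(rng.integers(lo, hi + 1))
        elif k in ("learning_rate", "reg_lambda"):
            p[k] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            p[k] = float(rng.uniform(lo, hi))
    return p


def search_xgb_params(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
    n_trials: int = 50, seed: int = 0, classify: bool = False,
) -> dict:
    """Budgeted random search over the boosted-tree space, scored on a
    held-out validation split by R^2 (regression) or accuracy."""
    n = X.shape[0]
    idx = rng.permutation(n)
    cut = int(0.8 * n)
    tr, va = idx[:cut], idx[cut:]
    best, best_score = None, -np.inf
    for _ in range(n_trials):
        params = _sample_xgb_params(rng)
        if classify:
            model = xgb.XGBClassifier(**params, random_state=seed, n_jobs=1, verbosity=0)
            model.fit(X[tr], y[tr])
            score = float((model.predict(X[va]) == y[va]).mean())
        else:
            model = xgb.XGBRegressor(**params, random_state=seed, n_jobs=1, verbosity=0)
            model.fit(X[tr], y[tr])
            pred = model.predict(X[va])
            ss_res = float(((y[va] - pred) ** 2).sum())
            ss_tot = float(((y[va] - y[va].mean()) ** 2).sum())
            score = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        if score > best_score:
            best, best_score = params, score
    return best or {}


def fit_regressors(
    table: FeatureTable,
    target: np.ndarray | pd.Series,
    cv_repeats: int = 10,
    seed: int = 0,
    n_trials: int = 50,
    max_features: int = 12,
    screen_top: int = 40,
) -> dict[str, ModelReport]:
    """Three regression harnesses over repeated random splits.

    linear: 60/20/20 train/test/validation, forward selection maximizing
    the test-set Pearson correlation; lasso: 80/20 with LassoCV choosing
    the penalty along its regularization path; xgboost: 60/20/20 with
    forward selection, hyperparameters from one budgeted random search.
    Forward selection searches the ``screen_top`` features most correlated
    with the target on the training rows. Each report records the
    validation-set correlation per repeat.
    """
    X = table.values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    y = np.asarray(target, dtype=float)
    names = list(table.values.columns)
    n = X.shape[0]
    if n < 30:
        raise ValueError(f"need at least 30 variants, got {n}")
    rng = np.random.default_rng(seed)
    xgb_params = search_xgb_params(X, y, rng, n_trials=n_trials, seed=seed)

    reports = {
        "linear": ModelReport("linear", [], [], {}),
        "lasso": ModelReport("lasso", [], [], {}),
        "xgboost": ModelReport("xgboost", [], [], xgb_params),
    }
    for rep in range(cv_repeats):
        idx = rng.permutation(n)
        n_tr, n_te = int(0.6 * n), int(0.2 * n)
        tr, te, va = idx[:n_tr], idx[n_tr : n_tr + n_te], idx[n_tr + n_te :]

        pool = _screen(X, y, tr, screen_top)

        def lin_score(cols):
            m = LinearRegression().fit(X[np.ix_(tr, cols)], y[tr])
            return _pearson(m.predict(X[np.ix_(te, cols)]), y[te])

        sel, _ = _forward_select(pool, lin_score, max_features)
        m = LinearRegression().fit(X[np.ix_(tr, sel)], y[tr])
        r = _pearson(m.predict(X[np.ix_(va, sel)]), y[va])
        reports["linear"].val_scores.append(r)
        reports["linear"].selected.append([names[j] for j in sel])

        cut = int(0.8 * n)
        tr8, va8 = idx[:cut], idx[cut:]
        mu, sd = X[tr8].mean(axis=0), X[tr8].std(axis=0)
        sd[sd == 0] = 1.0
        Xz = (X - mu) / sd  # the L1 path needs comparable feature scales
        lasso = LassoCV(cv=5, random_state=seed + rep, max_iter=20000).fit(Xz[tr8], y[tr8])
        r = _pearson(lasso.predict(Xz[va8]), y[va8])
        reports["lasso"].val_scores.append(r)
        reports["lasso"].selected.append(
            [names[j] for j in np.nonzero(lasso.coef_)[0]]
        )

        # small surrogate trees keep the greedy search tractable; the final
        # model per repeat uses the searched hyperparameters
        surrogate = dict(n_estimators=60, max_depth=3, learning_rate=0.2)

        def xgb_score(cols):
            m = xgb.XGBRegressor(**surrogate, random_state=seed, n_jobs=1, verbosity=0)
            m.fit(X[np.ix_(tr, cols)], y[tr])
            return _pearson(m.predict(X[np.ix_(te, cols)]), y[te])

        sel, _ = _forward_select(pool, xgb_score, max_features)
        m = xgb.XGBRegressor(**xgb_params, random_state=seed, n_jobs=1, verbosity=0)
        m.fit(X[np.ix_(tr, sel)], y[tr])
        r = _pearson(m.predict(X[np.ix_(va, sel)]), y[va])
        reports["xgboost"].val_scores.append(r)
        reports["xgboost"].selected.append([names[j] for j in sel])
    return reports


def tertile_labels(max_diff: np.ndarray, control_value: float) -> np.ndarray:
    """Three balanced classes from control-relative maximum differences."""
    rel = np.asarray(max_diff, dtype=float) - control_value
    q1, q2 = np.quantile(rel, [1 / 3, 2 / 3])
    labels = np.digitize(rel, [q1, q2])
    counts = np.bincount(labels, minlength=3)
    if counts.min() == 0 or counts.max() - counts.min() > max(3, 0.1 * len(rel)):
        raise ValueError(
            f"degenerate tertile split (class counts {counts.tolist()}): "
            "too many tied values"
        )
    return labels


def classify_variants(
    table: FeatureTable,
    max_diff: np.ndarray,
    control_value: float,
    cv_repeats: int = 10,
    seed: int = 0,
    n_permutations: int = 100,
    n_trials: int = 20,
    max_features: int = 10,
    screen_top: int = 30,
) -> dict[str, ModelReport]:
    """Three-class classification with label-permutation validation.

    Labels are tertiles of control-relative max_diff (balanced by
    construction). Two classifiers (RBF-kernel SVM, boosted trees), each
    80/20 split per repeat with forward selection on held-out accuracy.
    The null distribution refits each classifier on permuted labels using
    the features selected on the real labels.
    """
    X = table.values.to_numpy(dtype=float)
    names = list(table.values.columns)
    y = tertile_labels(max_diff, control_value)
    if np.bincount(y, minlength=3).min() < 3:
        raise ValueError("need at least 3 variants per class")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd  # SVM needs comparable scales
    xgb_params = search_xgb_params(Xs, y, rng, n_trials=n_trials, seed=seed, classify=True)

    def make_model(tag):
        if tag == "svm":
            return SVC(kernel="rbf", random_state=seed)
        return xgb.XGBClassifier(**xgb_params, random_state=seed, n_jobs=1, verbosity=0)

    reports = {
        "svm": ModelReport("svm", [], [], {"kernel": "rbf"}, null_scores=[]),
        "xgboost": ModelReport("xgboost", [], [], xgb_params, null_scores=[]),
    }
    splits = []
    for rep in range(cv_repeats):
        idx = rng.permutation(n)
        cut = int(0.8 * n)
        splits.append((idx[:cut], idx[cut:]))
        pool = _screen(Xs, y.astype(float), idx[:cut], screen_top)
        for tag in ("svm", "xgboost"):
            tr, te = splits[-1]

            def acc_score(cols, tr=tr, te=te, tag=tag):
                m = make_model(tag)
                m.fit(Xs[np.ix_(tr, cols)], y[tr])
                return float((m.predict(Xs[np.ix_(te, cols)]) == y[te]).mean())

            sel, best = _forward_select(pool, acc_score, max_features)
            reports[tag].val_scores.append(best)
            reports[tag].selected.append([names[j] for j in sel])

    for tag in ("svm", "xgboost"):
        sel_union = sorted(
            {names.index(f) for feats in reports[tag].selected for f in feats}
        )
        for _ in range(n_permutations):
            yp = rng.permutation(y)
            tr, te = splits[rng.integers(len(splits))]
            m = make_model(tag)
            m.fit(Xs[np.ix_(tr, sel_union)], yp[tr])
            acc = float((m.predict(Xs[np.ix_(te, sel_union)]) == yp[te]).mean())
            reports[tag].null_scores.append(acc)
    return reports


def _merge_importance_names(
    names: list[str], categories: dict[str, str]
) -> dict[str, str]:
    """Map each feature to a merged reporting name.

    Folding windows whose start positions are within 10 nt merge into one
    reported feature; sequence-motif features whose names differ by a
    single character also merge.
    """
    mapping = {n: n for n in names}
    fold = sorted(
        (int(n.split("_")[-1]), n)
        for n in names
        if categories.get(n) == "folding" and n.startswith("fold_win_")
    )
    group: list[tuple[int, str]] = []

    def flush():
        if len(group) > 1:
            rep = f"fold_win_{group[0][0]}_{group[-1][0]}"
            for _, n in group:
                mapping[n] = rep

    for pos, n in fold:
        if group and pos - group[-1][0] > 10:
            flush()
            group = []
        group.append((pos, n))
    flush()

    motif = [n for n in names if categories.get(n) == "motif_pssm"]
    used: set[str] = set()
    for i, a in enumerate(motif):
        if a in used:
            continue
        cluster = [a]
        for b in motif[i + 1 :]:
            if b in used:
                continue
            if len(a) == len(b) and sum(x != y for x, y in zip(a, b)) == 1:
                cluster.append(b)
                used.add(b)
        if len(cluster) > 1:
            for n in cluster:
                mapping[n] = cluster[0] + "_grp"
    return mapping


def feature_importance(
    report: ModelReport,
    table: FeatureTable,
    target: np.ndarray,
    top_fraction: float = 0.10,
    seed: int = 0,
    classify: bool = False,
) -> dict[str, pd.DataFrame]:
    """Three importance rankings from one model report.

    ``frequency``: how often each (merged) feature was selected across
    repeats, cut to the top ``top_fraction``; ``gain``: boosted-tree gain
    scores from a model fitted on the union of selected features;
    ``attribution``: signed mean and mean |value| of per-variant additive
    attributions (TreeSHAP) from the same model.
    """
    names = list(table.values.columns)
    mapping = _merge_importance_names(names, table.categories)
    counts: dict[str, int] = {}
    for feats in report.selected:
        for f in set(mapping[f] for f in feats):
            counts[f] = counts.get(f, 0) + 1
    freq = pd.DataFrame(
        sorted(counts.items(), key=lambda t: (-t[1], t[0])),
        columns=["feature", "times_selected"],
    )
    freq["frequency"] = freq["times_selected"] / max(len(report.selected), 1)
    n_top = max(1, int(np.ceil(top_fraction * len(freq))))
    freq["top"] = False
    freq.loc[: n_top - 1, "top"] = True

    sel_union = sorted({f for feats in report.selected for f in feats})
    if not sel_union:
        sel_union = names
    X = table.values[sel_union].to_numpy(dtype=float)
    y = np.asarray(target)
    cls = xgb.XGBClassifier if classify else xgb.XGBRegressor
    model = cls(n_estimators=100, max_depth=4, random_state=seed, n_jobs=1, verbosity=0)
    model.fit(X, y)
    booster = model.get_booster()
    booster.feature_names = sel_union
    gain = booster.get_score(importance_type="gain")
    gain_df = pd.DataFrame(
        sorted(gain.items(), key=lambda t: -t[1]), columns=["feature", "gain"]
    )
    dm = xgb.DMatrix(X, feature_names=sel_union)
    contribs = booster.predict(dm, pred_contribs=True)
    if contribs.ndim == 3:  # multiclass: average over classes
        contribs = np.abs(contribs).mean(axis=1)
        signed = contribs[:, :-1]
    else:
        signed = contribs[:, :-1]
    attr_df = pd.DataFrame(
        {
            "feature": sel_union,
            "mean_attribution": signed.mean(axis=0),
            "mean_abs_attribution": np.abs(signed).mean(axis=0),
        }
    ).sort_values("mean_abs_attribution", ascending=False, ignore_index=True)
    return {"frequency": freq, "gain": gain_df, "attribution": attr_df}


def attribution_additivity(
    table: FeatureTable, target: np.ndarray, seed: int = 0
) -> float:
    """Max |sum of per-feature attributions + baseline - prediction| over
    variants, for a boosted-tree model on the full table (should be ~0)."""
    X = table.values.to_numpy(dtype=float)
    model = xgb.XGBRegressor(n_estimators=50, max_depth=3, random_state=seed, n_jobs=1)
    model.fit(X, np.asarray(target, dtype=float))
    booster = model.get_booster()
    dm = xgb.DMatrix(X)
    contribs = booster.predict(dm, pred_contribs=True)
    pred = booster.predict(dm)
    return float(np.abs(contribs.sum(axis=1) - pred).max())


def variant_significance(
    replicates: dict[str, np.ndarray],
    control: np.ndarray,
    alpha: float = 0.05,
    n_random: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, float]:
    """Welch t-test of each variant's response values against the control's,
    with an FDR estimated from label-randomized datasets.

    FDR = (mean number significant after pooling and reshuffling all
    replicate values) / (observed number significant).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    control = np.asarray(control, dtype=float)
    rows = []
    for vid, vals in replicates.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2 or len(control) < 2:
            raise ValueError("need >= 2 replicates per group")
        if np.std(vals) == 0 and np.std(control) == 0:
            rows.append({"variant_id": vid, "t": np.nan, "p": np.nan, "flag": "zero-variance"})
            continue
        t, p = stats.ttest_ind(vals, control, equal_var=False)
        rows.append({"variant_id": vid, "t": float(t), "p": float(p), "flag": ""})
    df = pd.DataFrame(rows)
    observed = int((df["p"] <= alpha).sum())

    pool = np.concatenate([np.asarray(v, dtype=float) for v in replicates.values()] + [control])
    sizes = [len(v) for v in replicates.values()]
    n_ctrl = len(control)
    null_counts = np.zeros(n_random)
    for t_ in range(n_random):
        perm = rng.permutation(pool)
        pos = 0
        groups = []
        for s in sizes:
            groups.append(perm[pos : pos + s])
            pos += s
        ctrl = perm[pos : pos + n_ctrl]
        count = 0
        for g in groups:
            if np.std(g) == 0 and np.std(ctrl) == 0:
                continue
            _, p = stats.ttest_ind(g, ctrl, equal_var=False)
            if p <= alpha:
                count += 1
        null_counts[t_] = count
    fdr = float(null_counts.mean() / observed) if observed > 0 else float("nan")
    return df, fdr


def compute_ec200(
    dose: np.ndarray, ratio: np.ndarray, threshold: float = 2.0
) -> float | None:
    """Inducer concentration at which the response ratio first reaches the
    threshold (default 2), by linear interpolation in log(dose)-log(ratio)
    between the bracketing doses. Returns None when never reached.
    """
    dose = np.asarray(dose, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if dose.size < 2:
        raise ValueError("need at least two doses")
    if (ratio <= 0).any() or (dose <= 0).any():
        raise ValueError("doses and ratios must be positive")
    order = np.argsort(dose)
    dose, ratio = dose[order], ratio[order]
    crossings = np.nonzero(ratio >= threshold)[0]
    if crossings.size == 0:
        return None
    i = int(crossings[0])
    if (ratio[i:] < threshold).any():
        logger.warning("non-monotone dose response: using the first crossing")
    if ratio[i] == threshold:
        return float(dose[i])
    if i == 0:
        logger.warning("ratio already above threshold at the lowest dose")
        return float(dose[0])
    x1, x2 = np.log10(dose[i - 1]), np.log10(dose[i])
    y1, y2 = np.log(ratio[i - 1]), np.log(ratio[i])
    frac = (np.log(threshold) - y1) / (y2 - y1)
    return float(10 ** (x1 + frac * (x2 - x1)))
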