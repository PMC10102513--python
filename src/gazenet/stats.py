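"""Nonparametric group statistics for cohort tables.

Task effects on each network parameter are tested with Friedman
rank-sum tests over complete subject blocks, with Kendall's W
(chi2 / (N (k-1))) as effect size — read as small at 0.1, medium at
0.3, large at 0.5.  Post-hoc contrasts are Wilcoxon signed-rank tests
over the six unordered task pairs, Bonferroni-corrected (x6).

The dependence of each network parameter on the six classic
eye-movement metrics is quantified by rank-based linear regression in
the Hettmansperger–McKean framework: slopes minimize Jaeckel's rank
dispersion with Wilcoxon (linear) scores, the intercept is the median
residual, standard errors come from the Koul–Sievers–McKean
window estimate of the score scale tau, and the fit is summarized by
the robust coefficient of determination
R² = (D0 − D1)/(D0 − D1 + (n − p − 1) τ̂/2), with the plain dispersion
ratio 1 − D1/D0 reported alongside.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .events import METRIC_COLUMNS

__all__ = [
    "FriedmanResult",
    "PairwiseResult",
    "RankRegressionResult",
    "ComparisonReport",
    "kendall_w_from_chi2",
    "interpret_w",
    "friedman_kendall",
    "pairwise_wilcoxon",
    "rank_regression",
    "compare_tasks",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Friedman / Kendall


def kendall_w_from_chi2(chi2: float, n_blocks: int, k: int) -> float:
    """Kendall's W effect size from a Friedman chi-squared statistic."""
    if n_blocks < 1 or k < 2:
        raise ValueError("need n_blocks >= 1 and k >= 2")
    return chi2 / (n_blocks * (k - 1))


def interpret_w(w: float) -> str:
    if w >= 0.5:
        return "large"
    if w >= 0.3:
        return "medium"
    if w >= 0.1:
        return "small"
    return "negligible"


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    W: float
    interpretation: str
    n_blocks: int
    k: int
    p_method: str


def _friedman_chi2(blocks: np.ndarray) -> float:
    """Tie-corrected Friedman statistic from an N x k value matrix."""
    n, k = blocks.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, blocks)
    col = ranks.sum(axis=0)
    s = np.sum((col - n * (k + 1) / 2.0) ** 2)
    den = np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0
    if den == 0:  # every block constant
        return 0.0
    return float((k - 1) * s / den)


def friedman_kendall(
    blocks, p_method: str = "auto", max_exact: int = 200_000
) -> FriedmanResult:
    """Friedman test with Kendall's W on an N x k complete-block matrix.

    Within-block mid-ranks, tie-corrected statistic on k−1 degrees of
    freedom.  ``p_method``: "chi2" uses the asymptotic tail; "exact"
    enumerates all within-block rank permutations (only feasible while
    (k!)^N <= ``max_exact``); "auto" picks exact when feasible.  The
    asymptotic tail is anticonservative for very small N, which is why
    the exact null is the default there.
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2:
        raise ValueError("blocks must be a 2-D (subjects x conditions) matrix")
    n, k = blocks.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 conditions")
    if np.isnan(blocks).any():
        raise ValueError("incomplete blocks: NaN values present")
    chi2 = _friedman_chi2(blocks)
    w = kendall_w_from_chi2(chi2, n, k)
    n_perm = math.factorial(k) ** n
    if p_method == "auto":
        p_method = "exact" if n_perm <= max_exact else "chi2"
    if p_method == "exact":
        if n_perm > max_exact:
            raise ValueError(f"exact null needs {n_perm} permutations (> {max_exact})")
        ranks = np.apply_along_axis(sps.rankdata, 1, blocks)
        den = np.sum(ranks**2) - n * k * (k + 1) ** 2 / 4.0
        if den == 0:
            p = 1.0
        else:
            perms = np.array(list(itertools.permutations(range(k))))
            count = 0
            for combo in itertools.product(range(len(perms)), repeat=n):
                col = np.zeros(k)
                for b, pi in enumerate(combo):
                    col += ranks[b, perms[pi]]
                stat = (k - 1) * np.sum((col - n * (k + 1) / 2.0) ** 2) / den
                if stat >= chi2 - 1e-12:
                    count += 1
            p = count / n_perm
    elif p_method == "chi2":
        p = float(sps.chi2.sf(chi2, k - 1))
    else:
        raise ValueError(f"unknown p_method: {p_method!r}")
    return FriedmanResult(
        chi2=chi2,
        df=k - 1,
        p=p,
        W=w,
        interpretation=interpret_w(w),
        n_blocks=n,
        k=k,
        p_method=p_method,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank post hocs


@dataclass
class PairwiseResult:
    task_a: str
    task_b: str
    statistic: float  # W+ = signed-rank sum of positive differences
    z: float  # normal deviate with tie-corrected variance
    p_raw: float
    p_adj: float
    n_pairs: int  # non-zero differences


def _signed_rank(d: np.ndarray, exact_max: int = 25) -> tuple[float, float, float, int]:
    """(W+, z, two-sided p, n) for paired differences; zeros dropped."""
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 0.0, 1.0, 0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    # tie-corrected variance of W+
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return w_plus, 0.0, 1.0, n
    cc = 0.5 * np.sign(w_plus - mu)  # continuity correction
    z = (w_plus - mu - cc) / math.sqrt(var)
    has_ties = len(counts) < n
    if n <= exact_max and not has_ties:
        p = float(sps.wilcoxon(d, zero_method="wilcox", method="exact").pvalue)
    else:
        p = float(2 * sps.norm.sf(abs(z)))
    return w_plus, float(z), min(1.0, p), n


def pairwise_wilcoxon(
    cohort: pd.DataFrame,
    parameter: str,
    tasks: tuple | None = None,
    correction: str = "bonferroni",
) -> list[PairwiseResult]:
    """Wilcoxon signed-rank tests for one parameter over all task pairs.

    ``cohort`` must have columns ``subject_id``, ``task`` and the
    parameter; observations are paired within subject.  The Bonferroni
    factor is the number of unordered task pairs (6 for four tasks).
    """
    wide = cohort.pivot(index="subject_id", columns="task", values=parameter)
    tasks = tuple(tasks or wide.columns)
    pairs = list(itertools.combinations(tasks, 2))
    factor = len(pairs) if correction == "bonferroni" else 1
    out = []
    for a, b in pairs:
        sub = wide[[a, b]].dropna()
        if sub.empty:
            raise ValueError(f"no complete pairs for tasks {a}/{b}")
        w_plus, z, p, n = _signed_rank(sub[a].to_numpy() - sub[b].to_numpy())
        out.append(
            PairwiseResult(
                task_a=a,
                task_b=b,
                statistic=w_plus,
                z=z,
                p_raw=p,
                p_adj=min(1.0, factor * p),
                n_pairs=n,
            )
        )
    return out


# ---------------------------------------------------------------------------
# rank-based regression


@dataclass
class RankRegressionResult:
    predictors: list
    coef: np.ndarray  # slopes, one per predictor
    intercept: float
    t: np.ndarray
    p: np.ndarray
    R2: float  # robust coefficient of determination (see rank_regression)
    R2_dispersion: float  # plain dispersion ratio 1 - D_res/D_tot
    tau: float
    dropped: list = field(default_factory=list)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"B": self.coef, "t": self.t, "p": self.p}, index=self.predictors
        )


def _wilcoxon_scores(n: int) -> np.ndarray:
    return math.sqrt(12.0) * (np.arange(1, n + 1) / (n + 1) - 0.5)


def _dispersion(e: np.ndarray) -> float:
    """Jaeckel's rank dispersion with Wilcoxon scores (mid-ranks)."""
    n = len(e)
    r = sps.rankdata(e)
    a = math.sqrt(12.0) * (r / (n + 1) - 0.5)
    return float(np.sum(a * e))


def _tau_ksm(e: np.ndarray, p: int) -> float:
    """Koul–Sievers–McKean window estimate of the Wilcoxon score scale.

    tau = [sqrt(12) f*(0)]^{-1}, with f*(0) the density of residual
    differences at zero estimated by a uniform-kernel count at bandwidth
    h ~ sigma n^{-1/5}.
    """
    n = len(e)
    sigma = float(sps.median_abs_deviation(e, scale="normal"))
    if sigma <= 0:
        sigma = float(np.std(e))
    if sigma <= 0:
        return 1e-12  # residuals numerically zero: perfect fit
    h = 0.5 * sigma * n ** (-1 / 5)
    diffs = np.abs(e[:, None] - e[None, :])[np.triu_indices(n, 1)]
    dens = np.sum(diffs <= h) / (len(diffs) * 2 * h)
    if dens <= 0:
        return float("inf")
    tau = 1.0 / (math.sqrt(12.0) * dens)
    # small-sample df correction, as in the Hettmansperger–McKean framework
    return tau * math.sqrt(n / max(n - p - 1, 1))


def rank_regression(
    y,
    X,
    predictors: list | None = None,
    on_collinear: str = "error",
) -> RankRegressionResult:
    """Rank-based linear fit of y on the columns of X.

    Slopes minimize the Jaeckel dispersion of residuals under Wilcoxon
    scores (robust to outliers and heavy tails); the intercept is the
    median of the slope-fit residuals.  t statistics use the KSM tau
    estimate.  The headline determination coefficient is the robust R²
    reported by rank-regression software,
    R² = (D0 − D1) / (D0 − D1 + (n − p − 1) τ̂ / 2),
    the dispersion analogue of SSR/(SSR+SSE); the plain dispersion
    ratio 1 − D1/D0 is also returned.  Both are clipped to [0, 1].

    ``on_collinear``: "error" raises naming the aliased columns;
    "drop" removes them (recorded in ``dropped``) and fits the rest.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    predictors = list(predictors) if predictors is not None else [f"x{j + 1}" for j in range(p)]
    if len(y) != n:
        raise ValueError("y and X lengths differ")

    # detect aliased (collinear after centering) columns via pivoted QR
    Xc = X - X.mean(axis=0)
    dropped: list = []
    keep = list(range(p))
    from scipy.linalg import qr

    _, r, piv = qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(n, p) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    bad = [piv[j] for j in range(len(diag)) if diag[j] <= tol] + list(piv[len(diag):])
    if bad:
        names = [predictors[j] for j in sorted(bad)]
        if on_collinear == "error":
            raise ValueError(f"collinear predictors: {names}")
        if on_collinear != "drop":
            raise ValueError(f"unknown on_collinear: {on_collinear!r}")
        dropped = names
        keep = [j for j in range(p) if j not in set(bad)]
        X = X[:, keep]
        Xc = Xc[:, keep]
        predictors = [predictors[j] for j in keep]
        p = X.shape[1]
    if n <= p + 1:
        raise ValueError("need n > number of predictors + 1")

    beta0, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)

    def objective(b):
        return _dispersion(y - X @ b)

    def gradient(b):
        e = y - X @ b
        r = sps.rankdata(e)
        a = math.sqrt(12.0) * (r / (n + 1) - 0.5)
        return -X.T @ a

    res = optimize.minimize(objective, beta0, jac=gradient, method="BFGS")
    res2 = optimize.minimize(objective, res.x, method="Powell")
    beta = res2.x if res2.fun <= res.fun else res.x
    e = y - X @ beta
    intercept = float(np.median(e))
    resid = e - intercept

    d_res = _dispersion(e)
    d_tot = _dispersion(y)
    r2_disp = 1.0 if d_tot <= 0 else float(np.clip(1.0 - d_res / d_tot, 0.0, 1.0))

    tau = _tau_ksm(resid, p)
    reduction = max(d_tot - d_res, 0.0)
    denom = reduction + max(n - p - 1, 1) * tau / 2.0
    r2 = 1.0 if denom <= 0 else float(np.clip(reduction / denom, 0.0, 1.0))
    xtx_inv = np.linalg.pinv(Xc.T @ Xc)
    se = tau * np.sqrt(np.clip(np.diag(xtx_inv), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * sps.t.sf(np.abs(t), df=max(n - p - 1, 1))
    return RankRegressionResult(
        predictors=predictors,
        coef=beta,
        intercept=intercept,
        t=t,
        p=pvals,
        R2=r2,
        R2_dispersion=r2_disp,
        tau=tau,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# cohort-level report


@dataclass
class ComparisonReport:
    """Per-parameter task comparison plus metric regressions."""

    friedman: dict  # parameter -> FriedmanResult
    pairwise: dict  # parameter -> list[PairwiseResult]
    regressions: dict  # (parameter, task) -> RankRegressionResult
    screening: pd.DataFrame  # normality / variance-homogeneity record
    tasks: tuple
    n_subjects: int
    regression_errors: dict = field(default_factory=dict)  # (parameter, task) -> str

    def to_json(self, path=None) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if hasattr(o, "__dict__"):
                return o.__dict__
            raise TypeError(type(o))

        payload = {
            "tasks": list(self.tasks),
            "n_subjects": self.n_subjects,
            "friedman": {k: v.__dict__ for k, v in self.friedman.items()},
            "pairwise": {
                k: [r.__dict__ for r in v] for k, v in self.pairwise.items()
            },
            "regressions": {
                f"{par}|{task}": {
                    "predictors": r.predictors,
                    "B": r.coef.tolist(),
                    "t": r.t.tolist(),
                    "p": r.p.tolist(),
                    "intercept": r.intercept,
                    "R2": r.R2,
                    "dropped": r.dropped,
                }
                for (par, task), r in self.regressions.items()
            },
            "screening": self.screening.to_dict(orient="records"),
            "regression_errors": {
                f"{par}|{task}": msg for (par, task), msg in self.regression_errors.items()
            },
        }
        text = json.dumps(payload, indent=2, default=enc, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def regression_table(self) -> pd.DataFrame:
        """Task x parameter matrix of predictor t-values with an R² column."""
        rows = []
        for (par, task), r in self.regressions.items():
            row = {"task": task, "parameter": par}
            row.update({f"t_{name}": tv for name, tv in zip(r.predictors, r.t)})
            row["R2"] = r.R2
            rows.append(row)
        return pd.DataFrame(rows)

    def friedman_table(self) -> pd.DataFrame:
        """Parameter x statistic summary (chi2, p, W) with task means."""
        rows = []
        for par, fr in self.friedman.items():
            rows.append(
                {
                    "parameter": par,
                    "chi2": fr.chi2,
                    "df": fr.df,
                    "p": fr.p,
                    "W": fr.W,
                    "effect": fr.interpretation,
                }
            )
        return pd.DataFrame(rows)


def _screening(cohort: pd.DataFrame, parameters, tasks) -> pd.DataFrame:
    """Shapiro–Wilk per parameter x task and Levene across tasks.

    Recorded for the report; the nonparametric workflow runs regardless.
    """
    rows = []
    for par in parameters:
        groups = [
            cohort.loc[cohort["task"] == t, par].dropna().to_numpy() for t in tasks
        ]
        for t, g in zip(tasks, groups):
            sw_p = float(sps.shapiro(g).pvalue) if 3 <= len(g) <= 5000 and np.ptp(g) > 0 else float("nan")
            rows.append({"parameter": par, "task": t, "test": "shapiro", "p": sw_p})
        if all(len(g) >= 2 for g in groups) and len(groups) >= 2:
            lev_p = float(sps.levene(*groups).pvalue)
        else:
            lev_p = float("nan")
        rows.append({"parameter": par, "task": "all", "test": "levene", "p": lev_p})
    return pd.DataFrame(rows)


def compare_tasks(
    cohort: pd.DataFrame,
    parameters: tuple | None = None,
    metric_columns: tuple = METRIC_COLUMNS,
) -> ComparisonReport:
    """Full statistical comparison of tasks over a cohort table.

    ``cohort`` holds one row per (subject, task) with network parameters
    and the classic metrics as columns.  Every subject must have every
    task (complete blocks).  Regressions of each parameter on the six
    metrics are fitted per task with aliased metric columns dropped (in
    this pipeline saccade counts are fixation counts minus one, which is
    exactly aliased with the intercept present).
    """
    from .topology import TopologyProfile

    if parameters is None:
        # skip parameters never computed for this run (all-NaN columns,
        # e.g. small-worldness when null models were turned off)
        parameters = tuple(
            p
            for p in TopologyProfile.PARAMETERS
            if p in cohort.columns and cohort[p].notna().any()
        )
    if cohort.duplicated(["subject_id", "task"]).any():
        raise ValueError("duplicated (subject, task) keys")
    tasks = tuple(pd.unique(cohort["task"]))
    n_subjects = cohort["subject_id"].nunique()

    friedman: dict = {}
    pairwise: dict = {}
    regressions: dict = {}
    regression_errors: dict = {}
    for par in parameters:
        wide = cohort.pivot(index="subject_id", columns="task", values=par)[list(tasks)]
        if wide.isna().any().any():
            missing = wide[wide.isna().any(axis=1)].index.tolist()
            raise ValueError(
                f"incomplete blocks for parameter {par!r}: subjects {missing} "
                "lack at least one task"
            )
        friedman[par] = friedman_kendall(wide.to_numpy())
        if len(tasks) > 2:
            pairwise[par] = pairwise_wilcoxon(cohort, par, tasks=tasks)
        for task in tasks:
            sub = cohort[cohort["task"] == task]
            avail = [c for c in metric_columns if c in sub.columns]
            X = sub[avail].to_numpy(dtype=float)
            ok = ~np.isnan(X).any(axis=1) & ~np.isnan(sub[par].to_numpy(dtype=float))
            try:
                regressions[(par, task)] = rank_regression(
                    sub[par].to_numpy(dtype=float)[ok],
                    X[ok],
                    predictors=avail,
                    on_collinear="drop",
                )
            except ValueError as exc:  # e.g. cohort too small for 6 predictors
                regression_errors[(par, task)] = str(exc)
    screening = _screening(cohort, parameters, tasks)
    return ComparisonReport(
        friedman=friedman,
        pairwise=pairwise,
        regressions=regressions,
        screening=screening,
        tasks=tasks,
        n_subjects=n_subjects,
        regression_errors=regression_errors,
    )
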