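"""Cohort-level statistics: PCA of clinical intervention variables, single-
mediator path models with bootstrap indirect effects, Benjamini-Hochberg
correction, group comparisons and reading regressions.

The mediation model is the saturated linear path system

    m = a x + e1
    y = b m + c' x + e2,

for which maximum likelihood coincides with OLS; the indirect effect a*b is
tested with a percentile bootstrap over subjects, and total = direct +
indirect holds as an algebraic identity of the fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate import factor_rotation
from statsmodels.stats.multitest import multipletests

from .synthetic import CLINICAL_VARIABLES, SUBTESTS

__all__ = [
    "PCAResult",
    "MediationResult",
    "run_pca",
    "fit_mediation",
    "bh_adjust",
    "run_mediation_battery",
    "compare_groups",
    "fit_reading_regression",
]


@dataclass
class PCAResult:
    """Retained components of the clinical-variable PCA.

    ``loadings`` is the oblique (promax) pattern matrix; ``scores`` are the
    unrotated component scores (mutually uncorrelated); eigenvalue > 1 decides
    retention.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_explained: np.ndarray  # percent, per retained component
    eigenvalues: np.ndarray  # all eigenvalues, descending
    n_retained: int
    dropped_variables: list = field(default_factory=list)


@dataclass
class MediationResult:
    predictor: str
    mediator: str
    outcome: str
    a: float
    b: float
    direct: float
    total: float
    indirect: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_bh: float = np.nan
    n: int = 0


def run_pca(
    clinical: pd.DataFrame,
    rotation: str = "promax",
    variables=CLINICAL_VARIABLES,
    eigenvalue_cutoff: float = 1.0,
) -> PCAResult:
    """PCA of the standardized clinical variables (CI group only).

    Eigen-decomposition of the correlation matrix; components with eigenvalue
    above ``eigenvalue_cutoff`` are retained; the pattern matrix comes from an
    oblique promax rotation (power 4) of the retained loadings.  Constant
    variables are dropped with a warning; a rank-deficient correlation matrix
    raises.
    """
    data = clinical
    if "group" in clinical.columns:
        data = clinical[clinical["group"] == "CI"]
    X = data[list(variables)].astype(float)
    dropped = [v for v in X.columns if X[v].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant variables: {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    if X.isna().any().any():
        X = X.dropna()
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need at least two more subjects than variables")
    Z = (X - X.mean()) / X.std(ddof=1)
    corr = np.asarray(Z.corr())
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if eigvals[-1] < 1e-10:
        raise np.linalg.LinAlgError("correlation matrix is rank deficient")
    n_retained = int(np.sum(eigvals > eigenvalue_cutoff))
    if n_retained == 0:
        raise ValueError("no component has eigenvalue above the cutoff")

    raw_loadings = eigvecs[:, :n_retained] * np.sqrt(eigvals[:n_retained])
    if rotation == "promax":
        pattern, _ = factor_rotation.promax(raw_loadings, k=4)
    elif rotation == "varimax":
        pattern, _ = factor_rotation.rotate_factors(raw_loadings, "varimax")
    elif rotation in (None, "none"):
        pattern = raw_loadings
    else:
        raise ValueError(f"unknown rotation {rotation!r}")

    comp_names = [f"PC{i + 1}" for i in range(n_retained)]
    scores = np.asarray(Z) @ eigvecs[:, :n_retained]
    return PCAResult(
        loadings=pd.DataFrame(pattern, index=X.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        variance_explained=100.0 * eigvals[:n_retained] / eigvals.sum(),
        eigenvalues=eigvals,
        n_retained=n_retained,
        dropped_variables=dropped,
    )


def _path_coefficients(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Closed-form OLS paths for centered (optionally batched) samples.

    Accepts 1-D arrays or 2-D (n_boot, n) batches; returns (a, b, cprime)."""
    xc = x - x.mean(axis=-1, keepdims=True)
    mc = m - m.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    sxx = (xc * xc).sum(axis=-1)
    smm = (mc * mc).sum(axis=-1)
    sxm = (xc * mc).sum(axis=-1)
    sxy = (xc * yc).sum(axis=-1)
    smy = (mc * yc).sum(axis=-1)
    a = sxm / sxx
    det = smm * sxx - sxm**2
    b = (smy * sxx - sxy * sxm) / det
    cprime = (sxy * smm - smy * sxm) / det
    return a, b, cprime


def fit_mediation(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    n_boot: int = 5000,
    seed: int = 0,
    predictor: str = "x",
    mediator: str = "m",
    outcome: str = "y",
) -> MediationResult:
    """Single-mediator linear path model with percentile-bootstrap inference.

    Complete cases only; the two-sided p-value comes from the sign balance of
    the bootstrap distribution of a*b.  Raises on a zero-variance mediator or
    predictor.
    """
    x, m, y = (np.asarray(v, dtype=float) for v in (x, m, y))
    keep = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    x, m, y = x[keep], m[keep], y[keep]
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 complete cases")
    if np.var(m) == 0 or np.var(x) == 0:
        raise ValueError("zero-variance mediator or predictor")

    a, b, cprime = _path_coefficients(x, m, y)
    total = float(np.polyfit(x - x.mean(), y - y.mean(), 1)[0])
    indirect = float(a * b)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    ab_boot = None
    if n_boot > 0:
        xa, ma, ya = x[idx], m[idx], y[idx]
        a_b, b_b, _ = _path_coefficients(xa, ma, ya)
        ab_boot = a_b * b_b
        ab_boot = ab_boot[np.isfinite(ab_boot)]
    if ab_boot is not None and ab_boot.size:
        ci_low, ci_high = np.percentile(ab_boot, [2.5, 97.5])
        n_le = np.sum(ab_boot <= 0) + 1
        n_ge = np.sum(ab_boot >= 0) + 1
        p_raw = min(1.0, 2.0 * min(n_le, n_ge) / (ab_boot.size + 1))
    else:
        ci_low = ci_high = np.nan
        p_raw = np.nan

    return MediationResult(
        predictor=predictor,
        mediator=mediator,
        outcome=outcome,
        a=float(a),
        b=float(b),
        direct=float(cprime),
        total=total,
        indirect=indirect,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_raw=float(p_raw),
        n=int(n),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def run_mediation_battery(
    pca_scores: pd.DataFrame,
    connectivity: pd.DataFrame,
    reading: pd.DataFrame,
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    standardize: bool = True,
) -> pd.DataFrame:
    """One mediation per (retained PC x connection x subtest), BH within PC.

    Subjects are aligned on the index; a mismatch raises.  For 7 ROIs and 6
    subtests each PC contributes 252 tests; BH correction is applied within
    each PC's family.  Variables are z-scored by default so indirect effects
    are reported in standardized units.
    """
    subtests = [s for s in SUBTESTS if s in reading.columns]
    if not pca_scores.index.equals(connectivity.loc[pca_scores.index].index):
        raise KeyError("subject ids do not align between PCA scores and connectivity")
    missing = pca_scores.index.difference(reading.index)
    if len(missing):
        raise KeyError(f"subjects missing from reading table: {list(missing)[:5]}")
    conn = connectivity.loc[pca_scores.index]
    read = reading.loc[pca_scores.index]

    def z(v):
        v = np.asarray(v, dtype=float)
        sd = v.std(ddof=1)
        return (v - v.mean()) / sd if sd > 0 else v

    rows = []
    rng = np.random.default_rng(seed)
    for pc in pca_scores.columns:
        x = pca_scores[pc].to_numpy(dtype=float)
        xz = z(x) if standardize else x
        family = []
        for conn_name in conn.columns:
            mvals = conn[conn_name].to_numpy(dtype=float)
            mz = z(mvals) if standardize else mvals
            for subtest in subtests:
                yvals = read[subtest].to_numpy(dtype=float)
                yz = z(yvals) if standardize else yvals
                res = fit_mediation(
                    xz,
                    mz,
                    yz,
                    n_boot=n_boot,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    predictor=pc,
                    mediator=conn_name,
                    outcome=subtest,
                )
                family.append(res)
        p_adj = bh_adjust([r.p_raw for r in family])
        for r, p in zip(family, p_adj):
            r.p_bh = float(p)
            rows.append(r.__dict__ | {"significant": bool(p < alpha)})
    return pd.DataFrame(rows)


def compare_groups(reading: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Welch's t and Mann-Whitney U per subtest between the two groups."""
    groups = reading[group_col].unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    g1, g2 = sorted(groups)
    rows = []
    for subtest in [s for s in SUBTESTS if s in reading.columns]:
        x = reading.loc[reading[group_col] == g1, subtest].dropna().to_numpy()
        y = reading.loc[reading[group_col] == g2, subtest].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            raise ValueError("each group needs at least 2 subjects")
        t_res = stats.ttest_ind(x, y, equal_var=False)
        u_res = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append(
            {
                "subtest": subtest,
                "group_a": g1,
                "group_b": g2,
                "welch_t": float(t_res.statistic),
                "welch_df": float(t_res.df),
                "welch_p": float(t_res.pvalue),
                "mannwhitney_u": float(u_res.statistic),
                "mannwhitney_p": float(u_res.pvalue),
                "mean_a": float(x.mean()),
                "mean_b": float(y.mean()),
            }
        )
    return pd.DataFrame(rows)


def fit_reading_regression(
    reading: pd.DataFrame,
    predictors: pd.DataFrame,
    subtests=None,
) -> pd.DataFrame:
    """OLS of each subtest on the given predictors; R^2, overall F, slopes.

    ``predictors`` is a subject x predictor DataFrame aligned on the reading
    index.  Raises on collinear designs (condition number > 1e10).
    """
    import statsmodels.api as sm

    subtests = [s for s in SUBTESTS if s in reading.columns] if subtests is None else subtests
    X = predictors.loc[reading.index].astype(float)
    design = sm.add_constant(X)
    if np.linalg.cond(np.asarray(design)) > 1e10:
        raise np.linalg.LinAlgError("collinear predictors (condition number > 1e10)")
    rows = []
    for subtest in subtests:
        y = reading[subtest].astype(float)
        fit = sm.OLS(y, design).fit()
        row = {
            "subtest": subtest,
            "r_squared": float(fit.rsquared),
            "f_stat": float(fit.fvalue),
            "df_model": int(fit.df_model),
            "df_resid": int(fit.df_resid),
            "p_value": float(fit.f_pvalue),
            "intercept": float(fit.params.iloc[0]),
        }
        for name in X.columns:
            row[f"slope_{name}"] = float(fit.params[name])
        rows.append(row)
    return pd.DataFrame(rows)
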