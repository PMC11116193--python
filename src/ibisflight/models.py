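"""Regression models for the campaign summaries, fitted from first principles.

Two models are implemented:

* an ordinary least-squares model with treatment-coded factors and a
  two-way interaction, for the per-session gliding proportion
  (``gliding ~ shape * angle + bird``), fitted by the closed-form normal
  equations with classical standard errors;
* a random-intercept linear mixed model for log10 daily flight distance
  (``log10(km) ~ attachment * activity + (1 | bird)``), fitted by REML.
  The REML criterion is profiled down to a single parameter — the
  variance ratio lambda = sigma_b^2 / sigma_e^2 — by solving the GLS
  problem in closed form at each candidate lambda (the single-intercept
  structure makes V^-1 available analytically per group), and the 1-D
  profile is minimized by bounded scalar search including the lambda = 0
  boundary.

t statistics are reported against the residual degrees of freedom; for
the mixed model this is a simplification of Satterthwaite-type df and is
anticonservative for between-group contrasts when the number of groups is
small (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class ModelFit:
    """Coefficients and inference from an OLS or random-intercept REML fit."""

    terms: list
    estimates: np.ndarray
    se: np.ndarray
    df_resid: int
    sigma2: float                       # residual variance
    r2: float | None = None             # OLS only
    fstat: tuple | None = None          # (F, df1, df2), OLS only
    group_var: float | None = None      # LMM: random-intercept variance
    reml: float | None = None           # LMM: -2 * restricted log-likelihood
    converged: bool = True
    n_obs: int = 0
    note: str = ""

    @property
    def tvalues(self) -> np.ndarray:
        return self.estimates / self.se

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        from scipy import stats
        crit = stats.t.ppf(0.5 + level / 2, self.df_resid)
        half = crit * self.se
        return np.column_stack([self.estimates - half, self.estimates + half])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "estimate": self.estimates,
            "se": self.se,
            "t_value": self.tvalues,
        })


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(table: pd.DataFrame,
                 response: str,
                 factors: dict[str, str],
                 interactions: list[tuple[str, str]] = ()):
    """Treatment-coded design matrix with intercept.

    ``factors`` maps column name -> reference level; every other level of
    that column gets a dummy column named ``col[level]``.  Interactions
    are elementwise products of the two factors' dummy columns.

    Returns ``(X, y, names)``; raises on missing responses, levels absent
    from the data, or a rank-deficient design.
    """
    y = table[response].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite responses")

    cols = [np.ones(len(table))]
    names = ["Intercept"]
    dummies: dict[str, dict[str, np.ndarray]] = {}
    for col, ref in factors.items():
        levels = sorted(map(str, table[col].astype(str).unique()))
        if str(ref) not in levels:
            raise ValueError(f"reference level {ref!r} absent from {col!r}")
        dummies[col] = {}
        for lev in levels:
            if lev == str(ref):
                continue
            d = (table[col].astype(str) == lev).to_numpy(dtype=float)
            dummies[col][lev] = d
            cols.append(d)
            names.append(f"{col}[{lev}]")
    for a, b in interactions:
        for la, da in dummies[a].items():
            for lb, db in dummies[b].items():
                cols.append(da * db)
                names.append(f"{a}[{la}]:{b}[{lb}]")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return X, y, names


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

def fit_ols(X: np.ndarray, y: np.ndarray, names: list | None = None) -> ModelFit:
    """Closed-form least squares with classical standard errors.

    beta = (X'X)^-1 X'y (via a QR solve), sigma^2 = RSS / (n - p),
    cov(beta) = sigma^2 (X'X)^-1.  Reports R^2 and the overall F test
    against the intercept-only model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than parameters")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - p
    sigma2 = rss / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))

    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    df_model = p - 1
    if df_model > 0 and rss > 0:
        f = ((tss - rss) / df_model) / sigma2
    else:
        f = np.inf
    return ModelFit(terms=list(names) if names is not None else
                    [f"x{i}" for i in range(p)],
                    estimates=beta, se=se, df_resid=df_resid, sigma2=sigma2,
                    r2=r2, fstat=(f, df_model, df_resid), n_obs=n)


# ---------------------------------------------------------------------------
# random-intercept LMM by profiled REML
# ---------------------------------------------------------------------------

def _group_blocks(groups: np.ndarray):
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    idx = [np.flatnonzero(inv == g) for g in range(len(labels))]
    return labels, idx


def _reml_pieces(X, y, idx, lam):
    """Profiled-REML ingredients at variance ratio lam = sigma_b^2/sigma_e^2.

    With V = I + lam * sum_i 1_i 1_i', the Woodbury identity gives
    V_i^-1 = I - (lam / (1 + lam n_i)) J_i per group, so all quadratic
    forms reduce to group sums.
    """
    XtVX = X.T @ X
    XtVy = X.T @ y
    ytVy = float(y @ y)
    logdetV = 0.0
    for rows in idx:
        ni = len(rows)
        c = lam / (1.0 + lam * ni)
        sx = X[rows].sum(axis=0)
        sy = float(y[rows].sum())
        XtVX = XtVX - c * np.outer(sx, sx)
        XtVy = XtVy - c * sx * sy
        ytVy -= c * sy * sy
        logdetV += np.log1p(lam * ni)
    beta = np.linalg.solve(XtVX, XtVy)
    quad = ytVy - float(XtVy @ beta)          # r' V^-1 r
    return beta, XtVX, max(quad, 1e-300), logdetV


def _reml_criterion(X, y, idx, lam):
    n, p = X.shape
    _, XtVX, quad, logdetV = _reml_pieces(X, y, idx, lam)
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    sigma2 = quad / (n - p)
    # -2 * restricted log-likelihood, dropping additive constants
    return (n - p) * np.log(sigma2) + logdetV + logdetXtVX


def fit_lmm_random_intercept(X: np.ndarray, y: np.ndarray,
                             groups: np.ndarray,
                             names: list | None = None,
                             lam_max: float = 1e4) -> ModelFit:
    """REML fit of y = X beta + b_group + e with a single random intercept.

    The variance ratio lambda is profiled out and minimized by bounded
    Brent search on log(lambda), with the lambda = 0 boundary checked
    explicitly so the fit degenerates cleanly to OLS when the data carry
    no between-group variance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than parameters")
    labels, idx = _group_blocks(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")

    crit = lambda loglam: _reml_criterion(X, y, idx, np.exp(loglam))
    res = optimize.minimize_scalar(crit, bounds=(np.log(1e-10), np.log(lam_max)),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    lam_hat = float(np.exp(res.x))
    c_opt = float(res.fun)
    c_zero = _reml_criterion(X, y, idx, 0.0)
    note = ""
    if c_zero <= c_opt:
        lam_hat, c_opt = 0.0, c_zero
        note = "random-intercept variance estimated at the zero boundary"
    if not res.success and lam_hat > 0:
        note = (note + "; " if note else "") + "scalar search did not report success"

    beta, XtVX, quad, _ = _reml_pieces(X, y, idx, lam_hat)
    sigma2 = quad / (n - p)
    cov = np.linalg.inv(XtVX) * sigma2
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return ModelFit(terms=list(names) if names is not None else
                    [f"x{i}" for i in range(p)],
                    estimates=beta, se=se, df_resid=n - p, sigma2=sigma2,
                    group_var=lam_hat * sigma2, reml=c_opt,
                    converged=bool(res.success or lam_hat == 0.0),
                    n_obs=n, note=note)


def reml_criterion_at(X, y, groups, lam: float) -> float:
    """The profiled -2 restricted log-likelihood at a given variance ratio.

    Exposed so the optimality of a fit can be spot-checked against
    arbitrary candidate ratios.
    """
    _, idx = _group_blocks(groups)
    return _reml_criterion(np.asarray(X, dtype=float),
                           np.asarray(y, dtype=float), idx, lam)


# ---------------------------------------------------------------------------
# response preparation for the distance model
# ---------------------------------------------------------------------------

def log10_transform(daily: pd.DataFrame):
    """Build the distance-model table: log10(km) with attachment & activity.

    Daily flight distances are strongly right-skewed, so the model works
    on log10 kilometres.  Zero-distance days cannot be log-transformed and
    are excluded; the count of exclusions is returned alongside.

    Returns ``(table, n_excluded)`` where table has columns
    ``log10_km, attachment, activity, bird``.
    """
    d = daily.copy()
    zero = d["path_km"] <= 0
    n_excluded = int(zero.sum())
    d = d[~zero]
    out = pd.DataFrame({
        "log10_km": np.log10(d["path_km"].to_numpy(dtype=float)),
        "attachment": d["attachment"].to_numpy(),
        "activity": d["day_type"].to_numpy(),
        "bird": d["bird"].to_numpy(),
    })
    return out, n_excluded


GLIDING_PRESET = dict(
    response="gliding_proportion",
    factors={"logger_shape": "cube", "wind_angle": "+2", "bird": "310"},
    interactions=[("logger_shape", "wind_angle")],
)

DISTANCE_PRESET = dict(
    response="log10_km",
    factors={"attachment": "wing_loop", "activity": "stopover"},
    interactions=[("attachment", "activity")],
)
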