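"""Group-level statistics: repeated-measures mixed models, FDR, and
minimal-detectable-effect power analysis.

Model
-----
For each outcome (a graph metric at one cost level, global or nodal),

    value ~ group + phase + group:phase + covariates

with the within-subject dependence between the two menstrual-cycle
occasions (MENS, POV) modeled by a saturated ("unstructured") 2x2
covariance: occasion-specific variances plus a free within-subject
covariance, estimated by REML. Covariates (three hormones, four
psychological scores) are mean-centered before fitting; subjects missing
a phase are dropped.

Fixed effects are tested by Wald t statistics with model-based standard
errors and ``n_subjects - n_fixed_effects`` degrees of freedom (logged on
the result).

Power
-----
``mde_independent`` / ``mde_paired`` solve, via the noncentral t
distribution, for the smallest standardized effect size detectable with a
given power in two-sided two-sample or paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CostGrid

DEFAULT_COVARIATES = (
    "estradiol",
    "progesterone",
    "testosterone",
    "state_anxiety",
    "trait_anxiety",
    "beck_anxiety",
    "beck_depression",
)

PHASE_ORDER = ("MENS", "POV")


# ------------------------------------------------------------- mixed model

@dataclass
class MixedModelResult:
    """Fixed-effect estimates of one outcome's mixed-model fit."""

    outcome: str
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    tvalues: dict[str, float]
    df: float
    covariance: dict[str, float]  # sd_MENS, sd_POV, cov
    converged: bool
    n_subjects: int
    structure: str = "unstructured-2x2 (REML)"
    df_method: str = "n_subjects - n_fixed_effects"


def _build_design(
    df: pd.DataFrame,
    covariates: Sequence[str],
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Design matrix with treatment-coded group/phase, their interaction,
    and mean-centered covariates; returns (X, names, y, phase_index)."""
    groups = np.sort(df["group"].unique())
    if groups.size != 2:
        raise ValueError(f"exactly two groups required, got {list(groups)}")
    g = (df["group"].to_numpy() == groups[1]).astype(float)
    ph = (df["phase"].to_numpy() == PHASE_ORDER[1]).astype(float)
    cols = [np.ones(len(df)), g, ph, g * ph]
    names = ["intercept", f"group[{groups[1]}]", f"phase[{PHASE_ORDER[1]}]", "group:phase"]
    for c in covariates:
        v = df[c].to_numpy(dtype=float)
        cols.append(v - v.mean())
        names.append(c)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular design matrix (collinear fixed effects)")
    return x, names, df["value"].to_numpy(dtype=float), ph.astype(int)


def _sigma_of(theta: np.ndarray) -> np.ndarray:
    """Map unconstrained (log sd1, log sd2, atanh rho) to the 2x2
    within-subject covariance."""
    s1, s2 = np.exp(theta[0]), np.exp(theta[1])
    rho = np.tanh(theta[2])
    cov = rho * s1 * s2
    return np.array([[s1 * s1, cov], [cov, s2 * s2]])


def _gls_pieces(
    sigma: np.ndarray, x3: np.ndarray, y2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X'V^-1 X, X'V^-1 y, beta_hat) over uniform 2x2 subject blocks.

    ``x3`` is (subjects, 2, p) with the MENS row first, ``y2`` (subjects, 2).
    """
    vinv = np.linalg.inv(sigma)
    xtvx = np.einsum("sip,ij,sjq->pq", x3, vinv, x3)
    xtvy = np.einsum("sip,ij,sj->p", x3, vinv, y2)
    beta = np.linalg.solve(xtvx, xtvy)
    return xtvx, xtvy, beta


def _reml_neg_loglik(theta: np.ndarray, x3: np.ndarray, y2: np.ndarray) -> float:
    sigma = _sigma_of(theta)
    sign, ld = np.linalg.slogdet(sigma)
    if sign <= 0 or not np.all(np.isfinite(sigma)):
        return np.inf
    try:
        xtvx, _, beta = _gls_pieces(sigma, x3, y2)
    except np.linalg.LinAlgError:
        return np.inf
    sign_x, ld_x = np.linalg.slogdet(xtvx)
    if sign_x <= 0:
        return np.inf
    r = y2 - np.einsum("sip,p->si", x3, beta)
    vinv = np.linalg.inv(sigma)
    quad = np.einsum("si,ij,sj->", r, vinv, r)
    n_subj = x3.shape[0]
    return 0.5 * (n_subj * ld + ld_x + quad)


def fit_mixed_model(
    table: pd.DataFrame,
    outcome: str = "outcome",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> MixedModelResult:
    """REML fit of one outcome with the saturated two-occasion covariance.

    ``table`` needs columns subject_id, group, phase, value, plus the
    covariate columns. Subjects without both phases are dropped.
    """
    df = table.copy()
    counts = df.groupby("subject_id")["phase"].nunique()
    keep = counts[counts == 2].index
    df = df[df["subject_id"].isin(keep)]
    n_subj = keep.size
    if n_subj < 4:
        raise ValueError("need at least 2 complete subjects per group")
    covariates = [c for c in covariates if c in df.columns]
    x, names, y, ph = _build_design(df, covariates)

    sid = df["subject_id"].to_numpy()
    x3 = np.empty((n_subj, 2, x.shape[1]))
    y2 = np.empty((n_subj, 2))
    for s_idx, s in enumerate(keep):
        idx = np.nonzero(sid == s)[0]
        idx = idx[np.argsort(ph[idx])]  # MENS row first
        x3[s_idx] = x[idx]
        y2[s_idx] = y[idx]

    resid_var = max(np.var(y), 1e-12)
    theta0 = np.array([0.5 * np.log(resid_var), 0.5 * np.log(resid_var), 0.0])
    res = scipy.optimize.minimize(
        _reml_neg_loglik,
        theta0,
        args=(x3, y2),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-9, "maxiter": 1000},
    )
    converged = bool(res.success) and np.isfinite(res.fun)
    theta = res.x if converged else theta0

    sigma = _sigma_of(theta)
    s1, s2 = np.sqrt(sigma[0, 0]), np.sqrt(sigma[1, 1])
    rho = sigma[0, 1] / (s1 * s2) if s1 > 0 and s2 > 0 else 0.0
    xtvx, xtvy, beta = _gls_pieces(sigma, x3, y2)
    cov_beta = np.linalg.inv(xtvx)
    se = np.sqrt(np.diag(cov_beta))
    df_resid = float(n_subj - len(names))
    if df_resid < 1:
        raise ValueError("more fixed effects than subjects")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2 * scipy.stats.t.sf(np.abs(t), df_resid)
    return MixedModelResult(
        outcome=outcome,
        params=dict(zip(names, beta.tolist())),
        bse=dict(zip(names, se.tolist())),
        pvalues=dict(zip(names, p.tolist())),
        tvalues=dict(zip(names, t.tolist())),
        df=df_resid,
        covariance={"sd_MENS": float(s1), "sd_POV": float(s2), "cov": float(rho * s1 * s2)},
        converged=converged,
        n_subjects=int(n_subj),
    )


# --------------------------------------------------------------------- FDR

def fdr_bh(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over a family of p-values.

    Returns (reject, p_adjusted). Applied across nodes within one cost
    level in the nodewise analysis; cost levels are not corrected.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ------------------------------------------------------------------- power

@dataclass
class PowerSpec:
    """Design of a minimal-detectable-effect computation."""

    design: Literal["independent", "paired"]
    n1: int
    n2: int | None = None
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.design == "independent":
            if self.n2 is None:
                raise ValueError("independent design needs n2")
            if self.n1 < 2 or self.n2 < 2:
                raise ValueError("need at least 2 per group")
        elif self.n1 < 2:
            raise ValueError("need at least 2 pairs")


def _round_half_up(x: float, decimals: int) -> float:
    factor = 10.0**decimals
    return float(np.floor(x * factor + 0.5) / factor)


def _power_two_sided_t(nc: float, df: float, alpha: float) -> float:
    """Power of a two-sided t-test at noncentrality nc."""
    tcrit = scipy.stats.t.ppf(1 - alpha / 2, df)
    upper = scipy.stats.nct.sf(tcrit, df, nc)
    lower = scipy.stats.nct.cdf(-tcrit, df, nc)
    # the opposite-tail term underflows to NaN at large noncentrality
    if not np.isfinite(lower):
        lower = 0.0
    if not np.isfinite(upper):
        upper = 1.0
    return float(upper + lower)


def _solve_mde(nc_of_d, df: float, alpha: float, power: float) -> float:
    lo, hi = 1e-9, 10.0
    f = lambda d: _power_two_sided_t(nc_of_d(d), df, alpha) - power
    while f(hi) < 0:
        hi *= 2
        if hi > 1e4:
            raise ValueError("power target unreachable")
    return float(scipy.optimize.brentq(f, lo, hi, xtol=1e-10))


def mde_independent(spec: PowerSpec, decimals: int | None = 2) -> float:
    """Smallest Cohen's d a two-sided two-sample t-test detects with the
    requested power (noncentral-t solve); rounded half-up when
    ``decimals`` is given."""
    if spec.design != "independent":
        raise ValueError("spec.design must be 'independent'")
    n1, n2 = spec.n1, spec.n2
    df = n1 + n2 - 2
    nc_of_d = lambda d: d * np.sqrt(n1 * n2 / (n1 + n2))
    d = _solve_mde(nc_of_d, df, spec.alpha, spec.power)
    return _round_half_up(d, decimals) if decimals is not None else d


def mde_paired(spec: PowerSpec, decimals: int | None = 2) -> float:
    """Smallest Cohen's dz a two-sided paired t-test detects with the
    requested power (noncentral t, df = n_pairs - 1)."""
    if spec.design != "paired":
        raise ValueError("spec.design must be 'paired'")
    n = spec.n1
    df = n - 1
    nc_of_d = lambda d: d * np.sqrt(n)
    d = _solve_mde(nc_of_d, df, spec.alpha, spec.power)
    return _round_half_up(d, decimals) if decimals is not None else d


# -------------------------------------------------------- nodewise analysis

def nodewise_analysis(
    metrics: pd.DataFrame,
    grid: CostGrid,
    metric_names: Sequence[str] = ("local_efficiency", "clustering", "degree"),
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Per-node mixed models over a cost grid with BH-FDR across nodes
    within each cost level (cost levels left uncorrected).

    ``metrics`` is long-format with columns subject_id, group, phase,
    cost, metric, node, value plus covariates. Returns one row per node x
    cost x metric x fixed effect of interest with raw and FDR-adjusted
    decisions for the group, phase, and interaction effects.
    """
    rows = []
    effects = ("group", "phase", "group:phase")
    for metric in metric_names:
        sub_m = metrics[metrics["metric"] == metric]
        for cost in grid:
            sub_c = sub_m[np.isclose(sub_m["cost"], cost)]
            node_results: list[tuple[str, MixedModelResult]] = []
            for node, sub_n in sub_c.groupby("node"):
                try:
                    res = fit_mixed_model(
                        sub_n, outcome=f"{metric}@{cost}:{node}", covariates=covariates
                    )
                except ValueError:
                    continue
                if res.converged:
                    node_results.append((str(node), res))
            if not node_results:
                continue
            for effect in effects:
                key_of = {
                    "group": next(
                        k for k in node_results[0][1].params if k.startswith("group[")
                    ),
                    "phase": next(
                        k for k in node_results[0][1].params if k.startswith("phase[")
                    ),
                    "group:phase": "group:phase",
                }[effect]
                pvals = [res.pvalues[key_of] for _, res in node_results]
                reject, p_adj = fdr_bh(pvals, q=fdr_q)
                for (node, res), p_raw, p_a, rej in zip(
                    node_results, pvals, p_adj, reject
                ):
                    rows.append(
                        {
                            "metric": metric,
                            "cost": cost,
                            "node": node,
                            "effect": effect,
                            "estimate": res.params[key_of],
                            "se": res.bse[key_of],
                            "p": p_raw,
                            "p_fdr": p_a,
                            "significant_fdr": bool(rej),
                            "significant_uncorrected": bool(p_raw < fdr_q),
                        }
                    )
    return pd.DataFrame(rows)
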