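"""Stochastic epigenetic mutation (SEM) calling and global epimutation load.

A SEM is a subject's beta value at a CpG lying beyond the Tukey-style fence
of the **control** distribution at that CpG: below Q1 - 3*IQR or above
Q3 + 3*IQR, with quartiles taken over all control samples by linear
interpolation (the common "type 7" convention — recorded in the output
because fences move with the convention). Calls use strict inequalities and
are made for every subject, cases and controls alike; only the fences are
control-derived.

The per-subject genome-wide count of SEMs is the Global Epi-Mutation Load
(Global-EML); its natural-log transform ln(count + 1) is the burden scale
used for association. Case/control association is a logistic regression of
phenotype on log-EML, sex and the covariate principal components, mirroring
the adjustment used in the probe-level EWAS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ControlBoundsResult",
    "SemCalls",
    "AssociationFit",
    "control_bounds",
    "call_sems",
    "global_eml",
    "associate_global_eml",
]

IQR_MULTIPLIER = 3.0


@dataclass
class ControlBoundsResult:
    """Per-probe control quartiles and outlier fences.

    ``bounds`` columns: q1, q3, iqr, lower, upper, n_controls_used.
    ``excluded`` lists probes with fewer non-missing control values than the
    configured floor.
    """

    bounds: pd.DataFrame
    excluded: pd.Index
    quantile_method: str = "linear"


@dataclass
class SemCalls:
    """Ternary call matrix: +1 hyper, -1 hypo, 0 none (probe x subject).

    Missing betas are called 0; their coordinates are kept in ``missing``.
    ``skipped_probes`` are probes scored in the beta matrix but lacking
    fences.
    """

    calls: pd.DataFrame
    bounds: ControlBoundsResult
    missing: pd.DataFrame | None = None
    skipped_probes: pd.Index = field(default_factory=lambda: pd.Index([]))

    def to_triplets(self) -> pd.DataFrame:
        """Sparse (probe_id, subject_id, direction) for the nonzero calls."""
        arr = self.calls.to_numpy()
        i, j = np.nonzero(arr)
        return pd.DataFrame(
            {
                "probe_id": self.calls.index[i],
                "subject_id": self.calls.columns[j],
                "direction": np.where(arr[i, j] > 0, "hyper", "hypo"),
            }
        )


def control_bounds(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    *,
    min_controls: int = 8,
) -> ControlBoundsResult:
    """Compute per-probe Q1/Q3/IQR fences from control subjects only."""
    controls = sheet.index[sheet["phenotype"] == "control"]
    controls = controls.intersection(beta.columns, sort=False)
    if len(controls) == 0:
        raise ValueError("no control subjects available for fence computation")
    ctrl = beta.loc[:, controls].to_numpy(dtype=float)
    n_used = np.sum(~np.isnan(ctrl), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        q1 = np.nanquantile(ctrl, 0.25, axis=1)
        q3 = np.nanquantile(ctrl, 0.75, axis=1)
    iqr = q3 - q1
    bounds = pd.DataFrame(
        {
            "q1": q1,
            "q3": q3,
            "iqr": iqr,
            "lower": q1 - IQR_MULTIPLIER * iqr,
            "upper": q3 + IQR_MULTIPLIER * iqr,
            "n_controls_used": n_used,
        },
        index=beta.index,
    )
    keep = n_used >= min_controls
    return ControlBoundsResult(
        bounds=bounds.loc[keep], excluded=beta.index[~keep]
    )


def call_sems(beta: pd.DataFrame, bounds: ControlBoundsResult) -> SemCalls:
    """Score every (probe, subject) cell against the control fences.

    Strict inequalities: a beta exactly on a fence (including the iqr=0
    degenerate case) is not a SEM.
    """
    shared = beta.index.intersection(bounds.bounds.index, sort=False)
    skipped = beta.index.difference(bounds.bounds.index)
    values = beta.loc[shared].to_numpy(dtype=float)
    lower = bounds.bounds.loc[shared, "lower"].to_numpy()[:, None]
    upper = bounds.bounds.loc[shared, "upper"].to_numpy()[:, None]
    calls = np.zeros(values.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        calls[values > upper] = 1
        calls[values < lower] = -1
    missing_mask = np.isnan(values)
    calls[missing_mask] = 0
    mi, mj = np.nonzero(missing_mask)
    missing = (
        pd.DataFrame({"probe_id": shared[mi], "subject_id": beta.columns[mj]})
        if len(mi)
        else None
    )
    return SemCalls(
        calls=pd.DataFrame(calls, index=shared, columns=beta.columns),
        bounds=bounds,
        missing=missing,
        skipped_probes=skipped,
    )


def global_eml(calls: SemCalls) -> pd.DataFrame:
    """Per-subject genome-wide SEM burden.

    Returns a frame indexed by subject with ``global_count`` (nonzero calls)
    and ``log_eml`` = ln(count + 1).
    """
    counts = np.count_nonzero(calls.calls.to_numpy(), axis=0)
    return pd.DataFrame(
        {"global_count": counts, "log_eml": np.log1p(counts)},
        index=pd.Index(calls.calls.columns, name="subject_id"),
    )


@dataclass
class AssociationFit:
    """Fitted association model with Wald inference.

    ``params``/``bse``/``pvalues`` are indexed by predictor name; ``method``
    is "mle" or "firth" (a Jeffreys-prior bias-reduced fallback used and
    flagged when the likelihood does not converge, e.g. perfect separation).
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    model: str
    nobs: int
    converged: bool
    method: str = "mle"
    #: likelihood-ratio p for the focal predictor (penalized LR under
    #: Firth); preferred over Wald for strong effects, where the Wald
    #: statistic loses power (Hauck-Donner effect)
    p_lrt: float | None = None
    focal: str | None = None

    def summary(self) -> str:
        lines = [
            self.model,
            f"n = {self.nobs}, method = {self.method}, converged = {self.converged}",
        ]
        if self.p_lrt is not None:
            lines.append(f"likelihood-ratio p[{self.focal}] = {self.p_lrt:.3g}")
        lines += [
            f"{'predictor':<14}{'coef':>10}{'se':>10}{'p':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<14}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.pvalues[name]:>12.3g}"
            )
        return "\n".join(lines)


def _firth_logit(y: np.ndarray, X: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth bias-reduced logistic regression (Jeffreys-prior penalty).

    Gives finite estimates and usable Wald inference under (quasi-)complete
    separation, where plain maximum likelihood diverges. Standard errors
    come from the penalized Fisher information at convergence.
    """
    n, p = X.shape
    b = np.zeros(p)
    for _ in range(max_iter):
        mu = scipy.special.expit(X @ b)
        W = mu * (1.0 - mu)
        XW = X * W[:, None]
        info = XW.T @ X
        info_inv = np.linalg.pinv(info)
        # leverages of the weighted hat matrix
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        # dampen oversized steps for stability
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    mu = scipy.special.expit(X @ b)
    W = mu * (1.0 - mu)
    cov = np.linalg.pinv((X * W[:, None]).T @ X)
    return b, np.sqrt(np.diag(cov))


def _penalized_loglik(y: np.ndarray, X: np.ndarray, b: np.ndarray) -> float:
    """Firth-penalized log-likelihood: loglik + 0.5 log det(Fisher info)."""
    eta = X @ b
    mu = scipy.special.expit(eta)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    W = np.clip(mu * (1.0 - mu), 1e-12, None)
    sign, logdet = np.linalg.slogdet((X * W[:, None]).T @ X)
    return ll + 0.5 * logdet


def _lrt_pvalue(y: np.ndarray, Xv: np.ndarray, focal_idx: int, method: str,
                mle_fit=None) -> float:
    """Likelihood-ratio p for one predictor (penalized LR under Firth).

    Wald inference loses power as effects grow (Hauck-Donner); the LR test
    does not, so it is the headline test for the focal predictor.
    """
    X_red = np.delete(Xv, focal_idx, axis=1)
    if method == "mle" and mle_fit is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            red = sm.Logit(y, X_red).fit(disp=0, maxiter=200)
        stat = 2.0 * (mle_fit.llf - red.llf)
    else:
        b_full, _ = _firth_logit(y, Xv)
        b_red, _ = _firth_logit(y, X_red)
        stat = 2.0 * (
            _penalized_loglik(y, Xv, b_full) - _penalized_loglik(y, X_red, b_red)
        )
    stat = max(stat, 0.0)
    return float(np.clip(stats.chi2.sf(stat, 1), np.finfo(float).tiny, 1.0))


def associate_global_eml(
    eml: pd.DataFrame,
    sheet: pd.DataFrame,
    pcs,
) -> AssociationFit:
    """Logistic regression of phenotype on log-EML, sex and covariate PCs.

    The coefficient of interest is ``log_eml``: the log-odds of case status
    per unit of ln(SEM count + 1).
    """
    subjects = eml.index
    pheno = sheet.loc[subjects, "phenotype"]
    if pheno.nunique() < 2:
        raise ValueError("both phenotype groups must be present")
    y = (pheno == "case").to_numpy(dtype=float)
    X = pd.DataFrame({"const": 1.0, "log_eml": eml["log_eml"]}, index=subjects)
    X["sex_M"] = (sheet.loc[subjects, "sex"] == "M").astype(float)
    scores = pcs.scores.loc[subjects]
    for col in scores.columns:
        X[col] = scores[col]
    names = X.columns
    Xv = X.to_numpy(dtype=float)

    method, converged = "mle", True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xv).fit(disp=0, maxiter=200)
            ok = fit.mle_retvals.get("converged", False) and np.all(
                np.isfinite(fit.bse)
            ) and np.all(fit.bse < 1e2)
        except Exception:
            ok = False
    if ok:
        params, bse = fit.params, fit.bse
    else:
        # (quasi-)separation or non-convergence: Firth bias-reduced fit
        method, converged = "firth", False
        params, bse = _firth_logit(y, Xv)
    z = params / bse
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    focal_idx = list(names).index("log_eml")
    p_lrt = _lrt_pvalue(y, Xv, focal_idx, method, mle_fit=fit if ok else None)
    return AssociationFit(
        params=pd.Series(params, index=names),
        bse=pd.Series(bse, index=names),
        pvalues=pd.Series(pvals, index=names),
        model="logit(phenotype=case) ~ log_eml + sex + covariate PCs",
        nobs=len(y),
        converged=converged,
        method=method,
        p_lrt=p_lrt,
        focal="log_eml",
    )
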