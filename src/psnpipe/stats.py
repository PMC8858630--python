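"""Composition tables, Wilcoxon/BH comparisons and the random-intercept mixed model.

Group comparisons of per-sample fractions use the two-sided Wilcoxon rank-sum
(unpaired) or signed-rank (paired) test with Benjamini-Hochberg adjustment.
Functional-state scores are compared between clinical groups with the linear
mixed model  score ~ group + (1 | patient)  fitted by REML; fixed-effect
p-values use Satterthwaite's approximate degrees of freedom, computed from the
gradient of the contrast variance with respect to the variance components and
the curvature of the REML criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GROUP_PREFERENCE = ("nLung", "GG", "solid")


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def composition_table(
    labels: pd.DataFrame,
    sample_meta: pd.DataFrame,
    denominator_types: Sequence[str],
) -> pd.DataFrame:
    """Per-sample cell-type fractions over a stated denominator.

    Parameters
    ----------
    labels
        DataFrame with one row per cell and columns ``sample`` and ``cell_type``.
    sample_meta
        DataFrame with columns ``sample_id``, ``patient_id``, ``clinical_group``.
    denominator_types
        The cell types forming the denominator (e.g. immune types only); types
        outside it are excluded from both numerator and denominator.

    Samples with zero denominator cells are dropped with a log entry.
    """
    denom = list(dict.fromkeys(denominator_types))
    sub = labels[labels["cell_type"].isin(denom)]
    counts = (sub.groupby(["sample", "cell_type"], observed=False).size()
              .unstack(fill_value=0).reindex(columns=denom, fill_value=0))
    totals = counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.info("dropping %d samples with no denominator cells", int(empty.sum()))
    counts = counts[~empty]
    fracs = counts.div(counts.sum(axis=1), axis=0)
    meta = sample_meta.set_index("sample_id")[["patient_id", "clinical_group"]]
    fracs = fracs.join(meta, how="left")
    return fracs


# ---------------------------------------------------------------------------
# Wilcoxon and Benjamini-Hochberg
# ---------------------------------------------------------------------------

def wilcoxon_test(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (unpaired) or signed-rank (paired) test.

    Unpaired: exact enumeration when n1 + n2 <= 12 and the pooled data has no
    ties, otherwise the normal approximation with tie and continuity
    corrections.  Paired: zero differences are dropped; exact when the
    remaining n <= 15 with no tied absolute differences, else the normal
    approximation.  Returns (statistic, p, method-used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal-length samples")
        d = x - y
        d = d[d != 0]
        if d.size == 0:
            logger.info("paired Wilcoxon: all differences zero; p = 1")
            return 0.0, 1.0, "degenerate"
        no_ties = np.unique(np.abs(d)).size == d.size
        if d.size <= 15 and no_ties:
            res = scipy.stats.wilcoxon(d, alternative="two-sided", method="exact")
            return float(res.statistic), float(res.pvalue), "exact"
        res = scipy.stats.wilcoxon(d, alternative="two-sided", method="approx",
                                   correction=True)
        return float(res.statistic), float(res.pvalue), "approx"
    if x.size < 1 or y.size < 1:
        raise ValueError("unpaired test requires non-empty samples")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= 12 and no_ties:
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue), "asymptotic"


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def compare_composition_groups(
    comp: pd.DataFrame,
    group_a: str,
    group_b: str,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-cell-type Wilcoxon comparison of fractions between two clinical groups.

    For the paired variant, samples are matched by patient; patients missing
    either group are dropped.  BH adjustment is applied across cell types
    (one family per comparison panel).
    """
    types = [c for c in comp.columns if c not in ("patient_id", "clinical_group")]
    rows = []
    a = comp[comp["clinical_group"] == group_a]
    b = comp[comp["clinical_group"] == group_b]
    if paired:
        common = sorted(set(a["patient_id"]) & set(b["patient_id"]))
        a = a.set_index("patient_id").loc[common]
        b = b.set_index("patient_id").loc[common]
    for t in types:
        stat, p, method = wilcoxon_test(a[t].to_numpy(), b[t].to_numpy(), paired=paired)
        rows.append({"cell_type": t, "comparison": f"{group_a}_vs_{group_b}",
                     "statistic": stat, "p": p, "method": method})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# random-intercept linear mixed model (REML + Satterthwaite)
# ---------------------------------------------------------------------------

@dataclass
class LmmResult:
    """Fixed-effect contrast of  score ~ group + (1 | patient)."""

    contrast: str
    estimate: float
    se: float
    df: float
    tstat: float
    pvalue: float
    var_patient: float
    var_residual: float
    boundary: bool                  # patient variance estimated at 0
    reference: str
    converged: bool = True


class _RandomInterceptREML:
    """Sufficient-statistic REML machinery for y = X beta + patient intercept + e."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.n, self.p = X.shape
        self.levels, idx = np.unique(groups, return_inverse=True)
        self.Gxx, self.gxy, self.sx, self.sy, self.gyy, self.ni = [], [], [], [], [], []
        for g in range(len(self.levels)):
            sel = idx == g
            Xg, yg = X[sel], y[sel]
            self.Gxx.append(Xg.T @ Xg)
            self.gxy.append(Xg.T @ yg)
            self.sx.append(Xg.sum(axis=0))
            self.sy.append(yg.sum())
            self.gyy.append(float(yg @ yg))
            self.ni.append(int(sel.sum()))

    def _gls_parts(self, va: float, ve: float):
        p = self.p
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        ytViy = 0.0
        logdetV = 0.0
        for Gxx, gxy, sx, sy, gyy, ni in zip(self.Gxx, self.gxy, self.sx,
                                             self.sy, self.gyy, self.ni):
            c = va / (ve + va * ni)
            XtViX += (Gxx - c * np.outer(sx, sx)) / ve
            XtViy += (gxy - c * sx * sy) / ve
            ytViy += (gyy - c * sy**2) / ve
            logdetV += (ni - 1) * np.log(ve) + np.log(ve + va * ni)
        return XtViX, XtViy, ytViy, logdetV

    def neg2_reml(self, va: float, ve: float) -> float:
        XtViX, XtViy, ytViy, logdetV = self._gls_parts(va, ve)
        beta = np.linalg.solve(XtViX, XtViy)
        quad = ytViy - beta @ XtViy
        sign, logdetM = np.linalg.slogdet(XtViX)
        return logdetV + logdetM + quad + (self.n - self.p) * np.log(2 * np.pi)

    def profile_sigma2(self, lam: float) -> float:
        """REML residual variance with the variance ratio lambda fixed."""
        XtViX, XtViy, ytViy, _ = self._gls_parts(lam, 1.0)
        beta = np.linalg.solve(XtViX, XtViy)
        return (ytViy - beta @ XtViy) / (self.n - self.p)

    def fit(self, tol: float = 1e-8) -> tuple[float, float]:
        def objective(t: float) -> float:
            lam = np.exp(t)
            s2 = self.profile_sigma2(lam)
            return self.neg2_reml(lam * s2, s2)

        res = scipy.optimize.minimize_scalar(
            objective, bounds=(-25.0, 12.0), method="bounded",
            options={"xatol": tol})
        s2_zero = self.profile_sigma2(0.0)
        f_zero = self.neg2_reml(0.0, s2_zero)
        if f_zero <= res.fun or np.exp(res.x) * self.profile_sigma2(np.exp(res.x)) < 1e-12:
            return 0.0, s2_zero
        lam = float(np.exp(res.x))
        s2 = self.profile_sigma2(lam)
        return lam * s2, s2

    def beta_cov(self, va: float, ve: float) -> tuple[np.ndarray, np.ndarray]:
        XtViX, XtViy, _, _ = self._gls_parts(va, ve)
        cov = np.linalg.inv(XtViX)
        return cov @ XtViy, cov

    def satterthwaite_df(self, c: np.ndarray, va: float, ve: float) -> float:
        """df = 2 phi^2 / Var(phi), phi = c' Cov(beta) c, via the delta method."""
        def phi(theta):
            _, cov = self.beta_cov(max(theta[0], 0.0), theta[1])
            return float(c @ cov @ c)

        theta = np.array([va, ve])
        steps = np.maximum(1e-5 * np.maximum(theta, ve), 1e-10)
        # central differences for the gradient of phi
        grad = np.zeros(2)
        for j in range(2):
            e = np.zeros(2)
            e[j] = steps[j]
            lo = theta - e
            if lo[j] < 0:               # one-sided near the va >= 0 boundary
                grad[j] = (phi(theta + e) - phi(theta)) / steps[j]
            else:
                grad[j] = (phi(theta + e) - phi(lo)) / (2 * steps[j])
        # Hessian of the -2 log REML criterion
        def f(theta):
            return self.neg2_reml(max(theta[0], 0.0), theta[1])

        H = np.zeros((2, 2))
        for j in range(2):
            for k in range(j, 2):
                ej = np.zeros(2); ej[j] = steps[j]
                ek = np.zeros(2); ek[k] = steps[k]
                H[j, k] = H[k, j] = (
                    f(theta + ej + ek) - f(theta + ej - ek)
                    - f(theta - ej + ek) + f(theta - ej - ek)
                ) / (4 * steps[j] * steps[k])
        try:
            vcov_theta = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return float(self.n - self.p)
        denom = float(grad @ vcov_theta @ grad)
        ph = phi(theta)
        if denom <= 0:
            return float(self.n - self.p)
        return 2.0 * ph**2 / denom


def _choose_reference(levels: Sequence[str], reference: Optional[str]) -> str:
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference {reference!r} not among groups {levels}")
        return reference
    for g in GROUP_PREFERENCE:
        if g in levels:
            return g
    return sorted(levels)[0]


def fit_lmm(
    score: Sequence[float],
    group: Sequence[str],
    patient: Sequence[str],
    reference: Optional[str] = None,
    boundary_tol: float = 1e-8,
) -> list[LmmResult]:
    """REML fit of  score ~ group + (1 | patient)  with Satterthwaite p-values.

    Treatment coding with ``nLung`` (else ``GG``, else the first sorted level)
    as the reference; one :class:`LmmResult` per non-reference level.  When the
    patient variance is estimated at the boundary 0 the model reduces to OLS
    and the residual degrees of freedom are reported, with ``boundary=True``.
    """
    y = np.asarray(score, dtype=float)
    group = np.asarray(group)
    patient = np.asarray(patient)
    levels = list(pd.unique(group))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if np.unique(patient).size < 2:
        raise ValueError("need at least 2 patients")
    ref = _choose_reference(levels, reference)
    others = [g for g in sorted(levels) if g != ref]
    X = np.column_stack([np.ones_like(y)] +
                        [(group == g).astype(float) for g in others])

    reml = _RandomInterceptREML(y, X, patient)
    va, ve = reml.fit()
    boundary = va <= boundary_tol * max(ve, 1.0)
    beta, cov = reml.beta_cov(va, ve)

    results = []
    for j, g in enumerate(others, start=1):
        c = np.zeros(X.shape[1])
        c[j] = 1.0
        phi = float(c @ cov @ c)
        se = float(np.sqrt(phi))
        if boundary:
            df = float(reml.n - reml.p)
        else:
            df = reml.satterthwaite_df(c, va, ve)
        t = float(beta[j] / se)
        p = float(2 * scipy.stats.t.sf(abs(t), df))
        results.append(LmmResult(
            contrast=f"{g}_vs_{ref}", estimate=float(beta[j]), se=se, df=df,
            tstat=t, pvalue=p, var_patient=float(va), var_residual=float(ve),
            boundary=bool(boundary), reference=ref,
        ))
    return results


def lmm_group_comparison(
    scores: pd.DataFrame,
    group: Sequence[str],
    patient: Sequence[str],
    comparisons: Sequence[tuple[str, str]] = (("GG", "solid"),),
) -> pd.DataFrame:
    """Pairwise two-group LMM fits per score column (one fit per panel)."""
    group = np.asarray(group)
    patient = np.asarray(patient)
    rows = []
    for name in scores.columns:
        y = scores[name].to_numpy()
        for ref, other in comparisons:
            sel = np.isin(group, [ref, other])
            if np.unique(patient[sel]).size < 2 or np.unique(group[sel]).size < 2:
                continue
            res = fit_lmm(y[sel], group[sel], patient[sel], reference=ref)[0]
            rows.append({"score": name, "contrast": res.contrast,
                         "estimate": res.estimate, "se": res.se, "df": res.df,
                         "t": res.tstat, "p": res.pvalue,
                         "var_patient": res.var_patient,
                         "var_residual": res.var_residual,
                         "boundary": res.boundary})
    return pd.DataFrame(rows)
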