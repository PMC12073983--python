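"""Cohort-level diagnostic statistics.

Implements the study-level analyses: predictive values with exact
Clopper-Pearson intervals, the paired relative-NPV comparison of two tests
applied to the same patients, DerSimonian-Laird random-effects pooling of
proportions and odds ratios, a bivariate random-effects SROC model with AUC,
the Wilcoxon rank-sum comparison of channel rates, and the quantized linear
fixed-effects model of prediction correctness with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as spstats
from scipy.special import expit, logit
from statsmodels.api import OLS, add_constant
from statsmodels.stats.multitest import multipletests

from .containers import ConfusionMatrix, PatientRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# exact binomial intervals and predictive values
# ---------------------------------------------------------------------------

def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (beta-quantile) binomial confidence interval.

    The lower bound is 0 when successes = 0 and the upper bound is 1 when
    successes = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    alpha = 1.0 - level
    low = 0.0 if successes == 0 else float(spstats.beta.ppf(alpha / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(spstats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return low, high


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its exact CI and the defining counts."""

    point: float
    ci_low: float
    ci_high: float
    numer: int
    denom: int


@dataclass
class DiagnosticSummary:
    """PPV, NPV, sensitivity, specificity and accuracy of a patient-level
    confusion matrix; statistics with a zero denominator are None."""

    ppv: ProportionEstimate | None
    npv: ProportionEstimate | None
    sensitivity: ProportionEstimate | None
    specificity: ProportionEstimate | None
    accuracy: ProportionEstimate | None

    def as_dict(self) -> dict:
        out = {}
        for name in ("ppv", "npv", "sensitivity", "specificity", "accuracy"):
            est = getattr(self, name)
            out[name] = None if est is None else vars(est).copy()
        return out


def _prop(numer: int, denom: int, level: float) -> ProportionEstimate | None:
    if denom <= 0:
        return None
    lo, hi = clopper_pearson(numer, denom, level)
    return ProportionEstimate(numer / denom, lo, hi, numer, denom)


def diagnostic_summary(cm: ConfusionMatrix, level: float = 0.95) -> DiagnosticSummary:
    """Point estimates per the standard formulas, CIs via Clopper-Pearson.

    A degenerate test that makes no positive calls (TP = FP = 0, e.g. the
    resected-volume comparator) has no measurable discrimination: its PPV,
    sensitivity and specificity are all marked undefined, leaving NPV and
    accuracy.
    """
    degenerate = cm.TP + cm.FP == 0
    return DiagnosticSummary(
        ppv=None if degenerate else _prop(cm.TP, cm.TP + cm.FP, level),
        npv=_prop(cm.TN, cm.TN + cm.FN, level),
        sensitivity=None if degenerate else _prop(cm.TP, cm.TP + cm.FN, level),
        specificity=None if degenerate else _prop(cm.TN, cm.TN + cm.FP, level),
        accuracy=_prop(cm.TP + cm.TN, cm.n, level),
    )


# ---------------------------------------------------------------------------
# paired relative NPV (Moskowitz & Pepe style)
# ---------------------------------------------------------------------------

@dataclass
class RelativeNpvResult:
    """Ratio NPV(test1)/NPV(test2) on a paired cohort, with Wald inference on
    the log scale."""

    rnpv: float
    ci_low: float
    ci_high: float
    log_se: float
    p_value: float
    npv1: float
    npv2: float
    n: int


def relative_npv_test(
    test1_negative: np.ndarray,
    test2_negative: np.ndarray,
    outcome_good: np.ndarray,
    level: float = 0.95,
) -> RelativeNpvResult:
    """Compare the NPVs of two binary tests applied to the same patients.

    NPV_j = P(good outcome | test j negative). The estimator is the plug-in
    ratio; its log-scale variance is the empirical variance of the influence
    function of log NPV1 - log NPV2 under the joint (paired) multinomial —
    the delta-method variance for relative predictive values in paired
    designs. The null rNPV = 1 is tested with a two-sided Wald z-test.
    """
    n1 = np.asarray(test1_negative, dtype=bool)
    n2 = np.asarray(test2_negative, dtype=bool)
    good = np.asarray(outcome_good, dtype=bool)
    if not (len(n1) == len(n2) == len(good)):
        raise ValueError("paired inputs must have equal length")
    n = len(n1)
    if n == 0:
        raise ValueError("empty cohort")
    q1, q2 = n1.mean(), n2.mean()
    if q1 == 0 or q2 == 0:
        raise ValueError("each test needs >= 1 negative call")
    p1 = (good & n1).mean()
    p2 = (good & n2).mean()
    if p1 == 0 or p2 == 0:
        raise ValueError("each test needs >= 1 correct negative call for a ratio")
    npv1, npv2 = p1 / q1, p2 / q2
    theta = np.log(npv1) - np.log(npv2)
    infl = (
        (good & n1) / p1 - n1 / q1 - (good & n2) / p2 + n2 / q2
    )
    log_se = float(np.sqrt(np.mean(infl**2) / n))
    z_crit = spstats.norm.ppf(0.5 + level / 2)
    if log_se == 0.0:
        # identical negative calls and outcomes: ratio exactly estimated
        return RelativeNpvResult(float(np.exp(theta)), float(np.exp(theta)),
                                 float(np.exp(theta)), 0.0, 1.0, npv1, npv2, n)
    z = theta / log_se
    p = float(2 * spstats.norm.sf(abs(z)))
    return RelativeNpvResult(
        rnpv=float(np.exp(theta)),
        ci_low=float(np.exp(theta - z_crit * log_se)),
        ci_high=float(np.exp(theta + z_crit * log_se)),
        log_se=log_se,
        p_value=p,
        npv1=float(npv1),
        npv2=float(npv2),
        n=n,
    )


# ---------------------------------------------------------------------------
# random-effects pooling (DerSimonian-Laird)
# ---------------------------------------------------------------------------

@dataclass
class MetaResult:
    """A pooled estimate with heterogeneity statistics and per-centre detail."""

    pooled_estimate: float
    ci_low: float
    ci_high: float
    tau2: float
    i2: float  # percent
    q: float
    q_p: float
    per_centre: list[dict] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "pooled_estimate": self.pooled_estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "tau2": self.tau2,
            "i2": self.i2,
            "q": self.q,
            "q_p": self.q_p,
            "per_centre": self.per_centre,
            "excluded": self.excluded,
        }


def _dl_pool(
    effects: np.ndarray, variances: np.ndarray, level: float = 0.95
) -> tuple[float, float, float, float, float, float, float]:
    """DerSimonian-Laird random-effects pooling on the working scale.

    Returns (pooled, ci_low, ci_high, tau2, i2_percent, q, q_p). The
    between-centre variance is the moment estimator truncated at zero, so
    homogeneous inputs reduce exactly to the fixed-effect inverse-variance
    mean.
    """
    effects = np.asarray(effects, dtype=float)
    variances = np.asarray(variances, dtype=float)
    w = 1.0 / variances
    fe = float((w * effects).sum() / w.sum())
    df = len(effects) - 1
    q = float((w * (effects - fe) ** 2).sum())
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / c) if df > 0 and c > 0 else 0.0
    wr = 1.0 / (variances + tau2)
    pooled = float((wr * effects).sum() / wr.sum())
    se = float(np.sqrt(1.0 / wr.sum()))
    z = spstats.norm.ppf(0.5 + level / 2)
    q_p = float(spstats.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = 100.0 * max((q - df) / q, 0.0) if q > 0 and df > 0 else 0.0
    return pooled, pooled - z * se, pooled + z * se, tau2, i2, q, q_p


def _logit_and_var(x: int, n: int) -> tuple[float, float]:
    # 0.5 continuity adjustment only at the boundaries
    if x == 0 or x == n:
        x_adj, n_adj = x + 0.5, n + 1.0
    else:
        x_adj, n_adj = float(x), float(n)
    p = x_adj / n_adj
    return float(np.log(p / (1 - p))), float(1.0 / x_adj + 1.0 / (n_adj - x_adj))


def _ft_and_var(x: int, n: int) -> tuple[float, float]:
    # Freeman-Tukey double-arcsine
    t = np.arcsin(np.sqrt(x / (n + 1.0))) + np.arcsin(np.sqrt((x + 1.0) / (n + 1.0)))
    return float(t), float(1.0 / (n + 0.5))


def _ft_back(t: float, n_harmonic: float) -> float:
    # Miller's inverse of the double-arcsine transform, using the harmonic
    # mean of the centre sizes
    t = float(np.clip(t, 1e-9, np.pi - 1e-9))
    inner = np.sin(t) + (np.sin(t) - 1.0 / np.sin(t)) / n_harmonic
    return float(0.5 * (1 - np.sign(np.cos(t)) * np.sqrt(max(0.0, 1 - inner**2))))


def pooled_proportion(
    per_centre: list[tuple[int, int]],
    level: float = 0.95,
    transform: str = "logit",
    labels: list[str] | None = None,
) -> MetaResult:
    """Random-effects pooled proportion across centres.

    Pooling is on the logit scale with DerSimonian-Laird tau^2 (default) or on
    the Freeman-Tukey double-arcsine scale; per-centre CIs are exact
    Clopper-Pearson. A single centre returns itself with I^2 = 0.
    """
    usable = [(x, n) for x, n in per_centre if n >= 1]
    if not usable:
        raise ValueError("no centre with n >= 1")
    labels = labels or [f"centre{i + 1}" for i in range(len(per_centre))]
    detail = []
    for lab, (x, n) in zip(labels, per_centre):
        if n < 1:
            continue
        lo, hi = clopper_pearson(x, n, level)
        detail.append({"centre": lab, "estimate": x / n, "ci_low": lo, "ci_high": hi,
                       "successes": x, "n": n})
    if len(usable) == 1:
        x, n = usable[0]
        lo, hi = clopper_pearson(x, n, level)
        return MetaResult(x / n, lo, hi, 0.0, 0.0, 0.0, 1.0, detail)
    if transform == "logit":
        pairs = [_logit_and_var(x, n) for x, n in usable]
        back = expit
    elif transform == "freeman_tukey":
        pairs = [_ft_and_var(x, n) for x, n in usable]
        n_harm = len(usable) / sum(1.0 / n for _, n in usable)
        back = lambda t: _ft_back(t, n_harm)  # noqa: E731
    else:
        raise ValueError(f"unknown transform {transform!r}")
    eff = np.array([p[0] for p in pairs])
    var = np.array([p[1] for p in pairs])
    pooled_t, lo_t, hi_t, tau2, i2, q, q_p = _dl_pool(eff, var, level)
    return MetaResult(
        float(back(pooled_t)), float(back(lo_t)), float(back(hi_t)),
        tau2, i2, q, q_p, detail,
    )


def pooled_or(
    per_centre: list[tuple[int, int, int, int]],
    level: float = 0.95,
    labels: list[str] | None = None,
) -> MetaResult:
    """DerSimonian-Laird pooled odds ratio across centres.

    Each table is (a, b, c, d) with OR = (a*d)/(b*c); a 0.5 continuity
    correction is applied to all four cells of any table with a zero cell.
    Centres with an empty row or column carry no OR information and are
    excluded with a log entry.
    """
    labels = labels or [f"centre{i + 1}" for i in range(len(per_centre))]
    eff, var, detail, excluded = [], [], [], []
    z_crit = spstats.norm.ppf(0.5 + level / 2)
    for lab, (a, b, c, d) in zip(labels, per_centre):
        if min(a + b, c + d, a + c, b + d) == 0:
            logger.info("centre %s has an empty row/column; excluded from OR pooling", lab)
            excluded.append(lab)
            continue
        if min(a, b, c, d) == 0:
            a, b, c, d = (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
        log_or = np.log(a * d / (b * c))
        v = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
        eff.append(log_or)
        var.append(v)
        detail.append({
            "centre": lab, "estimate": float(np.exp(log_or)),
            "ci_low": float(np.exp(log_or - z_crit * np.sqrt(v))),
            "ci_high": float(np.exp(log_or + z_crit * np.sqrt(v))),
        })
    if not eff:
        raise ValueError("no usable centre for OR pooling")
    if len(eff) == 1:
        d0 = detail[0]
        return MetaResult(d0["estimate"], d0["ci_low"], d0["ci_high"],
                          0.0, 0.0, 0.0, 1.0, detail, excluded)
    pooled_t, lo_t, hi_t, tau2, i2, q, q_p = _dl_pool(np.array(eff), np.array(var), level)
    return MetaResult(float(np.exp(pooled_t)), float(np.exp(lo_t)), float(np.exp(hi_t)),
                      tau2, i2, q, q_p, detail, excluded)


# ---------------------------------------------------------------------------
# bivariate SROC
# ---------------------------------------------------------------------------

@dataclass
class SrocResult:
    """Bivariate random-effects summary of diagnostic accuracy across centres."""

    pooled_sensitivity: float
    sens_ci: tuple[float, float]
    pooled_specificity: float
    spec_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    curve: np.ndarray  # (m, 2) columns FPR, TPR
    method: str  # "bivariate_ml" or "univariate_fallback"
    params: dict = field(default_factory=dict)

    def auc_label(self) -> str:
        if self.auc <= 0.75:
            return "weak"
        if self.auc <= 0.92:
            return "good"
        return "excellent"


def _sroc_nll(params: np.ndarray, ys: np.ndarray, cvars: np.ndarray) -> float:
    mu = params[:2]
    s1, s2 = np.exp(params[2]), np.exp(params[3])
    rho = np.tanh(params[4])
    sigma = np.array([[s1 * s1, rho * s1 * s2], [rho * s1 * s2, s2 * s2]])
    nll = 0.0
    for y, cv in zip(ys, cvars):
        v = sigma + np.diag(cv)
        det = v[0, 0] * v[1, 1] - v[0, 1] * v[1, 0]
        if det <= 0:
            return 1e12
        r = y - mu
        quad = (r[0] * r[0] * v[1, 1] - 2 * r[0] * r[1] * v[0, 1] + r[1] * r[1] * v[0, 0]) / det
        nll += 0.5 * (np.log(det) + quad)
    return float(nll)


def _num_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(x)
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei, ej = np.zeros(k), np.zeros(k)
            ei[i], ej[j] = h, h
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return hess


def _sroc_curve_auc(mu1: float, mu2: float, slope: float, m: int = 2001) -> tuple[np.ndarray, float]:
    fpr = np.linspace(1e-6, 1 - 1e-6, m)
    tpr = expit(mu1 + slope * (logit(1 - fpr) - mu2))
    curve = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return curve, auc


def sroc(
    per_centre: list[tuple[int, int, int, int]],
    level: float = 0.95,
    n_mc: int = 2000,
    seed: int = 0,
) -> SrocResult:
    """Summary ROC across centres via a bivariate random-effects model.

    Per centre, (logit sensitivity, logit specificity) — continuity-corrected
    when any cell is zero — are modelled as bivariate normal around a common
    mean with between-centre covariance, fitted by maximum likelihood with the
    usual within-centre binomial variances. The SROC curve is the regression
    of logit sensitivity on logit specificity implied by the fit; AUC is its
    numerical integral over FPR in [0, 1]. CIs for the pooled operating point
    come from the observed information; the AUC CI from Monte Carlo draws of
    the parameters (seeded, hence reproducible).
    """
    if len(per_centre) < 2:
        raise ValueError("need >= 2 centres; use pooled_proportion for a single centre")
    ys, cvars = [], []
    for tp, fp, tn, fn in per_centre:
        if min(tp, fp, tn, fn) == 0:
            tp, fp, tn, fn = tp + 0.5, fp + 0.5, tn + 0.5, fn + 0.5
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        ys.append([np.log(sens / (1 - sens)), np.log(spec / (1 - spec))])
        cvars.append([1.0 / tp + 1.0 / fn, 1.0 / tn + 1.0 / fp])
    ys = np.asarray(ys)
    cvars = np.asarray(cvars)

    x0 = np.array([
        ys[:, 0].mean(), ys[:, 1].mean(),
        np.log(max(ys[:, 0].std(), 0.1)), np.log(max(ys[:, 1].std(), 0.1)), 0.0,
    ])
    opt = optimize.minimize(
        _sroc_nll, x0, args=(ys, cvars), method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
    )
    method = "bivariate_ml"
    params = opt.x
    cov = None
    try:
        hess = _num_hessian(lambda p: _sroc_nll(p, ys, cvars), params)
        # variance parameters can sit on the boundary (tau -> 0, |rho| -> 1),
        # flattening the likelihood there; the pseudo-inverse keeps the
        # informative (mu) block while zeroing degenerate directions
        cov = np.linalg.pinv(hess, hermitian=True)
        if not np.all(np.isfinite(cov)) or cov[0, 0] <= 0 or cov[1, 1] <= 0:
            cov = None
    except np.linalg.LinAlgError:
        cov = None
    if not opt.success or cov is None:
        # singular bivariate fit: univariate DL pooling of each axis
        method = "univariate_fallback"
        p1, l1, h1, *_ = _dl_pool(ys[:, 0], cvars[:, 0], level)
        p2, l2, h2, *_ = _dl_pool(ys[:, 1], cvars[:, 1], level)
        curve, auc = _sroc_curve_auc(p1, p2, 0.0)
        return SrocResult(
            float(expit(p1)), (float(expit(l1)), float(expit(h1))),
            float(expit(p2)), (float(expit(l2)), float(expit(h2))),
            auc, (float("nan"), float("nan")), curve, method,
            {"mu": [p1, p2]},
        )

    mu1, mu2 = params[0], params[1]
    s1, s2 = np.exp(params[2]), np.exp(params[3])
    rho = np.tanh(params[4])
    slope = rho * s1 / s2 if s2 > 0 else 0.0
    if slope > 0:
        logger.info("SROC regression slope positive (%.3g); clamped to 0", slope)
        slope = 0.0
    curve, auc = _sroc_curve_auc(mu1, mu2, slope)

    # t quantile with k-2 df: small-sample correction for the handful of
    # centres typical in multicentre studies (Wald z is anticonservative here)
    dof = max(len(per_centre) - 2, 1)
    z_crit = spstats.t.ppf(0.5 + level / 2, dof)
    se1, se2 = np.sqrt(cov[0, 0]), np.sqrt(cov[1, 1])
    sens_ci = (float(expit(mu1 - z_crit * se1)), float(expit(mu1 + z_crit * se1)))
    spec_ci = (float(expit(mu2 - z_crit * se2)), float(expit(mu2 + z_crit * se2)))

    rng = np.random.default_rng(seed)
    # symmetrize for sampling; fall back to diagonal if not PSD
    csym = (cov + cov.T) / 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            draws = rng.multivariate_normal(params, csym, size=n_mc, method="eigh")
        except (np.linalg.LinAlgError, ValueError):
            draws = params + rng.standard_normal((n_mc, 5)) * np.sqrt(np.abs(np.diag(csym)))
    # log-sd draws are clipped: near-degenerate covariance directions would
    # otherwise produce meaningless extreme slopes
    draws[:, 2:4] = np.clip(draws[:, 2:4], -10.0, 10.0)
    aucs = np.empty(n_mc)
    for i, p in enumerate(draws):
        sl = np.tanh(p[4]) * np.exp(p[2]) / np.exp(p[3])
        _, aucs[i] = _sroc_curve_auc(p[0], p[1], min(sl, 0.0), m=201)
    alpha = 1.0 - level
    auc_ci = (float(np.quantile(aucs, alpha / 2)), float(np.quantile(aucs, 1 - alpha / 2)))

    return SrocResult(
        float(expit(mu1)), sens_ci, float(expit(mu2)), spec_ci,
        auc, auc_ci, curve, method,
        {"mu": [float(mu1), float(mu2)], "tau": [float(s1), float(s2)], "rho": float(rho)},
    )


# ---------------------------------------------------------------------------
# group rate comparison
# ---------------------------------------------------------------------------

def rate_comparison(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two rate samples.

    Exact null distribution when both groups have n <= 25 and there are no
    ties; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (a.size <= 25 and b.size <= 25 and no_ties) else "asymptotic"
    res = spstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# quantized linear fixed-effects model of prediction correctness
# ---------------------------------------------------------------------------

#: effect name -> ordinal quantization (upper bin edges, left-closed)
_AGE_BINS = [13, 18, 25, 59]
_I_BINS = [44, 104]
_J_BINS = [1, 3]
_K_BINS = [5, 24]
_FU_BINS = [24, 37]

LM_EFFECTS = ["age", "sex", "pathology", "elecType", "i", "j", "k", "crHFOarea", "fu"]


def _ordinal(value: float, edges: list[int]) -> int:
    for lvl, edge in enumerate(edges):
        if value <= edge:
            return lvl
    return len(edges)


@dataclass
class LmResult:
    """OLS fit of prediction correctness on quantized clinical covariates."""

    table: pd.DataFrame  # index: intercept + effects; estimate, se, t, p, p_fdr
    dropped: list[str] = field(default_factory=list)
    n: int = 0


def quantize_patient(p: PatientRecord, cr_hfo: bool) -> dict[str, float]:
    """Ordinal covariate levels for one patient (levels as in the cohort
    report: e.g. age 0:[0-13] .. 4:[>=60], crHFOarea 0 = complete resection)."""
    return {
        "age": _ordinal(p.age if p.age is not None else 0, _AGE_BINS),
        "sex": 1 if (p.sex or "m").lower().startswith("f") else 0,
        "pathology": p.pathology if p.pathology is not None else 0,
        "elecType": {"ECoG": 0, "sEEG": 1, "both": 2}[p.electrode_type],
        "i": _ordinal(p.n_channels if p.n_channels is not None else 0, _I_BINS),
        "j": _ordinal(p.n_area_channels, _J_BINS),
        "k": _ordinal(p.n_resected_channels if p.n_resected_channels is not None else 0, _K_BINS),
        "crHFOarea": 0 if cr_hfo else 1,
        "fu": _ordinal(p.follow_up_months, _FU_BINS),
    }


def outcome_lm(patients: list[PatientRecord], level: float = 0.95) -> LmResult:
    """Fit y ~ age + sex + pathology + elecType + i + j + k + crHFOarea + fu.

    y is 1 when the HFO-area prediction was correct (TP or TN), 0 otherwise;
    covariates are quantized to ordinal levels; a linear (OLS) fit is used for
    the binary response, with Benjamini-Hochberg FDR across the non-intercept
    effects. Constant covariates are dropped with a warning.
    """
    from .outcome import confusion_label, resection_status

    rows, ys = [], []
    for p in patients:
        if not p.conclusive:
            continue
        cr = resection_status(p.hfo_area, p.resected_channels)
        label = confusion_label(cr, p.ilae)
        ys.append(1.0 if label in ("TP", "TN") else 0.0)
        rows.append(quantize_patient(p, cr))
    if not rows:
        raise ValueError("no conclusive patients to model")
    x = pd.DataFrame(rows, columns=LM_EFFECTS, dtype=float)
    y = np.asarray(ys)
    if len(np.unique(y)) < 2:
        table = pd.DataFrame(
            {"estimate": 0.0, "se": np.nan, "t": np.nan, "p": np.nan, "p_fdr": np.nan},
            index=["intercept"] + LM_EFFECTS,
        )
        table.loc["intercept", "estimate"] = float(y[0])
        return LmResult(table=table, dropped=[], n=len(y))

    dropped = [c for c in x.columns if x[c].nunique() < 2]
    for c in dropped:
        warnings.warn(f"covariate {c!r} is constant and was dropped", stacklevel=2)
    kept = [c for c in x.columns if c not in dropped]
    design = add_constant(x[kept], has_constant="add")
    fit = OLS(y, design).fit()

    table = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    ).rename(index={"const": "intercept"})
    eff_idx = [c for c in kept]
    rej, p_adj, *_ = multipletests(table.loc[eff_idx, "p"], alpha=1 - level, method="fdr_bh")
    table["p_fdr"] = np.nan
    table.loc[eff_idx, "p_fdr"] = p_adj
    # keep the full effect list in the output, dropped ones as NaN rows
    full = table.reindex(["intercept"] + LM_EFFECTS)
    return LmResult(table=full, dropped=dropped, n=len(y))
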