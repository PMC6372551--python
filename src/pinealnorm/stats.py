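"""Group statistics supporting the normative analysis.

Mann-Whitney-Wilcoxon group comparisons with the tie-corrected normal
approximation, Pearson/Spearman correlations, ordinary least squares with
group-interaction terms, Cohen's d, noncentral-t power / sample-size
computation, and the extreme-PGV percentile exclusion filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .normative import as_frame

__all__ = [
    "GroupComparison",
    "RegressionResult",
    "PowerSpec",
    "mann_whitney",
    "correlate",
    "fit_linear_model",
    "cohens_d",
    "power",
    "required_n",
    "apply_exclusions",
    "DEFAULT_TERMS",
]


@dataclass(frozen=True)
class GroupComparison:
    """Two-group Mann-Whitney comparison.

    ``u`` is the U statistic of group A (number of (a, b) pairs with
    a > b, ties counting one half). The z sign convention is *positive
    when group B stochastically exceeds group A*; ``p`` is the two-sided
    normal-approximation p-value.
    """

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u: float
    z: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class RegressionResult:
    """OLS fit with overall and per-term F-tests.

    ``anova`` holds the type-II per-term F and p values (each term tested
    by comparison with the model omitting it, respecting marginality).
    """

    terms: list[str]
    params: pd.Series
    fvalue: float
    df_num: int
    df_den: int
    f_pvalue: float
    rsquared: float
    anova: pd.DataFrame
    fitted: object = field(repr=False, default=None)  # statsmodels results

    def summary(self):
        return self.fitted.summary()

    def design_matrix(self) -> pd.DataFrame:
        """The expanded design matrix, exportable to CSV for audit."""
        return pd.DataFrame(self.fitted.model.exog, columns=self.fitted.model.exog_names)


@dataclass(frozen=True)
class PowerSpec:
    """Specification of a t-test power problem.

    ``d`` is Cohen's standardized mean difference; ``design`` one of
    ``one_sample``, ``two_sample_equal``, ``two_sample_ratio`` (the latter
    with allocation ratio ``ratio`` = n_b / n_a).
    """

    d: float
    alpha: float = 0.05
    power: float = 0.80
    design: str = "two_sample_equal"
    ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.power < 1):
            raise ValueError("power must be in (0, 1)")
        if self.design not in ("one_sample", "two_sample_equal", "two_sample_ratio"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "two_sample_ratio" and self.ratio <= 0:
            raise ValueError("ratio must be > 0")


# ---------------------------------------------------------------------------
# rank-based comparison


def mann_whitney(a, b, labels=("a", "b"), continuity: bool = False) -> GroupComparison:
    """Mann-Whitney U comparison of two samples via the normal approximation.

    U is computed from midranks; the variance uses the tie correction
    ``n_a n_b / 12 * [(n + 1) - sum(t^3 - t) / (n (n - 1))]``. With all
    values tied the variance is zero and the comparison degenerates to
    z = 0, p = 1. No continuity correction is applied unless requested.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)

    n = n_a + n_b
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    mu = n_a * n_b / 2.0
    if var <= 0:
        z = 0.0
    else:
        diff = mu - u_a  # positive when b stochastically exceeds a
        if continuity and diff != 0:
            diff -= 0.5 * np.sign(diff)
        z = diff / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return GroupComparison(
        group_a=labels[0], group_b=labels[1], n_a=n_a, n_b=n_b,
        u=u_a, z=float(z), p=float(p),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)) if n_a > 1 else 0.0,
        sd_b=float(b.std(ddof=1)) if n_b > 1 else 0.0,
    )


def correlate(x, y, method: str = "pearson") -> dict:
    """Correlation with r, r^2 and a two-sided p-value.

    Pearson p comes from the t transform ``t = r sqrt((n-2)/(1-r^2))``;
    Spearman p from the large-sample normal approximation
    ``z = r sqrt(n - 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched vectors of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    n = len(x)
    if method == "pearson":
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    elif method == "spearman":
        r = float(np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1])
        z = r * np.sqrt(n - 1)
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"r": r, "r_squared": r * r, "p": p, "n": n, "method": method}


# ---------------------------------------------------------------------------
# linear model with interactions

#: Default term specification: main effects plus group interactions, the
#: confounder structure relevant when modelling plasma melatonin.
DEFAULT_TERMS = {
    "main": ["group", "age", "sex", "iq", "tbv_cm3", "pgv_mm3"],
    "interactions": [
        ("group", "age"),
        ("group", "sex"),
        ("group", "iq"),
        ("group", "tbv_cm3"),
        ("group", "pgv_mm3"),
    ],
}


def _formula_term(name: str) -> str:
    if name == "group":
        return "C(group, Treatment('control'))"
    if name == "sex":
        return "C(sex)"
    return name


def build_formula(terms: dict | None = None, outcome: str = "np.log(melatonin_nM)") -> str:
    """Patsy formula from a term specification dict with keys ``main``
    (column names) and ``interactions`` (pairs)."""
    terms = terms if terms is not None else DEFAULT_TERMS
    parts = [_formula_term(t) for t in terms.get("main", [])]
    parts += [
        f"{_formula_term(a)}:{_formula_term(b)}" for a, b in terms.get("interactions", [])
    ]
    if not parts:
        raise ValueError("term specification is empty")
    return f"{outcome} ~ " + " + ".join(parts)


def fit_linear_model(records, terms: dict | None = None,
                     outcome: str = "np.log(melatonin_nM)") -> RegressionResult:
    """OLS of (by default) log-melatonin on demographic and volumetric
    terms with group interactions.

    Categorical terms use treatment coding with ``control`` as the
    reference level. Per-term F and p values come from type-II nested
    model comparisons. A rank-deficient design raises, naming the
    collinear columns.
    """
    frame = as_frame(records)
    formula = build_formula(terms, outcome)
    model = smf.ols(formula, data=frame)
    exog = model.exog
    if len(frame) <= exog.shape[1]:
        raise ValueError(
            f"need more observations ({len(frame)}) than design columns ({exog.shape[1]})"
        )
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify columns involved in the deficiency via the QR diagonal
        _, r = np.linalg.qr(exog)
        bad = [model.exog_names[i] for i in range(exog.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(f"rank-deficient design; collinear terms: {bad or 'unidentified'}")
    fitted = model.fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anova = anova_lm(fitted, typ=2)
    return RegressionResult(
        terms=list(model.exog_names),
        params=fitted.params,
        fvalue=float(fitted.fvalue),
        df_num=int(fitted.df_model),
        df_den=int(fitted.df_resid),
        f_pvalue=float(fitted.f_pvalue),
        rsquared=float(fitted.rsquared),
        anova=anova,
        fitted=fitted,
    )


# ---------------------------------------------------------------------------
# effect size and power


def cohens_d(a, b) -> float:
    """Cohen's d: ``(mean_a - mean_b) / pooled SD`` with (n-1) weights."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD; d undefined")
    return float((a.mean() - b.mean()) / pooled)


def power(spec: PowerSpec, n: int) -> float:
    """Exact power of the two-sided t-test at per-group size ``n`` via the
    noncentral t distribution."""
    d = abs(spec.d)
    if spec.design == "one_sample":
        df = n - 1
        ncp = d * np.sqrt(n)
    elif spec.design == "two_sample_equal":
        df = 2 * n - 2
        ncp = d * np.sqrt(n / 2.0)
    else:  # two_sample_ratio: n per group A, ratio*n in group B
        n_b = max(int(np.ceil(spec.ratio * n)), 1)
        df = n + n_b - 2
        ncp = d * np.sqrt(n * n_b / (n + n_b))
    if df < 1:
        return 0.0
    tcrit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
    nt = sps.nct(df, ncp)
    return float(nt.sf(tcrit) + nt.cdf(-tcrit))


def required_n(spec: PowerSpec, n_max: int = 100000) -> int:
    """Smallest per-group n whose two-sided t-test power reaches the target.

    Searches the exact noncentral-t power (not the normal approximation)
    over integer n. For ``one_sample`` the result is the total n; for the
    two-sample designs it is the size of group A (group B holds
    ``ratio * n``).
    """
    if spec.d == 0:
        raise ValueError("power target unreachable with d = 0")
    n_min = 2  # df >= 1 in every design
    n = n_min
    while n <= n_max:
        if power(spec, n) >= spec.power:
            return n
        n += 1
    raise ValueError(f"required n exceeds {n_max}")


# ---------------------------------------------------------------------------
# percentile exclusion


def apply_exclusions(records, percentile: float = 99.0) -> dict:
    """Flag records whose PGV exceeds the empirical percentile of the
    pooled sample (screening out cyst-inflated gland volumes).

    The threshold is the linearly interpolated empirical percentile of
    the full sample, using the exclusive-CDF (Weibull / type-6) plotting
    position so that a tail of mass 1 - percentile/100 sits *above* the
    threshold; records strictly above it are excluded. With fewer than 10
    records the percentile is unstable and the filter is skipped with a
    warning.

    Returns
    -------
    dict with keys ``kept`` and ``excluded`` (DataFrames), ``threshold``
    and ``reasons`` (id -> reason for each exclusion).
    """
    frame = as_frame(records).reset_index(drop=True)
    if frame["pgv_mm3"].isna().any():
        raise ValueError("PGV must be present for all records")
    if len(frame) < 10:
        warnings.warn(
            "fewer than 10 records: percentile exclusion skipped (unstable)",
            RuntimeWarning, stacklevel=2,
        )
        return {
            "kept": frame, "excluded": frame.iloc[0:0],
            "threshold": float("nan"), "reasons": {},
        }
    pgv = frame["pgv_mm3"].to_numpy(dtype=float)
    threshold = float(np.percentile(pgv, percentile, method="weibull"))
    mask = pgv > threshold
    excluded = frame[mask]
    reasons = {
        str(r.id): f"pgv_mm3 {r.pgv_mm3:.1f} above {percentile:g}th percentile ({threshold:.1f})"
        for r in excluded.itertuples()
    }
    return {
        "kept": frame[~mask].reset_index(drop=True),
        "excluded": excluded.reset_index(drop=True),
        "threshold": threshold,
        "reasons": reasons,
    }
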