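"""Univariate test battery, multiplicity correction and logistic regression.

The battery mirrors common clinical-imaging practice: a Lilliefors-
corrected Kolmogorov-Smirnov check gates each continuous comparison
between Student's pooled-variance t-test (both groups normal) and the
Mann-Whitney U-test reported as a tie-corrected asymptotic Z without
continuity correction; baseline-vs-nadir changes use the paired t-test or
the Wilcoxon signed-rank test under the same gate; categorical covariates
use the Pearson chi-square (Yates continuity correction on 2x2 tables when
any expected count is below 5) or Fisher's exact test; pairwise post-hoc
p-values get the Holm-Bonferroni step-down; the multivariable model is a
binary logistic regression with Wald 95% confidence intervals on the odds
ratios, with the 30-40% active-marrow group as the reference level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .marrow_quant import BM_GROUPS

__all__ = [
    "ContingencyTable",
    "TestResult",
    "LogisticFit",
    "ks_normality",
    "compare_continuous",
    "paired_change",
    "chi2_test",
    "fisher_exact",
    "holm_bonferroni",
    "logistic_fit",
    "build_table3",
]

#: normality gate: samples with Lilliefors p >= ALPHA_NORMAL are treated as normal
ALPHA_NORMAL = 0.05

#: univariate screen for carrying variables into the logistic model
SCREEN_P = 0.10


@dataclass(frozen=True)
class ContingencyTable:
    """r x c count table with labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
            raise ValueError("cells must be nonnegative integers")
        if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
            raise ValueError("every row and column margin must be positive")
        object.__setattr__(self, "counts", counts.astype(int))
        if not self.row_labels:
            object.__setattr__(self, "row_labels", tuple(f"r{i}" for i in range(counts.shape[0])))
        if not self.col_labels:
            object.__setattr__(self, "col_labels", tuple(f"c{j}" for j in range(counts.shape[1])))


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    correction: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class LogisticFit:
    terms: tuple[str, ...]
    coef: np.ndarray  # log-odds
    se: np.ndarray
    odds_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_obs: int
    reference: dict[str, str] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "se": self.se,
                "odds_ratio": self.odds_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            }
        )


# ---------------------------------------------------------------------------
# continuous comparisons


def ks_normality(sample) -> TestResult:
    """Lilliefors-corrected one-sample KS test against a fitted normal.

    The sample is called normal when p >= 0.05; this gate selects the
    parametric vs rank-based branch of the continuous comparisons.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError(f"need at least 4 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return TestResult(method="ks_normality", statistic=float(stat), p_value=float(p))


def _is_normal(x) -> bool:
    """Gate decision; samples too small for the Lilliefors table (n < 4)
    fall through to the rank-based branch."""
    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.ptp(x) == 0:
        return False
    return ks_normality(x).p_value >= ALPHA_NORMAL


def _mannwhitney_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """U statistic plus tie-corrected asymptotic Z (no continuity correction)."""
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 == 0:
        return u1, 0.0, 1.0
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return u1, float(z), float(min(p, 1.0))


def compare_continuous(x, y, method: str = "auto") -> TestResult:
    """Two-group comparison with the normality gate.

    Under ``method="auto"``, both samples normal by :func:`ks_normality`
    -> two-sided pooled-variance Student t; otherwise two-sided
    Mann-Whitney U reported as the tie-corrected asymptotic Z.  The gate
    is a pure function of the two samples; ``method="t"`` or
    ``"mann_whitney"`` forces a branch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if method not in ("auto", "t", "mann_whitney"):
        raise ValueError(f"method must be auto|t|mann_whitney, got {method!r}")
    if method == "auto":
        method = "t" if (_is_normal(x) and _is_normal(y)) else "mann_whitney"
    if method == "t":
        stat, p = sps.ttest_ind(x, y, equal_var=True)
        return TestResult(method="t", statistic=float(stat), p_value=float(p))
    if np.ptp(np.concatenate([x, y])) == 0:
        return TestResult(method="mann_whitney_u", statistic=0.0, p_value=1.0, notes="identical")
    _, z, p = _mannwhitney_z(x, y)
    return TestResult(method="mann_whitney_u", statistic=z, p_value=p)


def paired_change(baseline, nadir, method: str = "auto") -> TestResult:
    """Baseline-vs-nadir paired comparison with the normality gate on differences.

    ``method="paired_t"`` or ``"wilcoxon"`` forces a branch.
    """
    b = np.asarray(baseline, dtype=float)
    n = np.asarray(nadir, dtype=float)
    if b.shape != n.shape:
        raise ValueError(f"length mismatch: {b.shape} vs {n.shape}")
    if b.size < 2:
        raise ValueError("need at least 2 pairs")
    if method not in ("auto", "paired_t", "wilcoxon"):
        raise ValueError(f"method must be auto|paired_t|wilcoxon, got {method!r}")
    d = b - n
    if np.ptp(d) == 0 and d[0] == 0:
        return TestResult(method="paired_t", statistic=0.0, p_value=1.0, notes="no change")
    if method == "auto":
        method = "paired_t" if _is_normal(d) else "wilcoxon"
    if method == "paired_t":
        stat, p = sps.ttest_rel(b, n)
        return TestResult(method="paired_t", statistic=float(stat), p_value=float(p))
    stat, p = sps.wilcoxon(b, n, alternative="two-sided", method="auto")
    return TestResult(method="wilcoxon_signed_rank", statistic=float(stat), p_value=float(p))


# ---------------------------------------------------------------------------
# categorical comparisons


def chi2_test(tab: ContingencyTable, correction: str = "auto") -> TestResult:
    """Pearson chi-square with optional Yates continuity correction.

    ``correction``: ``"none"`` plain Pearson; ``"yates"`` always corrected
    (2x2 only); ``"auto"`` applies Yates on 2x2 tables iff any expected
    count is below 5 (matching common statistical-package behavior).
    """
    counts = tab.counts
    if correction not in ("auto", "none", "yates"):
        raise ValueError(f"correction must be auto|none|yates, got {correction!r}")
    expected = sps.contingency.expected_freq(counts)
    is2x2 = counts.shape == (2, 2)
    if correction == "yates" and not is2x2:
        raise ValueError("Yates correction applies only to 2x2 tables")
    use_yates = correction == "yates" or (
        correction == "auto" and is2x2 and expected.min() < 5
    )
    stat, p, dof, _ = sps.chi2_contingency(counts, correction=use_yates)
    return TestResult(
        method="chi2_yates" if use_yates else "chi2",
        statistic=float(stat),
        p_value=float(p),
        correction=use_yates,
        notes=f"df={dof}, min_expected={expected.min():.3g}",
    )


def fisher_exact(tab: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table (hypergeometric tail sum)."""
    if tab.counts.shape != (2, 2):
        raise ValueError(f"Fisher exact requires a 2x2 table, got {tab.counts.shape}")
    _, p = sps.fisher_exact(tab.counts, alternative="two-sided")
    return TestResult(method="fisher", statistic=float("nan"), p_value=float(p))


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# logistic regression


def logistic_fit(
    design: pd.DataFrame,
    outcome,
    categorical: dict[str, str] | None = None,
) -> LogisticFit:
    """Binary logistic regression by maximum likelihood (Newton/IRLS).

    ``categorical`` maps column names to their reference level; those
    columns are dummy-coded against the reference, everything else enters
    as-is.  Odds ratios are exp(coef); confidence intervals are Wald,
    exp(coef +/- 1.96 se).  Non-convergence or separation (detected as
    exploding standard errors) raises rather than returning a silently
    broken fit.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len({0.0, 1.0} & set(np.unique(y))) < 2:
        raise ValueError("outcome must contain both classes")
    categorical = categorical or {}

    cols: dict[str, np.ndarray] = {}
    for name in design.columns:
        col = design[name]
        if name in categorical:
            ref = categorical[name]
            levels = [lv for lv in pd.unique(col) if lv != ref]
            if ref not in set(col):
                raise ValueError(f"reference level {ref!r} absent from column {name!r}")
            for lv in sorted(map(str, levels)):
                cols[f"{name}[{lv} vs {ref}]"] = (col.astype(str) == lv).to_numpy(float)
        else:
            cols[name] = col.to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    X.insert(0, "intercept", 1.0)
    if len(y) <= X.shape[1]:
        raise ValueError(f"need n > {X.shape[1]} parameters, got n = {len(y)}")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix")

    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=False, maxiter=200)
    except Exception as err:  # statsmodels raises PerfectSeparationError and friends
        raise ValueError(f"logistic fit failed: {err}") from err
    se = np.asarray(res.bse, dtype=float)
    if not res.mle_retvals.get("converged", False) or not np.isfinite(se).all() or se.max() > 1e3:
        raise ValueError("logistic fit did not converge (possible complete separation)")
    coef = np.asarray(res.params, dtype=float)
    zcrit = sps.norm.ppf(0.975)
    return LogisticFit(
        terms=tuple(X.columns),
        coef=coef,
        se=se,
        odds_ratio=np.exp(coef),
        ci_low=np.exp(coef - zcrit * se),
        ci_high=np.exp(coef + zcrit * se),
        p_values=np.asarray(res.pvalues, dtype=float),
        converged=True,
        n_obs=len(y),
        reference=dict(categorical),
    )


# ---------------------------------------------------------------------------
# cohort-level battery


CONTINUOUS_COVARIATES = (
    "age",
    "bmi",
    "max_diameter",
    "bm_act_cm3",
    "bm_act_pct",
    "suvmax",
    "mtv_cm3",
    "tlg",
)

CATEGORICAL_COVARIATES = (
    "figo",
    "differentiation",
    "parametrial_invasion",
    "ln_metastasis",
)


def crosstab_bm_groups(cohort: pd.DataFrame) -> ContingencyTable:
    """Grouped BM_ACT% (rows LT30/MID30_40/GT40) by HT group (cols G0_2/G3plus)."""
    counts = np.zeros((3, 2), dtype=int)
    for i, g in enumerate(BM_GROUPS):
        for j, h in enumerate(("G0_2", "G3plus")):
            counts[i, j] = int(((cohort["bm_group"] == g) & (cohort["ht_group"] == h)).sum())
    return ContingencyTable(counts=counts, row_labels=BM_GROUPS, col_labels=("G0_2", "G3plus"))


def build_table3(cohort: pd.DataFrame) -> dict:
    """Run the full univariate battery over a cohort table.

    Returns a dict with:

    - ``univariate``: DataFrame of per-covariate TestResults (continuous
      covariates via :func:`compare_continuous`, categorical via
      chi-square or Fisher when any 2x2 expected count is < 1),
    - ``crosstab``: the grouped BM_ACT% x HT-group ContingencyTable and
      its overall chi-square,
    - ``pairwise``: the three 2x2 group comparisons with raw and
      Holm-adjusted p-values,
    - ``screened``: covariate names passing the p < 0.1 screen for the
      logistic model.
    """
    required = {"ht_group", "bm_group", *CONTINUOUS_COVARIATES, *CATEGORICAL_COVARIATES}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    g0 = cohort[cohort["ht_group"] == "G0_2"]
    g3 = cohort[cohort["ht_group"] == "G3plus"]

    rows = []
    for name in CONTINUOUS_COVARIATES:
        res = compare_continuous(g0[name], g3[name])
        rows.append({"covariate": name, **res.__dict__})
    for name in CATEGORICAL_COVARIATES:
        levels = sorted(map(str, pd.unique(cohort[name])))
        counts = np.array(
            [
                [int((g[name].astype(str) == lv).sum()) for g in (g0, g3)]
                for lv in levels
            ]
        )
        tab = ContingencyTable(counts=counts, row_labels=tuple(levels), col_labels=("G0_2", "G3plus"))
        expected = sps.contingency.expected_freq(tab.counts)
        if tab.counts.shape == (2, 2) and expected.min() < 1:
            res = fisher_exact(tab)
        else:
            res = chi2_test(tab, correction="auto")
        rows.append({"covariate": name, **res.__dict__})

    crosstab = crosstab_bm_groups(cohort)
    overall = chi2_test(crosstab, correction="none")
    rows.append({"covariate": "bm_group", **overall.__dict__})
    univariate = pd.DataFrame(rows)

    pair_rows = []
    pairs = [("LT30", "MID30_40"), ("MID30_40", "GT40"), ("LT30", "GT40")]
    for a, b in pairs:
        ia, ib = BM_GROUPS.index(a), BM_GROUPS.index(b)
        sub = ContingencyTable(
            counts=crosstab.counts[[ia, ib], :],
            row_labels=(a, b),
            col_labels=crosstab.col_labels,
        )
        res = chi2_test(sub, correction="auto")
        pair_rows.append(
            {"pair": f"{a} vs {b}", "method": res.method, "chi2": res.statistic, "p_raw": res.p_value}
        )
    pairwise = pd.DataFrame(pair_rows)
    pairwise["p_holm"] = holm_bonferroni(pairwise["p_raw"].to_numpy())

    screened = univariate.loc[univariate["p_value"] < SCREEN_P, "covariate"].tolist()
    return {
        "univariate": univariate,
        "crosstab": crosstab,
        "overall_group_test": overall,
        "pairwise": pairwise,
        "screened": screened,
    }
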