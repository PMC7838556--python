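"""Cohort-level statistics relating the PTS score to nodal metastasis.

The analysis layer mirrors a standard retrospective cohort workup:

* a sequential exclusion ledger (rectal primary → inadequate image →
  distant metastasis) producing the analyzable cohort;
* group assignment: LNM-positive (stage III, N1/N2) vs LNM-negative
  (stages I–II, N0);
* descriptive tables by LNM group with Student's t-test (continuous) and
  Pearson chi-square (categorical) p-values;
* unadjusted logistic regression of each outcome on the PTS score with
  Wald odds-ratio confidence intervals;
* ROC AUC via the Mann–Whitney rank identity with a DeLong-style variance
  for its confidence interval;
* the same logistic analyses stratified by depth of invasion
  (T0–T2 vs T3–T4).

Flags (LI/PI/VI/AnyI) are tri-state: "yes" / "no" / missing (NA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LogisticResult",
    "RocResult",
    "apply_exclusions",
    "derive_anyi",
    "table1_descriptives",
    "logistic_univariate",
    "roc_auc",
    "subgroup_by_tstage",
]

EXCLUSION_RULES = ("rectal", "inadequate_image", "distant_metastasis")


@dataclass(frozen=True)
class LogisticResult:
    """Unadjusted logistic fit of a binary outcome on one predictor."""

    coef: float
    se: float
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int
    separation: bool = False  # flagged when the likelihood is degenerate

    def to_dict(self) -> dict:
        return {
            "coef": self.coef, "se": self.se, "odds_ratio": self.odds_ratio,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "p_value": self.p_value, "n": self.n, "separation": self.separation,
        }


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_lower: float
    ci_upper: float
    n_positive: int
    n_negative: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "ci_lower": self.ci_lower, "ci_upper": self.ci_upper,
            "n_positive": self.n_positive, "n_negative": self.n_negative,
        }


# ---------------------------------------------------------------------------
# exclusions and derived flags
# ---------------------------------------------------------------------------


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sequentially filter the accession table, keeping a removal ledger.

    Rules are applied in order (rectal primary, inadequate image, distant
    metastasis); each record is removed at most once and attributed to the
    first rule that matches it.  Missing flag columns count as False.
    The ledger counts always sum to ``len(input) - len(output)``.
    """
    remaining = records
    ledger: dict[str, int] = {}
    for rule in EXCLUSION_RULES:
        if rule in remaining.columns:
            flag = remaining[rule].fillna(False).astype(bool)
        else:
            flag = pd.Series(False, index=remaining.index)
        ledger[rule] = int(flag.sum())
        remaining = remaining.loc[~flag]
    return remaining.copy(), ledger


def derive_anyi(li, pi, vi):
    """Any-invasion flag from the three tri-state invasion flags.

    "yes" if any flag is yes; NA if none is yes but at least one is
    missing (absence cannot be asserted from incomplete data); else "no".
    Accepts scalars or aligned pandas Series.
    """
    if isinstance(li, pd.Series):
        frame = pd.concat([li, pi, vi], axis=1)
        any_yes = (frame == "yes").any(axis=1)
        any_na = frame.isna().any(axis=1)
        out = pd.Series("no", index=frame.index, dtype=object)
        out[any_na] = np.nan
        out[any_yes] = "yes"
        return out
    flags = [li, pi, vi]
    if any(f == "yes" for f in flags):
        return "yes"
    if any(pd.isna(f) for f in flags):
        return np.nan
    return "no"


# ---------------------------------------------------------------------------
# descriptive table
# ---------------------------------------------------------------------------


def table1_descriptives(
    cohort: pd.DataFrame,
    continuous: tuple[str, ...] = ("age", "pts_score"),
    categorical: tuple[str, ...] = ("sex", "t_stage", "n_stage", "li", "pi", "vi", "anyi"),
) -> dict:
    """Descriptive statistics by LNM group with univariate tests.

    Continuous variables: per-group mean (SD) and a pooled-variance
    Student's t-test.  Categorical variables: per-group counts and
    percentages of the total group size (NA shown as its own category) and
    a Pearson chi-square test without continuity correction, computed over
    non-NA rows.  Zero-variance t-test input yields a NaN p with a warning.
    """
    if "anyi" in categorical and "anyi" not in cohort.columns and {"li", "pi", "vi"} <= set(cohort.columns):
        cohort = cohort.assign(anyi=derive_anyi(cohort["li"], cohort["pi"], cohort["vi"]))
    groups = {False: cohort[~cohort["lnm"].astype(bool)], True: cohort[cohort["lnm"].astype(bool)]}
    if groups[False].empty or groups[True].empty:
        raise ValueError("both LNM groups must be nonempty")
    out: dict = {
        "n": {"lnm_negative": len(groups[False]), "lnm_positive": len(groups[True])}
    }
    for var in continuous:
        a = groups[False][var].dropna().astype(float)
        b = groups[True][var].dropna().astype(float)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            warnings.warn(f"zero variance in {var}; t-test p set to NaN")
            p = float("nan")
        else:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        out[var] = {
            "lnm_negative": {"mean": float(a.mean()), "sd": float(a.std(ddof=1))},
            "lnm_positive": {"mean": float(b.mean()), "sd": float(b.std(ddof=1))},
            "p_value": p,
        }
    for var in categorical:
        if var not in cohort.columns:
            continue
        col = cohort[var]
        levels = sorted(col.dropna().unique().tolist())
        cells: dict = {}
        for level in levels + (["NA"] if col.isna().any() else []):
            row = {}
            for pos, g in groups.items():
                sel = g[var].isna() if level == "NA" else (g[var] == level)
                count = int(sel.sum())
                row["lnm_positive" if pos else "lnm_negative"] = {
                    "count": count,
                    "pct": round(100.0 * count / len(g), 1),
                }
            cells[str(level)] = row
        # chi-square over non-NA rows, no continuity correction
        sub = cohort.dropna(subset=[var])
        table = pd.crosstab(sub[var], sub["lnm"].astype(bool))
        if table.shape[0] >= 2 and table.shape[1] == 2 and (table.values > 0).any():
            chi2, p, _, _ = stats.chi2_contingency(table.values, correction=False)
            cells_p = float(p)
        else:
            cells_p = float("nan")
        out[var] = {"levels": cells, "p_value": cells_p}
    return out


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


def logistic_univariate(x, y) -> LogisticResult:
    """Maximum-likelihood fit of ``logit P(y=1) = b0 + b1 x``.

    Returns the slope with its Wald standard error, odds ratio
    ``exp(b1)`` and Wald 95% CI ``exp(b1 ± 1.96 SE)``.  NA pairs are
    dropped listwise.  Complete or quasi-complete separation is flagged
    (``separation=True``) with infinite CI bounds rather than reported as
    a silently huge odds ratio.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    x = pd.Series(np.asarray(x, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float))
    keep = ~(x.isna() | y.isna())
    x, y = x[keep], y[keep]
    n = int(len(x))
    if y.nunique() < 2:
        raise ValueError("both outcome levels must be present")
    if x.nunique() < 2:
        raise ValueError("predictor is constant; slope is not identifiable")
    design = sm.add_constant(x.to_numpy())
    failed = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y.to_numpy(), design).fit(disp=0, maxiter=200)
        except Exception:
            failed = True
    if failed:
        warnings.warn("separation detected: odds-ratio CI bounds are unbounded")
        return LogisticResult(
            coef=float("inf"), se=float("inf"), odds_ratio=float("inf"),
            ci_lower=0.0, ci_upper=float("inf"), p_value=float("nan"),
            n=n, separation=True,
        )
    separation = any(
        issubclass(w.category, PerfectSeparationWarning)
        or "separation" in str(w.message).lower()
        for w in caught
    )
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    if separation or not np.isfinite(se) or se > 50:
        warnings.warn("separation detected: odds-ratio CI bounds are unbounded")
        return LogisticResult(
            coef=coef, se=float("inf"), odds_ratio=float(np.exp(coef)),
            ci_lower=0.0, ci_upper=float("inf"), p_value=float("nan"),
            n=n, separation=True,
        )
    z = coef / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return LogisticResult(
        coef=coef, se=se, odds_ratio=float(np.exp(coef)),
        ci_lower=float(np.exp(coef - 1.96 * se)),
        ci_upper=float(np.exp(coef + 1.96 * se)),
        p_value=p, n=n,
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> RocResult:
    """AUC by the Mann–Whitney rank identity with midrank tie handling.

    The 95% CI uses the DeLong variance estimator (structural components
    over positives and negatives), truncated to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    keep = ~np.isnan(scores)
    scores, labels = scores[keep], labels[keep]
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    ranks = stats.rankdata(scores)  # midranks
    auc = (ranks[labels].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    all_ranks = ranks
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[labels] - pos_ranks) / n          # per-positive placement
    v01 = 1.0 - (all_ranks[~labels] - neg_ranks) / m   # per-negative placement
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = 1.96 * np.sqrt(max(var, 0.0))
    return RocResult(
        auc=float(auc),
        ci_lower=float(max(auc - half, 0.0)),
        ci_upper=float(min(auc + half, 1.0)),
        n_positive=m, n_negative=n,
    )


# ---------------------------------------------------------------------------
# T-stage stratified analysis
# ---------------------------------------------------------------------------

EARLY_T = ("T0", "T1", "T2")
LATE_T = ("T3", "T4")


def subgroup_by_tstage(
    cohort: pd.DataFrame,
    outcomes: tuple[str, ...] = ("li", "pi", "vi", "anyi"),
) -> dict:
    """PTS-score association with each invasion outcome, by T-stage stratum.

    Strata are exactly {T0, T1, T2} vs {T3, T4} (a partition of the
    cohort).  Each cell reports per-level mean (SD) PTS, a t-test p, and
    the univariate logistic odds ratio of the outcome on the PTS score;
    cells with fewer than 2 events (or 2 non-events) are reported as NA.
    """
    if "anyi" in outcomes and "anyi" not in cohort.columns and {"li", "pi", "vi"} <= set(cohort.columns):
        cohort = cohort.assign(anyi=derive_anyi(cohort["li"], cohort["pi"], cohort["vi"]))
    report: dict = {}
    for name, stages in (("T0-T2", EARLY_T), ("T3-T4", LATE_T)):
        stratum = cohort[cohort["t_stage"].isin(stages)]
        cells: dict = {"n": int(len(stratum))}
        for outcome in outcomes:
            sub = stratum.dropna(subset=[outcome, "pts_score"])
            yes = sub[sub[outcome] == "yes"]["pts_score"].astype(float)
            no = sub[sub[outcome] == "no"]["pts_score"].astype(float)
            cell: dict = {
                "mean_sd_no": [float(no.mean()), float(no.std(ddof=1))] if len(no) else None,
                "mean_sd_yes": [float(yes.mean()), float(yes.std(ddof=1))] if len(yes) else None,
            }
            if len(yes) < 2 or len(no) < 2:
                cell.update({"t_p": None, "logistic": None})
            else:
                cell["t_p"] = float(stats.ttest_ind(no, yes, equal_var=True).pvalue)
                try:
                    res = logistic_univariate(
                        sub["pts_score"].astype(float), (sub[outcome] == "yes").astype(int)
                    )
                    cell["logistic"] = res.to_dict()
                except ValueError:
                    cell["logistic"] = None
            cells[outcome] = cell
        report[name] = cells
    return report
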