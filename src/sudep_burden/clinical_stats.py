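"""Cohort-description statistics for cases versus living epilepsy controls.

Categorical risk factors are tested with Fisher's exact test (2x2) or the
Pearson chi-squared test (larger tables); continuous covariates with the
two-sample t-test or the Wilcoxon rank-sum test.  Unknown entries ('.')
are excluded per row (complete-case), so each row carries its own
denominators.  Bonferroni correction is applied over the eight established
risk factors; descriptive rows outside that set are reported uncorrected.

Also provides the expected-event calculation that contextualises the
control cohort: incidence per 1000 person-years times accumulated
person-years gives the count of events the cohort would have been
expected to suffer.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .burden_analysis import wilcoxon_rank_sum
from .io_formats import TRISTATE_COLUMNS, UNKNOWN, CohortManifest

RISK_FACTORS = (
    "sex",
    "syndrome",
    "age_first_seizure",
    "epilepsy_duration",
    "n_aeds",
    "lives_alone",
    "convulsive_seizures_12m",
    "nocturnal_seizures_12m",
)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p (probability-mass rule): sum of
    hypergeometric probabilities of same-margin tables no more likely than
    the observed one.  A zero margin gives p = 1."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def pearson_chi2(table):
    """Classic Pearson chi-squared without continuity correction.

    All-zero rows/columns are dropped with a warning.  Returns
    ``(chi2, df, p)``.
    """
    t = np.asarray(table, dtype=float)
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping all-zero row(s)/column(s)", stacklevel=2)
        t = t[keep_r][:, keep_c]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2 after dropping zeros")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def ttest_from_samples(a, b, welch: bool = False) -> float:
    """Two-sided two-sample t-test p (pooled variance unless ``welch``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)


def expected_event_count(incidence_per_1000py: float,
                         person_years: float) -> tuple[float, int]:
    """Expected events from an incidence rate applied to accumulated
    person-years; returns ``(expected, rounded)``."""
    if incidence_per_1000py < 0 or person_years < 0:
        raise ValueError("incidence and person-years must be non-negative")
    expected = incidence_per_1000py * person_years / 1000.0
    return expected, int(round(expected))


# ---------------------------------------------------------------------------
# Risk-factor panel
# ---------------------------------------------------------------------------

def _two_groups(manifest: CohortManifest):
    df = manifest.table
    return (
        df[df["group"] == "case"],
        df[df["group"] == "epilepsy_control"],
    )


def _tristate_table(a: pd.Series, b: pd.Series) -> np.ndarray | None:
    """2x2 yes/no counts, complete-case; None when a margin is empty."""
    ca = a[a != UNKNOWN].value_counts()
    cb = b[b != UNKNOWN].value_counts()
    t = np.array(
        [
            [ca.get("yes", 0), ca.get("no", 0)],
            [cb.get("yes", 0), cb.get("no", 0)],
        ]
    )
    if t.sum(axis=1).min() == 0:
        return None
    return t


def risk_factor_panel(manifest: CohortManifest, n_tests: int = 8,
                      base_alpha: float = 0.05) -> pd.DataFrame:
    """Clinical comparison of cases versus epilepsy controls.

    One row per covariate with the test used, group denominators, the
    uncorrected p and the Bonferroni-corrected significance flag
    (``alpha = base_alpha / n_tests`` over the established risk factors;
    descriptive rows are reported but excluded from the correction).
    """
    case, ctrl = _two_groups(manifest)
    alpha = base_alpha / n_tests
    rows = []

    def add(covariate, test, p, n_case, n_ctrl, in_correction):
        rows.append(
            {
                "covariate": covariate,
                "test": test,
                "n_case": n_case,
                "n_ctrl": n_ctrl,
                "p_uncorrected": p,
                "in_correction": in_correction,
                "bonferroni_alpha": alpha,
                "significant": bool(
                    in_correction and p == p and p < alpha
                ),
            }
        )

    def numeric(col, test_name, in_correction=True):
        a = case[col].dropna().to_numpy(float)
        b = ctrl[col].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            add(col, test_name, np.nan, len(a), len(b), in_correction)
            return
        if test_name == "t-test":
            p = ttest_from_samples(a, b)
        else:
            _, p = wilcoxon_rank_sum(a, b)
        add(col, test_name, p, len(a), len(b), in_correction)

    numeric("age_last_followup", "t-test", in_correction=False)

    male_case = int((case["sex"] == "male").sum())
    male_ctrl = int((ctrl["sex"] == "male").sum())
    gender = np.array(
        [
            [male_case, len(case) - male_case],
            [male_ctrl, len(ctrl) - male_ctrl],
        ]
    )
    add("sex", "fisher_exact", fisher_exact_2x2(gender), len(case),
        len(ctrl), True)

    syn = pd.crosstab(
        manifest.table.loc[manifest.table["group"].isin(
            ["case", "epilepsy_control"]), "group"],
        manifest.table["syndrome"],
    )
    syn = syn.loc[:, [c for c in syn.columns if c != UNKNOWN]]
    if syn.shape[1] >= 2 and (syn.sum(axis=1) > 0).all():
        _, _, p_syn = pearson_chi2(syn.to_numpy())
    else:
        p_syn = np.nan
    add("syndrome", "pearson_chi2", p_syn, int(syn.iloc[0].sum())
        if len(syn) else 0, int(syn.iloc[-1].sum()) if len(syn) else 0, True)

    numeric("age_first_seizure", "wilcoxon_rank_sum")
    numeric("epilepsy_duration", "wilcoxon_rank_sum")

    id_t = _tristate_table(case["intellectual_disability"],
                           ctrl["intellectual_disability"])
    if id_t is not None and (id_t.sum(axis=0) > 0).all():
        _, _, p_id = pearson_chi2(id_t)
    else:
        p_id = np.nan
    add("intellectual_disability", "pearson_chi2", p_id,
        int(id_t[0].sum()) if id_t is not None else 0,
        int(id_t[1].sum()) if id_t is not None else 0, False)

    a = case["n_aeds"].dropna().to_numpy(float)
    b = ctrl["n_aeds"].dropna().to_numpy(float)
    if len(a) >= 1 and len(b) >= 1:
        _, p_aed = wilcoxon_rank_sum(a, b)
    else:
        p_aed = np.nan
    add("n_aeds", "wilcoxon_rank_sum", p_aed, len(a), len(b), True)

    for col in ("lives_alone", "convulsive_seizures_12m",
                "nocturnal_seizures_12m"):
        t = _tristate_table(case[col], ctrl[col])
        p = fisher_exact_2x2(t) if t is not None else np.nan
        add(col, "fisher_exact", p,
            int(t[0].sum()) if t is not None else 0,
            int(t[1].sum()) if t is not None else 0, True)

    return pd.DataFrame(rows)
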