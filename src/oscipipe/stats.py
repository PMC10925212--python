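"""Mixed-effects models, correlations with age, and channel-wise FDR maps.

The workhorse model relates a channel-averaged EEG measure to the study
design::

    measure ~ task + time * age + group + sex
              + (1 | participant) + (1 | participant:session)

with random intercepts for participant and for session nested within
participant.  Reference levels are task=oddball, time=evening,
group=control, sex=female, so each beta is the departure from those
baselines (age and the time:age interaction are continuous).  Estimation
is delegated to statsmodels' linear mixed model with a variance
component for the nested session intercept; REML by default.

Reported degrees of freedom follow the residual convention
``n - rank(X)`` of the fixed-effects design; test statistics are Wald
t = beta / se with two-sided p-values.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "FitResult",
    "REFERENCE_LEVELS",
    "fit_lmm",
    "channelwise_lmm",
    "pearson_by_age",
    "cross_measure_lmm",
]

REFERENCE_LEVELS = {
    "task": "oddball",
    "time": "evening",
    "group": "control",
    "sex": "female",
}


@dataclass
class FitResult:
    """Fixed-effect estimates of one mixed-model fit."""

    formula: str
    table: pd.DataFrame  # effect, beta, t, p, df
    converged: bool = True
    singular: bool = False

    def beta(self, effect: str) -> float:
        return float(self.table.set_index("effect").loc[effect, "beta"])

    def p(self, effect: str) -> float:
        return float(self.table.set_index("effect").loc[effect, "p"])

    def conf_int(self, effect: str, alpha: float = 0.05) -> tuple[float, float]:
        row = self.table.set_index("effect").loc[effect]
        df = float(row["df"])
        half = spstats.t.ppf(1 - alpha / 2, df) * float(row["se"])
        return float(row["beta"]) - half, float(row["beta"]) + half


def _treatment(term: str) -> str:
    if term in REFERENCE_LEVELS:
        return f"C({term}, Treatment('{REFERENCE_LEVELS[term]}'))"
    return term


def _expand_fixed(fixed_terms: list[str]) -> str:
    out = []
    for term in fixed_terms:
        parts = re.split(r"([*:+])", term)
        out.append("".join(_treatment(p.strip()) if p not in "*:+" else p for p in parts))
    return " + ".join(out)


def _clean_effect_names(names: pd.Index) -> list[str]:
    """C(task, Treatment('oddball'))[T.gonogo] -> task[gonogo]."""
    cleaned = []
    for name in names:
        s = re.sub(r"C\((\w+), Treatment\('[^']*'\)\)\[T\.([^\]]+)\]", r"\1[\2]", name)
        cleaned.append(s)
    return cleaned


def _fit_mixed(
    data: pd.DataFrame,
    response: str,
    fixed_terms: list[str],
    nested_session: bool = True,
    reml: bool = True,
) -> FitResult:
    cols = {response, "participant"} | (
        {"session"} if nested_session else set()
    )
    for term in fixed_terms:
        for name in re.split(r"[*:+]", term):
            cols.add(name.strip())
    data = data.dropna(subset=[c for c in cols if c in data.columns]).copy()
    if data.empty:
        raise ValueError("no complete rows to fit")
    fixed = _expand_fixed(fixed_terms)
    formula = f"{response} ~ {fixed}"
    vc = {"session": "0 + C(session)"} if nested_session else None
    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(
            formula, data, groups=data["participant"], re_formula="1", vc_formula=vc
        )
        fitted = model.fit(reml=reml)
        for w in caught:
            if issubclass(w.category, ConvergenceWarning) or "singular" in str(w.message).lower():
                singular = True
    if singular:
        warnings.warn("mixed-model fit was singular or did not fully converge; result returned")
    fe = fitted.fe_params
    se = fitted.bse_fe
    df = int(len(data) - np.linalg.matrix_rank(model.exog))
    tvals = fe / se
    pvals = 2 * spstats.t.sf(np.abs(tvals), df)
    table = pd.DataFrame(
        {
            "effect": _clean_effect_names(fe.index),
            "beta": fe.values,
            "se": se.values,
            "t": tvals.values,
            "p": pvals,
            "df": df,
        }
    )
    random_part = "(1|participant)" + (" + (1|participant:session)" if nested_session else "")
    return FitResult(
        formula=f"{response} ~ {' + '.join(fixed_terms)} + {random_part}",
        table=table,
        converged=bool(fitted.converged),
        singular=singular,
    )


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    fixed_terms: list[str] | None = None,
    nested_session: bool = True,
    reml: bool = True,
) -> FitResult:
    """Fit ``response ~ task + time*age + group + sex + (1|P) + (1|P:S)``.

    ``fixed_terms`` replaces the default fixed-effects part; terms that
    name the categorical design columns are dummy-coded against the
    reference levels (oddball / evening / control / female).  Rows with
    a missing response are dropped.
    """
    if fixed_terms is None:
        fixed_terms = ["task", "time * age", "group", "sex"]
    return _fit_mixed(table, response, fixed_terms, nested_session=nested_session, reml=reml)


def channelwise_lmm(
    tables_by_channel: dict,
    response: str,
    fixed_terms: list[str] | None = None,
    effect: str = "time[morning]",
    q: float = 0.05,
    nested_session: bool = True,
) -> pd.DataFrame:
    """Per-channel fits with Benjamini-Hochberg correction across channels.

    Default model is ``measure ~ time + task`` with the nested random
    intercepts; the p-values of ``effect`` are corrected at level ``q``.
    A channel whose fit fails is flagged missing and excluded from the
    correction count.
    """
    if fixed_terms is None:
        fixed_terms = ["time", "task"]
    rows = []
    for ch, tab in sorted(tables_by_channel.items()):
        try:
            res = _fit_mixed(tab, response, fixed_terms, nested_session=nested_session)
            rows.append(
                {"channel": ch, "beta": res.beta(effect), "p": res.p(effect), "missing": False}
            )
        except Exception as exc:
            warnings.warn(f"channel {ch} fit failed: {exc}")
            rows.append({"channel": ch, "beta": np.nan, "p": np.nan, "missing": True})
    out = pd.DataFrame(rows)
    ok = ~out["missing"]
    out["significant"] = False
    if ok.any():
        rej, _, _, _ = multipletests(out.loc[ok, "p"].values, alpha=q, method="fdr_bh")
        out.loc[ok, "significant"] = rej
    return out


def pearson_by_age(
    table: pd.DataFrame,
    measure: str,
    task: str = "oddball",
) -> dict[str, float]:
    """Correlations between age and a measure on one task's recordings.

    Restricted to ``task``; each participant's sessions are averaged
    within each time of day, then r(age, evening), r(age, morning) and
    r(age, morning - evening) are computed.  Degenerate variance yields
    NaN for that condition.
    """
    sub = table[table["task"] == task].dropna(subset=[measure])
    if sub["participant"].nunique() < 3:
        raise ValueError("need at least 3 participants for a correlation")
    mean_by_time = (
        sub.groupby(["participant", "time"], observed=True)
        .agg(age=("age", "first"), value=(measure, "mean"))
        .reset_index()
    )
    wide = mean_by_time.pivot(index="participant", columns="time", values="value")
    ages = mean_by_time.groupby("participant")["age"].first()

    def _r(values: pd.Series) -> float:
        mask = values.notna()
        x, y = ages[mask.index[mask]], values[mask]
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(spstats.pearsonr(x, y)[0])

    out = {}
    out["evening"] = _r(wide["evening"]) if "evening" in wide else float("nan")
    out["morning"] = _r(wide["morning"]) if "morning" in wide else float("nan")
    if {"evening", "morning"} <= set(wide.columns):
        out["overnight_change"] = _r(wide["morning"] - wide["evening"])
    else:
        out["overnight_change"] = float("nan")
    return out


def cross_measure_lmm(
    table: pd.DataFrame,
    response_measure: str,
    predictor_measure: str,
    nested_session: bool = True,
) -> FitResult:
    """``measure1 ~ measure2 + time*age + task`` with the random intercepts.

    Relates two measures while controlling for time of day, age and
    task; with ``nested_session=False`` the session intercept is dropped
    (the sleep-wake variant, one session per participant).
    """
    fixed = [predictor_measure, "time * age", "task"]
    return _fit_mixed(table, response_measure, fixed, nested_session=nested_session)
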