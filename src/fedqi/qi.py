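"""EUSOMA quality-indicator engine.

Five indicators are implemented declaratively (numerator, denominator,
exclusion predicates over the cohort frame, plus minimum standard and
target):

* ``QI6a`` pre-operative MRI — operated patients examined preoperatively by
  breast MRI, excluding primary systemic therapy (PST); standard 10%.
* ``QI6b`` application of MRI — PST patients undergoing MRI before/during/
  after PST, excluding distant metastasis; standard 60%, target 90%.
* ``QI9a`` single breast operation — operated patients with exactly one
  breast operation for the primary tumour, excluding reconstruction and
  DCIS-only patients; standard 80%, target 90%.
* ``QI9c`` immediate reconstruction — mastectomy patients with immediate
  reconstruction; standard 40%.
* ``QI10a`` postoperative radiotherapy — breast-conserving-therapy patients
  receiving postoperative radiotherapy, excluding distant metastasis (M1);
  standard 90%, target 95%.

Each QI yields, per country, a crude proportion with Wilson 95% CI, a
stratum-averaged (PSS-adjusted) proportion with a between-stratum normal CI,
a Mantel-Haenszel odds ratio across strata with a Robins-Breslow-Greenland
CI, and a verdict against the standard/target.  QI6a additionally drops
patients with unknown tumour size (pTx) before analysis: they are rare and
interfere with propensity stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "QIDefinition",
    "QIResult",
    "QI_DEFINITIONS",
    "assemble_cohort",
    "eligible_mask",
    "crude_proportion",
    "pss_proportion",
    "stratified_odds_ratio",
    "score_standards",
    "evaluate_qi",
]

Predicate = Callable[[pd.DataFrame], pd.Series]


@dataclass
class QIDefinition:
    qi_id: str
    name: str
    numerator: Predicate
    denominator: Predicate
    exclusion: Predicate
    analysis_exclusion: Predicate | None = None
    minimum_standard: float | None = None
    target: float | None = None
    mandatory: bool = False


def _false(frame: pd.DataFrame) -> pd.Series:
    return pd.Series(False, index=frame.index)


QI_DEFINITIONS: dict[str, QIDefinition] = {
    "QI6a": QIDefinition(
        qi_id="QI6a",
        name="Pre-operative MRI",
        numerator=lambda f: f["preop_mri"] & f["any_operation"] & ~f["pst"],
        denominator=lambda f: f["any_operation"],
        exclusion=lambda f: f["pst"],
        analysis_exclusion=lambda f: f["pt"].astype(str) == "unknown",
        minimum_standard=0.10,
        target=None,
        mandatory=False,
    ),
    "QI6b": QIDefinition(
        qi_id="QI6b",
        name="Application of MRI",
        numerator=lambda f: f["mri_around_pst"] & f["pst"],
        denominator=lambda f: f["pst"],
        exclusion=lambda f: f["distant_metastasis"],
        minimum_standard=0.60,
        target=0.90,
        mandatory=False,
    ),
    "QI9a": QIDefinition(
        qi_id="QI9a",
        name="Single breast operation",
        numerator=lambda f: f["any_operation"]
        & (f["n_breast_operations"] == 1),
        denominator=lambda f: f["any_operation"],
        exclusion=lambda f: f["any_reconstruction"] | f["dcis_only"],
        minimum_standard=0.80,
        target=0.90,
        mandatory=True,
    ),
    "QI9c": QIDefinition(
        qi_id="QI9c",
        name="Immediate reconstruction",
        numerator=lambda f: f["immediate_reconstruction"],
        denominator=lambda f: f["mastectomy"],
        exclusion=_false,
        minimum_standard=0.40,
        target=None,
        mandatory=False,
    ),
    "QI10a": QIDefinition(
        qi_id="QI10a",
        name="Postoperative radiation therapy",
        numerator=lambda f: f["postop_radiotherapy"] & f["bct"],
        denominator=lambda f: f["bct"],
        exclusion=lambda f: f["distant_metastasis"],
        minimum_standard=0.90,
        target=0.95,
        mandatory=True,
    ),
}


def eligible_mask(frame: pd.DataFrame, qi: QIDefinition) -> pd.Series:
    """Denominator minus exclusions (clinical and analysis-level)."""
    mask = qi.denominator(frame) & ~qi.exclusion(frame)
    if qi.analysis_exclusion is not None:
        mask &= ~qi.analysis_exclusion(frame)
    return mask


def assemble_cohort(frame: pd.DataFrame, qi: QIDefinition) -> pd.DataFrame:
    """The QI-eligible records (may be empty: the QI is then not
    applicable)."""
    return frame[eligible_mask(frame, qi)]


def crude_proportion(
    numerator: int, denominator: int
) -> tuple[float, tuple[float, float]]:
    """Crude proportion with Wilson score 95% CI."""
    if denominator < 1:
        raise ValueError("denominator must be at least 1")
    p = numerator / denominator
    lo, hi = proportion_confint(numerator, denominator, method="wilson")
    return p, (float(lo), float(hi))


def pss_proportion(
    stratum_numerators: np.ndarray, stratum_denominators: np.ndarray
) -> tuple[float, tuple[float, float] | None]:
    """Stratum-averaged proportion: the unweighted mean of within-stratum
    proportions, with a between-stratum normal-approximation 95% CI.

    Strata in which the country has no eligible patients are excluded.  With
    a single occupied stratum the estimate collapses to the crude proportion
    and the CI is undefined (returned as None with a warning).
    """
    num = np.asarray(stratum_numerators, dtype=float)
    den = np.asarray(stratum_denominators, dtype=float)
    occupied = den > 0
    if not occupied.any():
        raise ValueError("no occupied strata")
    props = num[occupied] / den[occupied]
    estimate = float(props.mean())
    k_eff = int(occupied.sum())
    if k_eff < 2:
        warnings.warn(
            "country present in fewer than two strata: CI undefined",
            stacklevel=2,
        )
        return estimate, None
    half = 1.96 * float(np.std(props, ddof=1)) / np.sqrt(k_eff)
    return estimate, (estimate - half, estimate + half)


def stratified_odds_ratio(
    tables: list[np.ndarray],
) -> tuple[float | None, tuple[float, float] | None]:
    """Mantel-Haenszel odds ratio across 2x2 strata with the
    Robins-Breslow-Greenland 95% CI.

    Each table is ``[[a, b], [c, d]]`` with rows = countries and columns =
    (event, no event).  Strata with both event cells zero contribute nothing
    to the MH sums and are dropped, as are strata missing a country
    entirely.  Returns (None, None) when every stratum is degenerate.
    """
    kept = []
    for t in tables:
        t = np.asarray(t, dtype=float)
        if t.shape != (2, 2):
            raise ValueError("each stratum must be a 2x2 table")
        if t.sum(axis=1).min() == 0:  # a country absent from the stratum
            continue
        if t[0, 0] == 0 and t[1, 0] == 0:  # both case cells zero
            continue
        kept.append(t)
    if not kept:
        return None, None
    n = np.array([t.sum() for t in kept])
    mh_den = sum(t[0, 1] * t[1, 0] / s for t, s in zip(kept, n))
    if mh_den == 0:
        return None, None
    st = StratifiedTable(kept)
    oratio = float(st.oddsratio_pooled)
    try:
        lo, hi = st.oddsratio_pooled_confint()
        ci = (float(lo), float(hi))
        if not np.isfinite(ci).all():
            ci = None
    except (ValueError, ZeroDivisionError, FloatingPointError):
        ci = None
    return oratio, ci


def score_standards(
    estimate: float | None, qi: QIDefinition
) -> str:
    """Verdict of the stratum-adjusted estimate against the EUSOMA
    standards; boundaries count as met (>=)."""
    if estimate is None:
        return "not_applicable"
    if qi.target is not None and estimate >= qi.target:
        return "meets_target"
    if qi.minimum_standard is not None and estimate >= qi.minimum_standard:
        return "meets_standard"
    return "below_standard"


@dataclass
class QIResult:
    qi_id: str
    name: str
    per_country: dict  # country -> crude/pss estimates, CIs, n_denominator
    odds_ratio: float | None
    or_ci: tuple[float, float] | None
    strata_used: int
    verdicts: dict  # country -> verdict string


def evaluate_qi(
    eligible_nodes,
    qi: QIDefinition,
    model=None,
    boundaries: np.ndarray | None = None,
) -> QIResult:
    """Evaluate one QI over (already QI-eligible) registry nodes.

    Per-country crude and stratum-averaged proportions, the stratified MH
    odds ratio (first country alphabetically in the numerator row), and the
    standards verdicts.  With ``model``/``boundaries`` absent everything is
    computed in a single stratum (crude analysis).
    """
    counts = pd.concat(
        [
            node.stratum_outcome_counts(qi.numerator, model, boundaries)
            for node in eligible_nodes
        ],
        ignore_index=True,
    )
    counts = (
        counts.groupby(["country", "stratum"], observed=True)
        .sum()
        .reset_index()
    )
    if (counts["numerator"] > counts["denominator"]).any():
        raise AssertionError(f"{qi.qi_id}: numerator exceeds denominator")
    countries = sorted(counts["country"].unique())
    k = int(counts["stratum"].max()) if len(counts) else 1

    per_country = {}
    verdicts = {}
    for country in countries:
        sub = counts[counts["country"] == country].set_index("stratum")
        num = sub["numerator"].reindex(range(1, k + 1), fill_value=0)
        den = sub["denominator"].reindex(range(1, k + 1), fill_value=0)
        n_den = int(den.sum())
        if n_den == 0:
            per_country[country] = {
                "crude": None, "crude_ci": None, "pss": None,
                "pss_ci": None, "n_denominator": 0,
            }
            verdicts[country] = "not_applicable"
            continue
        crude, crude_ci = crude_proportion(int(num.sum()), n_den)
        pss, pss_ci = pss_proportion(num.to_numpy(), den.to_numpy())
        per_country[country] = {
            "crude": crude, "crude_ci": crude_ci,
            "pss": pss, "pss_ci": pss_ci, "n_denominator": n_den,
        }
        verdicts[country] = score_standards(pss, qi)

    oratio, or_ci = None, None
    if len(countries) == 2:
        c1, c2 = countries
        tables = []
        for s in range(1, k + 1):
            row = {}
            for country in countries:
                sub = counts[(counts["country"] == country)
                             & (counts["stratum"] == s)]
                n_num = int(sub["numerator"].sum())
                n_den = int(sub["denominator"].sum())
                row[country] = (n_num, n_den - n_num)
            tables.append(np.array([row[c1], row[c2]], dtype=float))
        oratio, or_ci = stratified_odds_ratio(tables)

    return QIResult(
        qi_id=qi.qi_id,
        name=qi.name,
        per_country=per_country,
        odds_ratio=oratio,
        or_ci=or_ci,
        strata_used=k,
        verdicts=verdicts,
    )
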