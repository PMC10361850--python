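"""Propensity-score stratification and covariate balance diagnostics.

Released propensity scores (pooled over both countries) are cut at quantiles
into k equal-count strata.  Balance between the two countries is measured per
covariate *level* by the standardized mean difference of the level's dummy
proportion,

    SMD = (p1 - p2) / sqrt((p1 (1 - p1) + p2 (1 - p2)) / 2),

i.e. the two-proportion standardized difference; |SMD| > 0.1 flags imbalance.
After stratification the per-stratum SMDs are combined as a mean weighted by
total stratum size.  The stratum count is chosen from a candidate set by
minimizing the maximum absolute after-stratification SMD, preferring the
smallest k among near-ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "smd_level",
    "Stratification",
    "BalanceReport",
    "PropensityStratifier",
    "stratify",
    "balance_report",
    "select_strata",
]


def smd_level(p1: float, p2: float) -> float:
    """Standardized mean difference between two level proportions.

    Antisymmetric in its arguments; 0 when both proportions are 0 or both
    are 1; signed infinity in the degenerate case where one group sits at a
    boundary the other group sits at the opposite boundary of.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    if p1 == p2:
        return 0.0
    denom = np.sqrt((p1 * (1.0 - p1) + p2 * (1.0 - p2)) / 2.0)
    if denom == 0.0:
        return float(np.sign(p1 - p2) * np.inf)
    return float((p1 - p2) / denom)


@dataclass
class Stratification:
    """Quantile strata over the pooled propensity-score distribution."""

    k: int
    boundaries: np.ndarray  # k-1 ascending cut points in (0, 1)
    labels: np.ndarray  # per-patient stratum index, 1..k
    countries: np.ndarray  # per-patient country label
    per_stratum_counts: pd.DataFrame = field(default=None)  # country x stratum

    @property
    def effective_k(self) -> int:
        return len(self.boundaries) + 1


class PropensityStratifier(BaseEstimator, TransformerMixin):
    """Sklearn-style quantile stratifier: ``fit`` learns score cut points,
    ``transform`` maps scores to stratum labels 1..k (boundary ties go to
    the lower stratum)."""

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y=None):
        scores = np.asarray(X, dtype=float).ravel()
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(scores) < self.k:
            raise ValueError("need at least k scores")
        qs = np.arange(1, self.k) / self.k
        boundaries = np.quantile(scores, qs)
        unique = np.unique(boundaries)
        if len(unique) < len(boundaries):
            warnings.warn(
                "tied score quantiles: fewer effective strata than requested",
                stacklevel=2,
            )
        self.boundaries_ = unique
        return self

    def transform(self, X):
        scores = np.asarray(X, dtype=float).ravel()
        return np.searchsorted(self.boundaries_, scores, side="left") + 1


def stratify(
    scores: np.ndarray, k: int, countries: np.ndarray | None = None
) -> Stratification:
    """Cut pooled released scores into k equal-count quantile strata."""
    scores = np.asarray(scores, dtype=float).ravel()
    strat = PropensityStratifier(k=k).fit(scores)
    labels = strat.transform(scores)
    if countries is None:
        countries = np.full(len(scores), "?")
    countries = np.asarray(countries)
    counts = (
        pd.DataFrame({"country": countries, "stratum": labels})
        .groupby(["country", "stratum"])
        .size()
        .unstack(fill_value=0)
    )
    return Stratification(
        k=k,
        boundaries=strat.boundaries_,
        labels=labels,
        countries=countries,
        per_stratum_counts=counts,
    )


@dataclass
class BalanceReport:
    """Per-variable-level SMDs before and (optionally) after stratification.

    ``table`` columns: variable, level, smd_before, smd_after, flag — the
    flag marks levels whose after-stratification |SMD| (before-, when no
    stratification was applied) exceeds the threshold.
    """

    table: pd.DataFrame
    threshold: float = 0.1

    @property
    def flags(self) -> list[tuple[str, str]]:
        flagged = self.table[self.table["flag"]]
        return list(zip(flagged["variable"], flagged["level"]))

    @property
    def max_abs_before(self) -> float:
        return float(self.table["smd_before"].abs().max())

    @property
    def max_abs_after(self) -> float:
        return float(self.table["smd_after"].abs().max())

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.rename(
            columns={"smd_before": "SMD_before", "smd_after": "SMD_after"}
        )
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _two_countries(counts: pd.DataFrame) -> tuple[str, str]:
    countries = sorted(counts["country"].unique())
    if len(countries) != 2:
        raise ValueError(f"balance needs exactly two countries, "
                         f"got {countries}")
    return countries[0], countries[1]


def balance_report(
    nodes,
    model=None,
    strat: Stratification | None = None,
    covariates: list[str] | None = None,
    threshold: float = 0.1,
) -> BalanceReport:
    """Compute the two-country balance table from aggregate node queries.

    Before-stratification SMDs come from marginal per-country level
    proportions; after-stratification SMDs are computed within each stratum
    and combined as a stratum-size-weighted mean.  Strata in which one
    country has no patients are excluded from the weighted mean (warning).
    """
    marginal = pd.concat(
        [node.level_counts(covariates) for node in nodes], ignore_index=True
    )
    marginal = (
        marginal.groupby(["variable", "level", "country"], observed=True,
                         sort=False)["count"].sum().reset_index()
    )
    c1, c2 = _two_countries(marginal)
    totals = marginal.groupby("country", observed=True)["count"].sum() / len(
        marginal["variable"].unique()
    )

    per_stratum = None
    if strat is not None:
        if model is None:
            raise ValueError("after-stratification balance needs the model")
        per_stratum = pd.concat(
            [node.stratum_level_counts(model, strat.boundaries, covariates)
             for node in nodes],
            ignore_index=True,
        )
        per_stratum = (
            per_stratum.groupby(
                ["variable", "level", "country", "stratum"], observed=True,
                sort=False,
            )["count"].sum().reset_index()
        )
        stratum_sizes = (
            per_stratum[per_stratum["variable"] ==
                        per_stratum["variable"].iloc[0]]
            .groupby(["country", "stratum"], observed=True)["count"].sum()
            .unstack(fill_value=0)
        )
        usable = [
            s for s in stratum_sizes.columns
            if (stratum_sizes[s] > 0).all()
        ]
        skipped = [s for s in stratum_sizes.columns if s not in usable]
        if skipped:
            warnings.warn(
                f"strata {skipped} empty for one country; excluded from "
                "the weighted after-stratification SMD", stacklevel=2,
            )
        weights = {s: float(stratum_sizes[s].sum()) for s in usable}

    rows = []
    for (var, level), grp in marginal.groupby(["variable", "level"],
                                              observed=True, sort=False):
        by_country = grp.set_index("country")["count"]
        p1 = float(by_country.get(c1, 0)) / float(totals[c1])
        p2 = float(by_country.get(c2, 0)) / float(totals[c2])
        before = smd_level(p1, p2)
        after = np.nan
        if per_stratum is not None:
            sub = per_stratum[(per_stratum["variable"] == var)
                              & (per_stratum["level"] == level)]
            cell = sub.set_index(["country", "stratum"])["count"]
            parts, wts = [], []
            for s in weights:
                n1 = float(stratum_sizes.at[c1, s])
                n2 = float(stratum_sizes.at[c2, s])
                q1 = float(cell.get((c1, s), 0)) / n1
                q2 = float(cell.get((c2, s), 0)) / n2
                parts.append(smd_level(q1, q2))
                wts.append(weights[s])
            after = float(np.average(parts, weights=wts)) if parts else np.nan
        current = before if per_stratum is None else after
        rows.append(
            {"variable": var, "level": level, "smd_before": before,
             "smd_after": after, "flag": bool(abs(current) > threshold)}
        )
    return BalanceReport(table=pd.DataFrame(rows), threshold=threshold)


def select_strata(
    nodes,
    model,
    candidate_ks: tuple[int, ...] = (5, 6, 7, 8, 9),
    covariates: list[str] | None = None,
    threshold: float = 0.1,
    sparse_cell: int = 30,
    tie_tolerance: float = 0.01,
) -> tuple[Stratification, BalanceReport]:
    """Pick the stratum count minimizing the maximum absolute
    after-stratification |SMD|.

    Among candidates whose maximum |SMD| comes within ``tie_tolerance`` of
    the minimum, the smallest k wins (near-ties are genuine ties under
    sampling noise).  A warning is emitted when any (country, stratum) cell
    of the winner holds fewer than ``sparse_cell`` patients.
    """
    if not candidate_ks:
        raise ValueError("candidate_ks must be nonempty")
    released = [node.release_scores(model) for node in nodes]
    scores = np.concatenate([s for s, _ in released])
    countries = np.concatenate([c for _, c in released])

    results = {}
    for k in sorted(candidate_ks):
        strat = stratify(scores, k, countries)
        report = balance_report(nodes, model, strat, covariates, threshold)
        results[k] = (strat, report)
    best = min(results, key=lambda k: results[k][1].max_abs_after)
    best_val = results[best][1].max_abs_after
    for k in sorted(results):
        if results[k][1].max_abs_after <= best_val + tie_tolerance:
            best = k
            break
    strat, report = results[best]
    counts = strat.per_stratum_counts
    sparse = counts[counts < sparse_cell].stack()
    if len(sparse):
        cells = [f"{c}/stratum {s} (n={int(v)})"
                 for (c, s), v in sparse.items()]
        warnings.warn(
            "sparse propensity strata: " + "; ".join(cells), stacklevel=2,
        )
    return strat, report
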