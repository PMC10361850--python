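"""Synthetic national registry cohorts.

Emulates two national breast-cancer registries (labelled ``NL`` and ``NO``)
whose categorical covariate margins follow the published composition of the
Dutch and Norwegian invasive breast cancer cohorts diagnosed 2017-2018
(32,786 and 6,377 patients).  Covariates are sampled independently per the
margins — only margins, not joint distributions, are publicly reported — and
each treatment/outcome flag is drawn from a logistic assignment model in the
covariates, so that downstream estimators can be checked by parameter
recovery against known truth.

Flag dependencies that a registry would enforce structurally (immediate
reconstruction only with mastectomy, operation counts only for operated
patients, MRI around systemic therapy only for treated patients) are applied
as gates after sampling; breast-conserving therapy is the complement of
mastectomy among operated patients.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import write_cohort
from .schema import COVARIATES, LEVELS, coerce_frame, frame_to_records

__all__ = [
    "AssignmentModel",
    "RegistryConfig",
    "SyntheticCohort",
    "ConfigError",
    "generate_registry",
    "make_two_country_scenario",
    "default_config",
    "confounded_scenario",
    "TABLE_COUNTS",
]


class ConfigError(ValueError):
    """Registry configuration violates its invariants."""


#: Published cohort composition used as the default margins: per-level patient
#: counts for the Dutch (NL, N=32786) and Norwegian (NO, N=6377) registries.
TABLE_COUNTS: dict[str, dict[str, dict[str, int]]] = {
    "NL": {
        "year": {"2017": 16567, "2018": 16219},
        "age_band": {"<40": 1758, "40-49": 4479, "50-59": 7614,
                     "60-69": 8329, "70-79": 6653, "80+": 3953},
        "histology": {"ductal": 25146, "lobular": 4292, "other": 3348},
        "grade": {"well": 7156, "moderate": 15434, "poor": 7336,
                  "unknown": 2860},
        "pt": {"<2cm": 18430, "2-5cm": 6751, "5+cm": 1142, "unknown": 6463},
        "pn": {"pN0": 19520, "pN1-3": 6684, "pN4+": 1261, "unknown": 5321},
        "her2": {"negative": 27376, "positive": 4168, "unknown": 1242},
        "er": {"negative": 5011, "positive": 27417, "unknown": 358},
        "pr": {"negative": 10100, "positive": 22306, "unknown": 380},
    },
    "NO": {
        "year": {"2017": 3230, "2018": 3147},
        "age_band": {"<40": 342, "40-49": 938, "50-59": 1630,
                     "60-69": 1807, "70-79": 1152, "80+": 508},
        "histology": {"ductal": 4975, "lobular": 791, "other": 611},
        "grade": {"well": 1372, "moderate": 2789, "poor": 1515,
                  "unknown": 701},
        "pt": {"<2cm": 3711, "2-5cm": 1573, "5+cm": 104, "unknown": 989},
        "pn": {"pN0": 3941, "pN1-3": 1508, "pN4+": 237, "unknown": 691},
        "her2": {"negative": 5464, "positive": 829, "unknown": 84},
        "er": {"negative": 906, "positive": 5393, "unknown": 78},
        "pr": {"negative": 1944, "positive": 4358, "unknown": 75},
    },
}

COHORT_SIZES = {"NL": 32786, "NO": 6377}


@dataclass
class AssignmentModel:
    """Logistic model on the log-odds scale: intercept plus one coefficient
    per non-reference covariate level, keyed ``var=level``."""

    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(frame), self.intercept)
        for key, coef in self.coefficients.items():
            var, level = key.split("=", 1)
            if var not in LEVELS:
                raise ConfigError(f"assignment model refers to unknown "
                                  f"covariate {var!r}")
            lp += coef * (frame[var].astype(str) == level).to_numpy()
        return lp


@dataclass
class RegistryConfig:
    country_label: str
    n_patients: int
    covariate_margins: dict[str, dict[str, float]]
    assignment_models: dict[str, AssignmentModel]
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        for var, margin in self.covariate_margins.items():
            if var not in LEVELS:
                raise ConfigError(f"unknown covariate {var!r} in margins")
            probs = np.array(list(margin.values()), dtype=float)
            if (probs < 0).any() or (probs > 1).any():
                raise ConfigError(f"{var}: probabilities outside [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{var}: probabilities sum to "
                                  f"{probs.sum()!r}, not 1")
            undeclared = set(margin) - set(LEVELS[var])
            if undeclared:
                raise ConfigError(f"{var}: undeclared levels {undeclared}")


@dataclass
class SyntheticCohort:
    frame: pd.DataFrame
    true_assignment_models: dict[str, AssignmentModel]
    generator_seed: int
    country_label: str

    @property
    def records(self):
        return frame_to_records(self.frame)

    def write(self, directory: str | Path, stem: str | None = None) -> Path:
        """Write the cohort CSV plus a JSON sidecar holding the truth
        (assignment models and seed)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = stem or f"cohort_{self.country_label}"
        csv_path = directory / f"{stem}.csv"
        write_cohort(self.frame, csv_path)
        truth = {
            "country_label": self.country_label,
            "generator_seed": self.generator_seed,
            "assignment_models": {
                name: {"intercept": m.intercept,
                       "coefficients": m.coefficients}
                for name, m in self.true_assignment_models.items()
            },
        }
        (directory / f"{stem}.truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True)
        )
        return csv_path


def _draw(rng, model, frame) -> np.ndarray:
    return rng.random(len(frame)) < expit(model.linear_predictor(frame))


def generate_registry(config: RegistryConfig) -> SyntheticCohort:
    """Sample one registry cohort: covariates from the margins, flags from
    the assignment models, structural gates applied last.

    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    data: dict[str, np.ndarray | str] = {}
    for var in COVARIATES:
        margin = config.covariate_margins.get(var)
        if margin is None:
            raise ConfigError(f"margins missing covariate {var!r}")
        levels = list(margin)
        probs = np.array(list(margin.values()), dtype=float)
        idx = rng.choice(len(levels), size=n, p=probs / probs.sum())
        data[var] = np.array(levels, dtype=object)[idx]
    frame = pd.DataFrame(data)
    frame["country"] = config.country_label

    models = config.assignment_models

    def draw(name: str, default: bool = False) -> np.ndarray:
        if name in models:
            return _draw(rng, models[name], frame)
        return np.full(n, default)

    frame["distant_metastasis"] = draw("distant_metastasis")
    frame["pst"] = draw("pst")
    frame["any_operation"] = draw("any_operation", default=True)
    frame["preop_mri"] = draw("preop_mri")
    frame["mri_around_pst"] = draw("mri_around_pst") & frame["pst"]
    frame["mastectomy"] = draw("mastectomy") & frame["any_operation"]
    frame["bct"] = frame["any_operation"] & ~frame["mastectomy"]
    reop = draw("reoperation")
    frame["n_breast_operations"] = np.where(
        frame["any_operation"], 1 + reop.astype(int), 0
    )
    frame["immediate_reconstruction"] = (
        draw("immediate_reconstruction") & frame["mastectomy"]
    )
    delayed = draw("delayed_reconstruction") & frame["mastectomy"]
    frame["any_reconstruction"] = frame["immediate_reconstruction"] | delayed
    frame["postop_radiotherapy"] = draw("postop_radiotherapy") & frame["bct"]
    frame["dcis_only"] = draw("dcis_only")

    structured = {
        "distant_metastasis", "pst", "any_operation", "preop_mri",
        "mri_around_pst", "mastectomy", "reoperation",
        "immediate_reconstruction", "delayed_reconstruction",
        "postop_radiotherapy", "dcis_only",
    }
    # generic extra outcomes (e.g. for parameter-recovery studies): plain
    # Bernoulli draws from their logistic model, no gating
    for name, model in models.items():
        if name not in structured:
            frame[name] = _draw(rng, model, frame)

    extra = _extra_names(frame)
    cohort_frame = coerce_frame(frame.drop(columns=extra))
    for name in extra:
        cohort_frame[name] = frame[name].astype(bool).to_numpy()
    return SyntheticCohort(
        frame=cohort_frame,
        true_assignment_models=dict(models),
        generator_seed=config.seed,
        country_label=config.country_label,
    )


def _extra_names(frame: pd.DataFrame) -> list[str]:
    from .schema import COLUMNS

    return [c for c in frame.columns if c not in COLUMNS]


def make_two_country_scenario(
    nl_config: RegistryConfig, no_config: RegistryConfig
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Generate a pair of cohorts for a two-country comparison."""
    if nl_config.country_label == no_config.country_label:
        raise ConfigError("country labels must be distinct")
    return generate_registry(nl_config), generate_registry(no_config)


# --------------------------------------------------------------------------
# default parameterization

def _margins_from_counts(counts: dict[str, dict[str, int]]):
    return {
        var: {lvl: c / sum(m.values()) for lvl, c in m.items()}
        for var, m in counts.items()
    }


def _default_models(country: str) -> dict[str, AssignmentModel]:
    """Default treatment/outcome assignment models.

    Intercepts differ by country where the two systems plausibly differ in
    practice (MRI use, reoperation rates, systemic-therapy uptake); covariate
    effects are shared.  Values are on the log-odds scale and chosen to land
    the flag prevalences near realistic registry rates.
    """
    nl = country == "NL"
    age_decline = {"age_band=50-59": -0.3, "age_band=60-69": -0.6,
                   "age_band=70-79": -1.2, "age_band=80+": -2.0}
    return {
        "distant_metastasis": AssignmentModel(-3.6, {
            "pt=2-5cm": 0.8, "pt=5+cm": 1.6,
            "pn=pN1-3": 0.7, "pn=pN4+": 1.5}),
        "pst": AssignmentModel(-1.9 if nl else -2.6, {
            "pt=2-5cm": 1.2, "pt=5+cm": 2.2, "her2=positive": 1.0,
            **age_decline}),
        "any_operation": AssignmentModel(3.2, {
            "age_band=70-79": -0.8, "age_band=80+": -2.0,
            "pt=unknown": -1.8}),
        "preop_mri": AssignmentModel(-0.9 if nl else -1.9, {
            "histology=lobular": 1.2, "age_band=70-79": -0.5,
            "age_band=80+": -1.2, "year=2018": 0.1}),
        "mri_around_pst": AssignmentModel(1.7 if nl else 0.9, {
            "her2=positive": 0.3}),
        "mastectomy": AssignmentModel(-1.0, {
            "pt=2-5cm": 1.0, "pt=5+cm": 2.2, "histology=lobular": 0.5,
            "age_band=80+": 0.8, "pt=unknown": 0.3}),
        "reoperation": AssignmentModel(-3.1 if nl else -2.5, {
            "pt=5+cm": 0.5, "histology=lobular": 0.4}),
        "immediate_reconstruction": AssignmentModel(-0.35 if nl else -0.30, {
            "age_band=60-69": -0.5, "age_band=70-79": -1.4,
            "age_band=80+": -2.8}),
        "delayed_reconstruction": AssignmentModel(-2.2),
        "postop_radiotherapy": AssignmentModel(3.0 if nl else 3.2, {
            "age_band=80+": -1.3}),
        "dcis_only": AssignmentModel(-4.2),
    }


def default_config(
    country: str, n_patients: int | None = None, seed: int | None = None
) -> RegistryConfig:
    """Default registry configuration for ``country`` in {"NL", "NO"}:
    margins derived from the published cohort counts, default assignment
    models, and the documented default seed (11 for NL, 13 for NO)."""
    if country not in TABLE_COUNTS:
        raise ConfigError(f"no default configuration for {country!r}")
    if seed is None:
        seed = {"NL": 11, "NO": 13}[country]
    return RegistryConfig(
        country_label=country,
        n_patients=n_patients or COHORT_SIZES[country],
        covariate_margins=_margins_from_counts(TABLE_COUNTS[country]),
        assignment_models=_default_models(country),
        seed=seed,
    )


# --------------------------------------------------------------------------
# confounded study scenario for balance / parameter-recovery experiments

#: Margins for the comparison country in the confounded scenario: older, worse
#: grade and heavier nodal involvement than the reference margins, so that
#: several covariate levels are imbalanced (|SMD| > 0.1) before stratification.
_CONFOUNDED_SHIFTS = {
    "age_band": {"<40": 0.02, "40-49": 0.08, "50-59": 0.18,
                 "60-69": 0.27, "70-79": 0.27, "80+": 0.18},
    "grade": {"well": 0.12, "moderate": 0.38, "poor": 0.38, "unknown": 0.12},
    "pn": {"pN0": 0.45, "pN1-3": 0.32, "pN4+": 0.08, "unknown": 0.15},
}

#: Outcome model used in recovery experiments: risk increases with age,
#: grade and nodal stage (the same covariates whose margins are shifted, so
#: the crude country comparison is confounded).
_RECOVERY_OUTCOME = AssignmentModel(-1.2, {
    "age_band=40-49": 0.05, "age_band=50-59": 0.1, "age_band=60-69": 0.2,
    "age_band=70-79": 0.3, "age_band=80+": 0.35,
    "grade=moderate": 0.2, "grade=poor": 0.4, "grade=unknown": 0.1,
    "pn=pN1-3": 0.3, "pn=pN4+": 0.4, "pn=unknown": 0.1,
})


def confounded_scenario(
    seed: int,
    n_ref: int = 3000,
    n_other: int = 3000,
    gamma: float = 0.0,
    outcome: str = "study_outcome",
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Two-country scenario with known confounding and a known country effect.

    The reference country keeps the default NL margins; the other country is
    older with worse grade and nodal stage.  Both carry a synthetic outcome
    whose risk depends on those covariates; the reference country's log-odds
    are shifted by ``gamma``, so the true conditional odds ratio
    (reference vs other) is ``exp(gamma)``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2)
    ref_outcome = AssignmentModel(
        _RECOVERY_OUTCOME.intercept + gamma, dict(_RECOVERY_OUTCOME.coefficients)
    )
    ref = default_config("NL", n_patients=n_ref, seed=int(seeds[0]) % 2**31)
    ref = dataclasses.replace(
        ref, assignment_models={**ref.assignment_models, outcome: ref_outcome}
    )
    other_margins = {**_margins_from_counts(TABLE_COUNTS["NL"]),
                     **_CONFOUNDED_SHIFTS}
    other = RegistryConfig(
        country_label="NO",
        n_patients=n_other,
        covariate_margins=other_margins,
        assignment_models={**_default_models("NO"),
                           outcome: _RECOVERY_OUTCOME},
        seed=int(seeds[1]) % 2**31,
    )
    return make_two_country_scenario(ref, other)
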