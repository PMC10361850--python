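"""End-to-end benchmark orchestration.

``run_benchmark`` drives the full comparison for every quality indicator:
assemble the QI-eligible population inside each registry node, fit the
federated propensity model for that population (the eligible populations —
and hence the covariate balance — differ per QI, so the model is refitted
per QI), pick the stratum count with the best balance, and produce crude and
stratum-adjusted proportions, the stratified odds ratio, and the standards
verdicts.  ``validate_against_pooled`` reruns each propensity fit as a
centralized logistic regression on the pooled rows (statsmodels GLM) and
tabulates the coefficient discrepancy — the federated fit is algebraically
identical, so discrepancies sit at solver-tolerance level.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from .federation import FederatedLogisticRegression, RegistryNode
from .io import encode, read_cohort
from .qi import QI_DEFINITIONS, QIResult, eligible_mask, evaluate_qi
from .schema import COVARIATES
from .stratification import select_strata
from .synthetic import default_config, generate_registry

logger = logging.getLogger("fedqi")

__all__ = ["RunConfig", "BenchmarkReport", "run_benchmark",
           "validate_against_pooled", "load_config", "simulate_to_csv"]


@dataclass
class RunConfig:
    """Benchmark run configuration (one input mode: synthetic or csv)."""

    mode: str = "synthetic"
    countries: dict = field(
        default_factory=lambda: {"NL": {}, "NO": {}}
    )  # synthetic: {country: {n_patients}}; csv: {country: {path}}
    reference_country: str = "NL"
    covariates: list[str] = field(default_factory=lambda: list(COVARIATES))
    candidate_strata: list[int] = field(
        default_factory=lambda: [5, 6, 7, 8, 9]
    )
    smd_threshold: float = 0.1
    tol: float = 1e-8
    max_iter: int = 25
    seed: int = 2017
    out_dir: str = "fedqi_out"

    def validate(self) -> None:
        if self.mode not in {"synthetic", "csv"}:
            raise ValueError(f"unknown input mode {self.mode!r}")
        if len(self.countries) < 2:
            raise ValueError("need at least two countries")
        if self.reference_country not in self.countries:
            raise ValueError("reference country missing from countries")


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def _load_frames(config: RunConfig) -> dict[str, pd.DataFrame]:
    config.validate()
    frames = {}
    if config.mode == "synthetic":
        seeds = np.random.SeedSequence(config.seed).generate_state(
            len(config.countries)
        )
        for (country, opts), s in zip(sorted(config.countries.items()),
                                      seeds):
            reg = default_config(
                country,
                n_patients=opts.get("n_patients"),
                seed=int(s) % 2**31,
            )
            frames[country] = generate_registry(reg).frame
    else:
        for country, opts in sorted(config.countries.items()):
            frame, report = read_cohort(opts["path"], country=country)
            if not report.ok:
                logger.warning(
                    "%s: %d validation violations", country,
                    len(report.violations),
                )
            frames[country] = frame
    return frames


def _build_nodes(config: RunConfig,
                 frames: dict[str, pd.DataFrame]) -> list[RegistryNode]:
    return [
        RegistryNode(country, frame, config.covariates)
        for country, frame in sorted(frames.items())
    ]


@dataclass
class BenchmarkReport:
    results: dict  # qi_id -> QIResult
    balance: dict  # qi_id -> BalanceReport
    models: dict  # qi_id -> FederatedLogisticRegression
    failures: dict  # qi_id -> error message

    def to_frame(self) -> pd.DataFrame:
        """Human-readable benchmark table, one row per (QI, country)."""
        rows = []
        for qi_id, res in self.results.items():
            qi = QI_DEFINITIONS[qi_id]
            for country, est in res.per_country.items():
                rows.append({
                    "qi": qi_id,
                    "name": res.name,
                    "country": country,
                    "n": est["n_denominator"],
                    "crude_pct": _pct(est["crude"]),
                    "crude_ci": _ci_pct(est["crude_ci"]),
                    "pss_pct": _pct(est["pss"]),
                    "pss_ci": _ci_pct(est["pss_ci"]),
                    "strata": res.strata_used,
                    "odds_ratio": None if res.odds_ratio is None
                    else round(res.odds_ratio, 2),
                    "or_ci": _ci_plain(res.or_ci),
                    "minimum_standard": _pct(qi.minimum_standard),
                    "target": _pct(qi.target),
                    "verdict": res.verdicts[country],
                })
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {}
        for qi_id, res in self.results.items():
            payload[qi_id] = {
                "name": res.name,
                "per_country": res.per_country,
                "odds_ratio": res.odds_ratio,
                "or_ci": res.or_ci,
                "strata_used": res.strata_used,
                "verdicts": res.verdicts,
            }
        payload["failures"] = self.failures
        (out / "results.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True, default=list)
        )
        self.to_frame().to_csv(out / "benchmark.tsv", sep="\t", index=False)
        for qi_id, report in self.balance.items():
            report.to_tsv(out / f"balance_{qi_id}.tsv")
        for qi_id, model in self.models.items():
            model.to_json(out / f"propensity_{qi_id}.json")


def _pct(x):
    return None if x is None else round(100.0 * x, 1)


def _ci_pct(ci):
    if ci is None:
        return None
    return f"{100 * ci[0]:.1f}-{100 * ci[1]:.1f}"


def _ci_plain(ci):
    if ci is None:
        return None
    return f"{ci[0]:.2f}-{ci[1]:.2f}"


def run_benchmark(config: RunConfig) -> BenchmarkReport:
    """Run the full federated benchmark; deterministic given
    ``config.seed``.  A failure in one QI is logged and the remaining QIs
    are still attempted."""
    frames = _load_frames(config)
    nodes = _build_nodes(config, frames)
    results, balance, models, failures = {}, {}, {}, {}
    audit_nodes = list(nodes)
    for qi_id, qi in QI_DEFINITIONS.items():
        try:
            eligible = _eligible_nodes(nodes, qi)
            countries = {c for n in eligible for c in n.countries()}
            if len(countries) < 2:
                raise ValueError(
                    f"eligible patients found for {sorted(countries)} only"
                )
            model = FederatedLogisticRegression(
                tol=config.tol, max_iter=config.max_iter
            ).fit(eligible, config.reference_country)
            logger.info(
                "%s: federated fit converged=%s after %d iterations "
                "(deviance %.3f)", qi_id, model.converged_, model.n_iter_,
                model.deviance_,
            )
            strat, report = select_strata(
                eligible, model,
                candidate_ks=tuple(config.candidate_strata),
                covariates=config.covariates,
                threshold=config.smd_threshold,
            )
            results[qi_id] = evaluate_qi(eligible, qi, model,
                                         strat.boundaries)
            balance[qi_id] = report
            models[qi_id] = model
            audit_nodes.extend(eligible)
        except Exception as exc:  # keep going: one QI must not sink the run
            logger.exception("%s failed", qi_id)
            failures[qi_id] = str(exc)
    report = BenchmarkReport(results, balance, models, failures)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.write(out)
    audit_path = out / "audit.jsonl"
    audit_path.unlink(missing_ok=True)
    for node in audit_nodes:
        node.write_audit_log(audit_path)
    return report


def _eligible_nodes(nodes: list[RegistryNode],
                    qi) -> list[RegistryNode]:
    eligible = []
    for node in nodes:
        try:
            eligible.append(
                node.subset(lambda f: eligible_mask(f, qi), qi.qi_id)
            )
        except ValueError:
            logger.warning("node %s: no eligible patients for %s",
                           node.node_id, qi.qi_id)
    if not eligible:
        raise ValueError(f"no eligible patients anywhere for {qi.qi_id}")
    return eligible


def pooled_logistic_fit(
    frames: dict[str, pd.DataFrame],
    reference_country: str,
    covariates: list[str],
    drop_columns: list[str] = (),
):
    """Centralized oracle: statsmodels GLM logistic fit on the pooled rows.

    Explicitly *not* federated — this is the validation route that a
    registry could only run after pooling patient-level data.
    """
    pooled = pd.concat(frames.values(), ignore_index=True)
    design = encode(pooled, covariates, drop_constant=False)
    keep = [i for i, c in enumerate(design.column_names)
            if c not in set(drop_columns)]
    X = design.values[:, keep]
    y = (pooled["country"] == reference_country).to_numpy(float)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    names = [design.column_names[i] for i in keep]
    return names, np.asarray(fit.params)


def validate_against_pooled(config: RunConfig) -> pd.DataFrame:
    """Per-QI comparison of federated vs pooled (centralized) propensity
    coefficients; returns a table with the maximum absolute discrepancy."""
    frames = _load_frames(config)
    nodes = _build_nodes(config, frames)
    rows = []
    for qi_id, qi in QI_DEFINITIONS.items():
        eligible = _eligible_nodes(nodes, qi)
        model = FederatedLogisticRegression(
            tol=config.tol, max_iter=config.max_iter
        ).fit(eligible, config.reference_country)
        eligible_frames = {
            c: assemble(frames[c], qi) for c in sorted(frames)
        }
        eligible_frames = {c: f for c, f in eligible_frames.items()
                           if not f.empty}
        names, pooled_beta = pooled_logistic_fit(
            eligible_frames, config.reference_country, config.covariates,
            drop_columns=model.dropped_columns_,
        )
        fed_beta = np.array([
            model.coef_[model.column_names_.index(c)] for c in names
        ])
        rows.append({
            "qi": qi_id,
            "n_coefficients": len(names),
            "max_abs_discrepancy": float(np.abs(fed_beta - pooled_beta).max()),
            "federated_converged": model.converged_,
        })
    return pd.DataFrame(rows)


def assemble(frame: pd.DataFrame, qi) -> pd.DataFrame:
    from .qi import assemble_cohort

    return assemble_cohort(frame, qi)


def simulate_to_csv(config: RunConfig, out_dir: str | Path) -> list[Path]:
    """Generate the configured synthetic cohorts and write them (CSV plus
    truth sidecars) to ``out_dir``."""
    if config.mode != "synthetic":
        raise ValueError("simulate requires a synthetic-mode config")
    paths = []
    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(config.countries)
    )
    for (country, opts), s in zip(sorted(config.countries.items()), seeds):
        reg = default_config(
            country, n_patients=opts.get("n_patients"),
            seed=int(s) % 2**31,
        )
        cohort = generate_registry(reg)
        paths.append(cohort.write(out_dir))
    return paths
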