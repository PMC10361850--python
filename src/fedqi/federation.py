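"""Simulated horizontal federation and the federated logistic regression.

Each :class:`RegistryNode` holds its patient rows privately and answers only
aggregate queries — per-iteration IRLS sufficient statistics (a p x p matrix
and a p-vector), level counts, and stratum-level count tables — whose
dimension never depends on the number of records.  The single per-record
release is the propensity-score vector (score plus country label), matching
the protocol in which fitted scores, void of identifying information, are
sent to the investigator.  Every exchange is recorded in the node's audit
log.

The aggregator runs iteratively reweighted least squares (IRLS): logistic
regression needs only Sum(w_i x_i x_i^T) and Sum(w_i x_i z_i) per iteration,
and both are additive across nodes, so the federated fit is algebraically the
same computation as a centralized fit on the pooled rows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .io import DesignMatrix, encode
from .schema import COVARIATES

__all__ = [
    "RegistryNode",
    "IRLSPartial",
    "FederatedLogisticRegression",
    "PropensityModel",
    "federated_fit",
    "local_irls_partial",
    "release_scores",
]

_WEIGHT_FLOOR = 1e-10
_MU_EPS = 1e-12


@dataclass
class IRLSPartial:
    """One node's contribution to an IRLS iteration."""

    xtwx: np.ndarray  # p x p, Sum(w_i x_i x_i^T)
    xtwz: np.ndarray  # p,    Sum(w_i x_i z_i)
    deviance: float
    n: int


class RegistryNode:
    """A data silo: private records, aggregate-only interface."""

    def __init__(
        self,
        node_id: str,
        frame: pd.DataFrame,
        covariates: list[str] | None = None,
    ):
        if frame.empty:
            raise ValueError(f"node {node_id!r} holds no records")
        self.node_id = node_id
        self._frame = frame.reset_index(drop=True)
        self._covariates = list(covariates or COVARIATES)
        # fixed declared-level encoding so every node shares one column set
        self._design: DesignMatrix = encode(
            self._frame, self._covariates, drop_constant=False
        )
        self.audit_log: list[dict] = []

    # -- aggregate interface ------------------------------------------------

    @property
    def column_names(self) -> list[str]:
        return self._design.column_names

    @property
    def n_records(self) -> int:
        return len(self._frame)

    def countries(self) -> list[str]:
        return sorted(self._frame["country"].unique())

    def subset(self, mask_fn, suffix: str) -> "RegistryNode":
        """A node over the rows selected by ``mask_fn(frame)``.

        Local computation: nothing leaves the silo.  Raises ``ValueError``
        when no rows qualify.
        """
        mask = np.asarray(mask_fn(self._frame), dtype=bool)
        return RegistryNode(
            f"{self.node_id}/{suffix}", self._frame[mask], self._covariates
        )

    def irls_partial(self, beta: np.ndarray, membership_label: str) -> IRLSPartial:
        """Sufficient statistics for one IRLS step at ``beta``.

        The membership outcome is y_i = 1 when the record belongs to the
        reference country ``membership_label``.  Working weights near zero
        (fitted probabilities at 0 or 1) are floored at 1e-10 with a warning.
        """
        X = self._design.values
        if len(beta) != X.shape[1]:
            raise ValueError("beta length does not match design width")
        y = (self._frame["country"] == membership_label).to_numpy(float)
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        if (w < _WEIGHT_FLOOR).any():
            warnings.warn(
                f"node {self.node_id}: IRLS weights floored at {_WEIGHT_FLOOR}",
                stacklevel=2,
            )
            w = np.maximum(w, _WEIGHT_FLOOR)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        mu_c = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
        deviance = -2.0 * float(
            y @ np.log(mu_c) + (1.0 - y) @ np.log1p(-mu_c)
        )
        partial = IRLSPartial(X.T @ Xw, Xw.T @ z, deviance, len(y))
        self.audit_log.append(
            {"operation": "irls_partial",
             "payload_dim": [list(partial.xtwx.shape),
                             [len(partial.xtwz)], [1], [1]]}
        )
        return partial

    def release_scores(self, model: "FederatedLogisticRegression"):
        """The one per-record release: (propensity score, country label)."""
        X = self._design.values
        beta = model.coef_
        if len(beta) != X.shape[1]:
            raise ValueError("model width does not match node design")
        scores = expit(X @ beta)
        countries = self._frame["country"].to_numpy()
        self.audit_log.append(
            {"operation": "release_scores", "payload_dim": "per-record",
             "fields": ["score", "country"]}
        )
        return scores, countries

    def level_counts(self, covariates: list[str] | None = None) -> pd.DataFrame:
        """Per-country covariate level counts (aggregate: dimension =
        number of declared levels x countries)."""
        covariates = list(covariates or self._covariates)
        rows = []
        for var in covariates:
            counts = (
                self._frame.groupby(["country", var], observed=False)
                .size()
                .rename("count")
                .reset_index()
            )
            counts.insert(0, "variable", var)
            counts = counts.rename(columns={var: "level"})
            rows.append(counts)
        out = pd.concat(rows, ignore_index=True)
        self.audit_log.append(
            {"operation": "level_counts", "payload_dim": [len(out)]}
        )
        return out

    def stratum_level_counts(
        self,
        model: "FederatedLogisticRegression",
        boundaries: np.ndarray,
        covariates: list[str] | None = None,
    ) -> pd.DataFrame:
        """Covariate level counts per (country, stratum) given score cut
        points — dimension k x levels x countries, independent of n."""
        covariates = list(covariates or self._covariates)
        scores = expit(self._design.values @ model.coef_)
        stratum = np.searchsorted(boundaries, scores, side="left") + 1
        rows = []
        for var in covariates:
            tab = (
                self._frame.assign(stratum=stratum)
                .groupby(["country", "stratum", var], observed=False)
                .size()
                .rename("count")
                .reset_index()
                .rename(columns={var: "level"})
            )
            tab.insert(0, "variable", var)
            rows.append(tab)
        out = pd.concat(rows, ignore_index=True)
        self.audit_log.append(
            {"operation": "stratum_level_counts", "payload_dim": [len(out)]}
        )
        return out

    def stratum_outcome_counts(
        self,
        numerator_fn,
        model: "FederatedLogisticRegression | None",
        boundaries: np.ndarray | None,
    ) -> pd.DataFrame:
        """Per-(country, stratum) numerator and denominator counts for a QI
        evaluated on this node's (already QI-eligible) records.  With no
        stratification everything is stratum 1."""
        if model is None or boundaries is None:
            stratum = np.ones(self.n_records, dtype=int)
        else:
            scores = expit(self._design.values @ model.coef_)
            stratum = np.searchsorted(boundaries, scores, side="left") + 1
        num = np.asarray(numerator_fn(self._frame), dtype=bool)
        out = (
            self._frame.assign(stratum=stratum, numerator=num)
            .groupby(["country", "stratum"], observed=True)
            .agg(numerator=("numerator", "sum"), denominator=("numerator", "size"))
            .reset_index()
        )
        self.audit_log.append(
            {"operation": "stratum_outcome_counts", "payload_dim": [len(out)]}
        )
        return out

    def write_audit_log(self, path: str | Path) -> None:
        with open(path, "a") as fh:
            for entry in self.audit_log:
                fh.write(json.dumps({"node": self.node_id, **entry},
                                    sort_keys=True) + "\n")


class FederatedLogisticRegression(BaseEstimator):
    """Logistic regression fitted by federated IRLS over registry nodes.

    The outcome is membership of the reference country, so the fitted
    probabilities are propensity scores P(country = reference | x).

    Parameters
    ----------
    tol : float
        Convergence tolerance on the relative deviance change
        ``|dD| / (|D| + 0.1)``.
    max_iter : int
        IRLS iteration cap.
    ridge : float
        Tikhonov term applied to the normal equations once separation is
        suspected (diverging coefficients), keeping the solution finite.

    Attributes
    ----------
    coef_ : (p,) coefficients on the log-odds scale (intercept included,
        matching ``column_names_``).
    column_names_ : design column names.
    converged_ : whether the deviance criterion was met.
    n_iter_ : IRLS iterations run.
    deviance_ : final deviance.
    dropped_columns_ : design columns excluded because no pooled record
        carries them (all-zero columns); their coefficients are fixed at 0.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 25,
                 ridge: float = 1e-8):
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge

    def fit(self, nodes: list[RegistryNode], membership_label: str):
        if len(nodes) < 2:
            raise ValueError("a federation needs at least two nodes")
        columns = nodes[0].column_names
        for node in nodes[1:]:
            if node.column_names != columns:
                raise ValueError("nodes disagree on design columns")
        present = {c for node in nodes for c in node.countries()}
        if membership_label not in present or present == {membership_label}:
            raise ValueError(
                "both membership classes must be present across nodes"
            )
        p = len(columns)
        beta = np.zeros(p)
        active = None
        deviance = np.inf
        converged = False
        separated = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            partials = [n.irls_partial(beta, membership_label) for n in nodes]
            xtwx = sum(pt.xtwx for pt in partials)
            xtwz = sum(pt.xtwz for pt in partials)
            new_dev = float(sum(pt.deviance for pt in partials))
            if active is None:
                # columns no pooled record carries contribute nothing:
                # exclude them rather than solving a singular system
                active = np.diag(xtwx) > 0
                if not active.all():
                    warnings.warn(
                        "design columns with no observations fixed at 0: "
                        f"{[c for c, a in zip(columns, active) if not a]}",
                        stacklevel=2,
                    )
            A = xtwx[np.ix_(active, active)]
            b = xtwz[active]
            if separated:
                A = A + self.ridge * np.eye(A.shape[0])
            try:
                sol = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                warnings.warn("singular IRLS system; using pseudoinverse "
                              "(collinear design)", stacklevel=2)
                sol = np.linalg.pinv(A) @ b
            if not np.isfinite(sol).all():
                warnings.warn("non-finite IRLS solution; using pseudoinverse",
                              stacklevel=2)
                sol = np.linalg.pinv(A) @ b
            beta = np.zeros(p)
            beta[active] = sol
            if not separated and np.abs(beta).max() > 50.0:
                separated = True
                warnings.warn(
                    "diverging coefficients suggest separation; "
                    "continuing with a ridge term", stacklevel=2,
                )
            change = abs(deviance - new_dev) / (abs(new_dev) + 0.1)
            deviance = new_dev
            if change < self.tol:
                converged = True
                break
        self.coef_ = beta
        self.column_names_ = list(columns)
        self.converged_ = converged and not separated
        self.n_iter_ = n_iter
        self.deviance_ = deviance
        self.dropped_columns_ = [
            c for c, a in zip(columns, active) if not a
        ]
        self.membership_label_ = membership_label
        return self

    def predict_proba_design(self, X: np.ndarray) -> np.ndarray:
        """Propensity scores for rows of an already-encoded design matrix."""
        return expit(np.asarray(X) @ self.coef_)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "column_names": self.column_names_,
                "coefficients": self.coef_.tolist(),
                "converged": self.converged_,
                "n_iterations": self.n_iter_,
                "final_deviance": self.deviance_,
                "membership_label": self.membership_label_,
                "dropped_columns": self.dropped_columns_,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "FederatedLogisticRegression":
        data = json.loads(text)
        model = cls()
        model.coef_ = np.asarray(data["coefficients"])
        model.column_names_ = data["column_names"]
        model.converged_ = data["converged"]
        model.n_iter_ = data["n_iterations"]
        model.deviance_ = data["final_deviance"]
        model.membership_label_ = data["membership_label"]
        model.dropped_columns_ = data.get("dropped_columns", [])
        return model


#: The fitted estimator *is* the propensity model.
PropensityModel = FederatedLogisticRegression


def federated_fit(
    nodes: list[RegistryNode],
    membership_label: str,
    tol: float = 1e-8,
    max_iter: int = 25,
) -> FederatedLogisticRegression:
    """Fit the federated propensity model; see
    :class:`FederatedLogisticRegression`."""
    return FederatedLogisticRegression(tol=tol, max_iter=max_iter).fit(
        nodes, membership_label
    )


def local_irls_partial(
    node: RegistryNode, beta: np.ndarray, membership_label: str
) -> IRLSPartial:
    return node.irls_partial(np.asarray(beta, dtype=float), membership_label)


def release_scores(node: RegistryNode, model: FederatedLogisticRegression):
    return node.release_scores(model)
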