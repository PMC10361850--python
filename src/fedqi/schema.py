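"""Canonical patient schema for cross-registry breast cancer benchmarking.

A cohort is a pandas DataFrame with one row per patient: nine categorical
covariates describing patient and tumour (year of diagnosis, age band,
histology, differentiation grade, pathological T and N stage, HER2/ER/PR
receptor status), a country label, and the treatment/outcome fields needed by
the quality indicators (MRI use, systemic therapy, surgery counts,
reconstruction, radiotherapy, metastasis status).

Registries spell levels differently ("pTx", "T1", "ductal carcinoma"); a
versioned alias table shipped with the package maps registry spellings onto
the canonical levels.  Receptor-positivity cutoffs differ between registries
(e.g. ER >=10% vs >1%); the schema stores each registry's own call and makes
no attempt to re-harmonize.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, fields as dc_fields
from importlib import resources

import pandas as pd
import yaml

#: Propensity covariates, in presentation order.  The first level of each is
#: the dummy-coding reference level.
COVARIATES = [
    "year",
    "age_band",
    "histology",
    "grade",
    "pt",
    "pn",
    "her2",
    "er",
    "pr",
]

LEVELS: dict[str, list[str]] = {
    "year": ["2017", "2018"],
    "age_band": ["<40", "40-49", "50-59", "60-69", "70-79", "80+"],
    "histology": ["ductal", "lobular", "other"],
    "grade": ["well", "moderate", "poor", "unknown"],
    "pt": ["<2cm", "2-5cm", "5+cm", "unknown"],
    "pn": ["pN0", "pN1-3", "pN4+", "unknown"],
    "her2": ["negative", "positive", "unknown"],
    "er": ["negative", "positive", "unknown"],
    "pr": ["negative", "positive", "unknown"],
}

#: Binary treatment/outcome flags.
FLAG_COLUMNS = [
    "preop_mri",
    "pst",
    "mri_around_pst",
    "mastectomy",
    "immediate_reconstruction",
    "bct",
    "postop_radiotherapy",
    "distant_metastasis",
    "dcis_only",
    "any_reconstruction",
    "any_operation",
]

INT_COLUMNS = ["n_breast_operations"]

#: Full canonical CSV column order.
COLUMNS = COVARIATES + ["country"] + FLAG_COLUMNS + INT_COLUMNS


@functools.cache
def alias_table() -> dict[str, dict[str, str]]:
    """Registry-spelling -> canonical-level map, loaded from the shipped
    versioned config (``data/aliases.yaml``)."""
    text = resources.files("fedqi").joinpath("data/aliases.yaml").read_text()
    table = yaml.safe_load(text)
    return {var: dict(m) for var, m in table.items() if var != "version"}


@dataclass
class PatientRecord:
    """One registry row.

    Structural invariants (checked by :meth:`validate`):

    * every categorical field takes a declared level;
    * immediate reconstruction implies mastectomy;
    * ``n_breast_operations >= 1`` whenever ``any_operation`` is true.

    ``mri_around_pst`` without ``pst`` is tolerated in data (validation warns
    rather than fails); registries occasionally record the scan without the
    therapy episode.
    """

    year: str
    age_band: str
    histology: str
    grade: str
    pt: str
    pn: str
    her2: str
    er: str
    pr: str
    country: str
    preop_mri: bool = False
    pst: bool = False
    mri_around_pst: bool = False
    mastectomy: bool = False
    immediate_reconstruction: bool = False
    bct: bool = False
    postop_radiotherapy: bool = False
    distant_metastasis: bool = False
    dcis_only: bool = False
    any_reconstruction: bool = False
    any_operation: bool = False
    n_breast_operations: int = 0

    def validate(self) -> list[str]:
        """Return a list of violation messages (empty when valid)."""
        problems = []
        for var in COVARIATES:
            value = getattr(self, var)
            if value not in LEVELS[var]:
                problems.append(f"{var}: undeclared level {value!r}")
        if self.immediate_reconstruction and not self.mastectomy:
            problems.append("immediate_reconstruction without mastectomy")
        if self.any_operation and self.n_breast_operations < 1:
            problems.append("any_operation with n_breast_operations < 1")
        if self.n_breast_operations < 0:
            problems.append("negative n_breast_operations")
        return problems


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Convert a list of records into the canonical cohort DataFrame."""
    frame = pd.DataFrame([vars(r) for r in records], columns=COLUMNS)
    return coerce_frame(frame)


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    names = [f.name for f in dc_fields(PatientRecord)]
    return [
        PatientRecord(**{k: row[k] for k in names})
        for row in frame.to_dict("records")
    ]


def coerce_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Apply canonical dtypes: ordered categoricals for the covariates,
    bool for flags, int for operation counts."""
    frame = frame.copy()
    for var in COVARIATES:
        frame[var] = pd.Categorical(
            frame[var].astype(str), categories=LEVELS[var]
        )
    for col in FLAG_COLUMNS:
        frame[col] = frame[col].astype(bool)
    for col in INT_COLUMNS:
        frame[col] = frame[col].astype(int)
    frame["country"] = frame["country"].astype(str)
    return frame
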