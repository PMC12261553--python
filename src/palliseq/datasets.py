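"""Claims-like tabular containers and their CSV on-disk form.

All timing is death-anchored: ``day_before_death`` counts backwards from the
day of death (0 = day of death, 365 = one year before), and every record lies
inside the final-year window [0, 365].
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: The four palliative-care service types whose first initiation forms a pathway.
PALLIATIVE_SERVICES = ("PPC", "SPHC", "IPC", "HOSPICE")

#: Utilization events used for the 30-days-before-death quality indicators.
EOL_EVENTS = ("HOSPITAL", "ICU", "EMERGENCY", "PEG", "VENTILATION")

SERVICE_SYMBOLS = PALLIATIVE_SERVICES + EOL_EVENTS

PLACES_OF_DEATH = ("hospital", "ipc_unit", "nursing_home", "hospice", "other")

SEXES = ("female", "male")

_ICD_RE = re.compile(r"^[A-Z][0-9]{2}")

DIAGNOSES_COLUMNS = ["individual_id", "icd10_code", "setting", "day_before_death"]
SERVICES_COLUMNS = ["individual_id", "service", "day_before_death"]
PERSONS_COLUMNS = ["individual_id", "sex", "age_at_death", "place_of_death"]


class ClaimsSchemaError(ValueError):
    """A claims table violates the schema contract."""


@dataclass
class ClaimsDataset:
    """Raw per-individual records within the 365-day pre-death window.

    ``truth`` is an optional sidecar (individual_id, template_name) carrying
    simulation ground-truth labels.  It is never part of the pipeline-facing
    tables and is written to a separate file.
    """

    diagnoses: pd.DataFrame
    services: pd.DataFrame
    persons: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.diagnoses = self.diagnoses.reindex(columns=DIAGNOSES_COLUMNS)
        self.services = self.services.reindex(columns=SERVICES_COLUMNS)
        self.persons = self.persons.reindex(columns=PERSONS_COLUMNS)

    def validate(self) -> "ClaimsDataset":
        for name, df in (("diagnoses", self.diagnoses), ("services", self.services)):
            if len(df):
                days = df["day_before_death"]
                if days.lt(0).any() or days.gt(365).any():
                    raise ClaimsSchemaError(
                        f"{name}.day_before_death outside [0, 365]"
                    )
        if len(self.diagnoses):
            bad = ~self.diagnoses["icd10_code"].astype(str).str.match(_ICD_RE)
            if bad.any():
                codes = sorted(self.diagnoses.loc[bad, "icd10_code"].unique())
                raise ClaimsSchemaError(f"malformed ICD-10 codes: {codes}")
        known = set(self.persons["individual_id"])
        for name, df in (("diagnoses", self.diagnoses), ("services", self.services)):
            missing = sorted(set(df["individual_id"]) - known)
            if missing:
                raise ClaimsSchemaError(
                    f"{name} references individuals absent from persons: {missing}"
                )
        return self

    def write(self, out_dir: str | Path) -> None:
        """Write diagnoses/services/persons CSVs plus the truth sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.diagnoses.to_csv(out / "diagnoses.csv", index=False)
        self.services.to_csv(out / "services.csv", index=False)
        self.persons.to_csv(out / "persons.csv", index=False)
        if self.truth is not None:
            self.truth.to_csv(out / "truth.csv", index=False)

    @classmethod
    def read(cls, in_dir: str | Path) -> "ClaimsDataset":
        p = Path(in_dir)
        truth_path = p / "truth.csv"
        return cls(
            diagnoses=pd.read_csv(p / "diagnoses.csv"),
            services=pd.read_csv(p / "services.csv"),
            persons=pd.read_csv(p / "persons.csv"),
            truth=pd.read_csv(truth_path) if truth_path.exists() else None,
        ).validate()


def normalize_icd10(code: str) -> str:
    """Upper-case and strip the dot: ``'i21.0' -> 'I210'``.

    Raises ``ValueError`` for anything not matching ``^[A-Z][0-9]{2}``.
    """
    c = str(code).strip().upper().replace(".", "")
    if not _ICD_RE.match(c):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return c
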