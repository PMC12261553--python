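"""Cohort construction from claims.

Selects the ALS cohort (at least one G12.2 diagnosis in the final-year
window, no C00-C97 cancer diagnosis), and derives per-individual analysis
variables: weighted Charlson Comorbidity Index (Quan ICD-10 mapping,
original weights), six chronic-condition flags, first-initiation day of
each palliative-care service, five 30-days-before-death utilization flags,
and place of death.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from ._rounding import pct, round_half_up
from .datasets import (
    ClaimsDataset,
    EOL_EVENTS,
    PALLIATIVE_SERVICES,
    normalize_icd10,
)

__all__ = [
    "CohortMember",
    "select_als_cohort",
    "compute_cci",
    "flag_conditions",
    "derive_eol_flags",
    "summarize_cohort",
    "cohort_to_frame",
    "CONDITIONS",
    "EOL_WINDOW_DAYS",
]

#: The six tracked chronic-condition flags, in reporting order.
CONDITIONS = (
    "cardiovascular",
    "cerebrovascular",
    "kidney",
    "liver",
    "respiratory",
    "dementia",
)

#: Events count toward end-of-life indicators iff day_before_death <= this.
EOL_WINDOW_DAYS = 30

_ALS_PREFIX = "G122"  # G12.2, dot stripped


def _expand_code_spec(spec: str) -> list[str]:
    """Expand a ``;``-separated code spec with ranges into dotless prefixes.

    A range like ``C00-C97`` or ``I420-I429`` spans same-letter, same-width
    codes inclusively.
    """
    prefixes: list[str] = []
    for part in spec.split(";"):
        part = part.strip()
        if "-" in part:
            lo, hi = part.split("-")
            if lo[0] != hi[0] or len(lo) != len(hi):
                raise ValueError(f"bad code range {part!r}")
            width = len(lo) - 1
            for n in range(int(lo[1:]), int(hi[1:]) + 1):
                prefixes.append(f"{lo[0]}{n:0{width}d}")
        else:
            prefixes.append(part)
    return prefixes


def _load_code_table(name: str) -> list[dict]:
    with resources.files("palliseq.data").joinpath(name).open() as fh:
        return list(csv.DictReader(fh))


def _charlson_map() -> list[tuple[str, int, tuple[str, ...]]]:
    return [
        (row["condition"], int(row["weight"]),
         tuple(_expand_code_spec(row["codes"])))
        for row in _load_code_table("charlson_quan.csv")
    ]


def _condition_map() -> dict[str, tuple[str, ...]]:
    return {
        row["condition"]: tuple(_expand_code_spec(row["codes"]))
        for row in _load_code_table("condition_flags.csv")
    }


_CHARLSON = _charlson_map()
_CONDITION_SETS = _condition_map()

# Charlson hierarchy: the severe form supersedes the mild form.
_CHARLSON_SUPERSEDES = {
    "diabetes_complicated": "diabetes_uncomplicated",
    "severe_liver": "mild_liver",
    "metastatic_tumor": "malignancy",
}


def _matches_any(code: str, prefixes: tuple[str, ...]) -> bool:
    return any(code.startswith(p) for p in prefixes)


def compute_cci(codes: list[str]) -> int:
    """Weighted Charlson Comorbidity Index from raw ICD-10 codes.

    Each Charlson condition counts once regardless of how many codes map to
    it; hierarchy rules drop the mild form when the severe form is present
    (complicated diabetes over uncomplicated, severe over mild liver
    disease, metastatic tumour over any malignancy).  Malformed codes are
    rejected with their list position.
    """
    normalized = []
    for pos, code in enumerate(codes):
        try:
            normalized.append(normalize_icd10(code))
        except ValueError as exc:
            raise ValueError(f"code at position {pos}: {exc}") from None
    present = {
        cond
        for cond, _w, prefixes in _CHARLSON
        if any(_matches_any(c, prefixes) for c in normalized)
    }
    for severe, mild in _CHARLSON_SUPERSEDES.items():
        if severe in present:
            present.discard(mild)
    weights = {cond: w for cond, w, _ in _CHARLSON}
    return sum(weights[cond] for cond in present)


def flag_conditions(codes: list[str]) -> dict[str, bool]:
    """Six chronic-condition flags from raw ICD-10 codes (prefix membership)."""
    normalized = [normalize_icd10(c) for c in codes]
    return {
        cond: any(_matches_any(c, _CONDITION_SETS[cond]) for c in normalized)
        for cond in CONDITIONS
    }


def derive_eol_flags(services: pd.DataFrame) -> dict[str, bool]:
    """Five end-of-life utilization flags for one individual.

    A flag is true iff a matching event was billed within the closed 30-day
    window before death (day_before_death <= 30).
    """
    recent = services.loc[services["day_before_death"] <= EOL_WINDOW_DAYS, "service"]
    seen = set(recent)
    return {event.lower(): event in seen for event in EOL_EVENTS}


@dataclass
class CohortMember:
    """Derived analysis record for one cohort individual."""

    individual_id: str
    sex: str
    age_at_death: int
    place_of_death: str
    cci: int
    condition_flags: dict[str, bool]
    pc_initiation: dict[str, int]  # service -> first billing day before death
    eol_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def has_palliative_care(self) -> bool:
        return bool(self.pc_initiation)


def select_als_cohort(claims: ClaimsDataset) -> list[CohortMember]:
    """Apply inclusion/exclusion filters and derive all member variables.

    Inclusion: at least one G12.2 diagnosis within the window.  Exclusion:
    any diagnosis with code in C00-C97 (3-character prefix level), anywhere
    in the window.  All derived fields are populated for every member.
    """
    claims.validate()
    diag = claims.diagnoses.copy()
    if len(diag):
        diag["norm"] = diag["icd10_code"].map(normalize_icd10)
    else:
        diag["norm"] = pd.Series(dtype=str)

    by_person = dict(tuple(diag.groupby("individual_id"))) if len(diag) else {}
    svc_by_person = (
        dict(tuple(claims.services.groupby("individual_id")))
        if len(claims.services)
        else {}
    )
    empty_svc = claims.services.iloc[0:0]

    members: list[CohortMember] = []
    for person in claims.persons.itertuples(index=False):
        pid = person.individual_id
        codes_df = by_person.get(pid)
        if codes_df is None:
            continue
        norm = codes_df["norm"]
        if not norm.str.startswith(_ALS_PREFIX).any():
            continue
        cancer = norm.str[:3].between("C00", "C97")
        if cancer.any():
            continue

        raw_codes = list(codes_df["icd10_code"])
        svc = svc_by_person.get(pid, empty_svc)
        pc = (
            svc[svc["service"].isin(PALLIATIVE_SERVICES)]
            .groupby("service")["day_before_death"]
            .max()  # first billing = furthest from death
            .astype(int)
            .to_dict()
        )
        members.append(
            CohortMember(
                individual_id=pid,
                sex=person.sex,
                age_at_death=int(person.age_at_death),
                place_of_death=person.place_of_death,
                cci=compute_cci(raw_codes),
                condition_flags=flag_conditions(raw_codes),
                pc_initiation=pc,
                eol_flags=derive_eol_flags(svc),
            )
        )
    return members


def cohort_to_frame(cohort: list[CohortMember]) -> pd.DataFrame:
    """Flatten members to one row each (pipeline-facing cohort table)."""
    rows = []
    for m in cohort:
        row = {
            "individual_id": m.individual_id,
            "sex": m.sex,
            "age_at_death": m.age_at_death,
            "place_of_death": m.place_of_death,
            "cci": m.cci,
        }
        row.update({f"dx_{c}": m.condition_flags[c] for c in CONDITIONS})
        row.update(
            {f"init_{s.lower()}": m.pc_initiation.get(s, pd.NA)
             for s in PALLIATIVE_SERVICES}
        )
        row.update({f"eol_{k}": v for k, v in m.eol_flags.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _column_stats(members: list[CohortMember]) -> dict[str, float]:
    n = len(members)
    out: dict[str, float] = {"n": n}
    out["female_n"] = sum(m.sex == "female" for m in members)
    out["female_pct"] = pct(out["female_n"], n)
    for name, values in (
        ("age", [m.age_at_death for m in members]),
        ("cci", [m.cci for m in members]),
    ):
        if n:
            s = pd.Series(values)
            out[f"{name}_median"] = round_half_up(s.median(), 1)
            out[f"{name}_q1"] = round_half_up(s.quantile(0.25), 1)
            out[f"{name}_q3"] = round_half_up(s.quantile(0.75), 1)
        else:
            out[f"{name}_median"] = out[f"{name}_q1"] = out[f"{name}_q3"] = float("nan")
    for cond in CONDITIONS:
        cnt = sum(m.condition_flags.get(cond, False) for m in members)
        out[f"{cond}_n"] = cnt
        out[f"{cond}_pct"] = pct(cnt, n)
    return out


def summarize_cohort(cohort: list[CohortMember], split_by_pc: bool = True) -> pd.DataFrame:
    """Demographic/clinical summary table (counts, %, median, IQR).

    Columns: ``full`` and, when ``split_by_pc``, ``with_pc`` / ``without_pc``
    (a member is "with" iff any palliative-care service was initiated).
    Percentages are rounded half-up to one decimal; an empty column reports
    counts of 0 and NaN percentages.
    """
    groups = {"full": cohort}
    if split_by_pc:
        groups["with_pc"] = [m for m in cohort if m.has_palliative_care]
        groups["without_pc"] = [m for m in cohort if not m.has_palliative_care]
    table = pd.DataFrame({name: _column_stats(g) for name, g in groups.items()})
    if split_by_pc:
        table.loc["with_pc_pct", "full"] = pct(len(groups["with_pc"]), len(cohort))
    return table


def write_cohort(cohort: list[CohortMember], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_to_frame(cohort).to_csv(out / "cohort.csv", index=False)
    summarize_cohort(cohort).to_csv(out / "table1.csv")
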