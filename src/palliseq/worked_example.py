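"""Synthetic worked-example cohort with planted aggregate counts.

The original claims cohort behind the published summary tables is
proprietary and cannot be shipped.  This module constructs a *synthetic*
stand-in cohort of 1,295 members whose marginal counts match the published
aggregates exactly — 695 with palliative care, 727 female (416 among those
with palliative care), per-service user counts PPC 496 / SPHC 400 /
IPC 138 / hospice 94, and the per-condition diagnosis counts — so that the
summary and utilization computations can be exercised against printed
reference percentages.  Only those aggregate counts are planted; individual
records are otherwise schematic.
"""

from __future__ import annotations

from .cohort import CONDITIONS, CohortMember

__all__ = ["synthetic_reference_cohort"]

# planted counts: (with-PC count of 695, without-PC count of 600)
_CONDITION_COUNTS = {
    "cardiovascular": (568, 528),
    "respiratory": (457, 420),
    "cerebrovascular": (192, 227),
    "dementia": (174, 215),
    "kidney": (141, 176),
    "liver": (88, 87),
}

_EOL_COUNTS_WITH = {"hospital": 264, "icu": 41, "emergency": 206,
                    "peg": 34, "ventilation": 32}
_EOL_COUNTS_WITHOUT = {"hospital": 362, "icu": 118, "emergency": 312,
                       "peg": 38, "ventilation": 119}

# categorical place-of-death counts; "other" absorbs the remainder
_POD_COUNTS_WITH = {"hospital": 169, "ipc_unit": 37, "nursing_home": 0,
                    "hospice": 80}
_POD_COUNTS_WITHOUT = {"hospital": 321, "ipc_unit": 4, "nursing_home": 87,
                       "hospice": 0}

# schematic initiation days (only counts matter for the worked example)
_SERVICE_DAYS = {"PPC": 126, "SPHC": 31, "IPC": 6, "HOSPICE": 20}


def _place_of_death(i: int, counts: dict[str, int]) -> str:
    offset = 0
    for place, cnt in counts.items():
        if i < offset + cnt:
            return place
        offset += cnt
    return "other"


def _member(i: int, with_pc: bool) -> CohortMember:
    if with_pc:
        n_female, eol, pod = 416, _EOL_COUNTS_WITH, _POD_COUNTS_WITH
        services = {}
        if i < 496:
            services["PPC"] = _SERVICE_DAYS["PPC"]
        if i >= 295:
            services["SPHC"] = _SERVICE_DAYS["SPHC"]
        if i < 138:
            services["IPC"] = _SERVICE_DAYS["IPC"]
        if 601 <= i:
            services["HOSPICE"] = _SERVICE_DAYS["HOSPICE"]
        age, cci = 72, 3
    else:
        n_female, eol, pod = 311, _EOL_COUNTS_WITHOUT, _POD_COUNTS_WITHOUT
        services = {}
        age, cci = 74, 4
    return CohortMember(
        individual_id=f"{'W' if with_pc else 'N'}{i:04d}",
        sex="female" if i < n_female else "male",
        age_at_death=age,
        place_of_death=_place_of_death(i, pod),
        cci=cci,
        condition_flags={
            cond: i < _CONDITION_COUNTS[cond][0 if with_pc else 1]
            for cond in CONDITIONS
        },
        pc_initiation=services,
        eol_flags={event: i < eol[event] for event in eol},
    )


def synthetic_reference_cohort() -> list[CohortMember]:
    """1,295 synthetic members reproducing the published marginal counts."""
    cohort = [_member(i, with_pc=True) for i in range(695)]
    cohort += [_member(i, with_pc=False) for i in range(600)]
    return cohort
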