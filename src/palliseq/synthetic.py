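"""Seeded synthetic claims generator.

Emulates the statistical structure of a final-year-of-life health-claims
extract for people with ALS (ICD-10 G12.2): planted palliative-care pathway
archetypes with noisy initiation timing, comorbidity diagnoses, 30-day
end-of-life utilization events, and place of death, all conditional on the
archetype.  Ground-truth archetype labels travel in a sidecar table and are
never part of the pipeline-facing schema.

Archetype defaults mirror the nine pathway clusters reported for a German
statutory-insurance ALS cohort: service composition, initiation-day medians,
30-day indicator rates and place-of-death distributions.  Only medians and
rates are published for that cohort; dispersions are this package's own
assumptions (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import (
    ClaimsDataset,
    PALLIATIVE_SERVICES,
    PLACES_OF_DEATH,
)

__all__ = [
    "DayDistribution",
    "OutcomeProfile",
    "PathwayTemplate",
    "SimulationConfig",
    "default_templates",
    "three_archetype_templates",
    "archetype_config",
    "demo_config",
    "generate_claims",
    "NO_CARE_OUTCOMES",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class DayDistribution:
    """Distribution of an initiation day before death, on [0, 365].

    ``lognormal`` is parameterized by its median (exp of the log-mean) and
    the log-scale sigma; ``uniform`` by inclusive integer bounds.
    """

    kind: str = "lognormal"
    median: float = 60.0
    sigma: float = 0.35
    low: int = 0
    high: int = 365

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "uniform"):
            raise ConfigError(f"DayDistribution.kind: unknown kind {self.kind!r}")
        if self.kind == "lognormal" and self.median <= 0:
            raise ConfigError("DayDistribution.median: must be > 0")
        if not (0 <= self.low <= self.high <= 365):
            raise ConfigError("DayDistribution.low/high: need 0 <= low <= high <= 365")

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "uniform":
            return int(rng.integers(self.low, self.high + 1))
        day = math.exp(math.log(self.median) + self.sigma * rng.standard_normal())
        return int(np.clip(round(day), 0, 365))


@dataclass(frozen=True)
class OutcomeProfile:
    """Cluster-conditional end-of-life outcome probabilities.

    Five Bernoulli rates for utilization billed within 30 days before death,
    plus a categorical place-of-death distribution over
    (hospital, ipc_unit, nursing_home, hospice, other).
    """

    hospital: float
    icu: float
    emergency: float
    peg: float
    ventilation: float
    place_of_death: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        for name in ("hospital", "icu", "emergency", "peg", "ventilation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"OutcomeProfile.{name}: {v} not in [0, 1]")
        total = sum(self.place_of_death)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ConfigError(
                f"OutcomeProfile.place_of_death: probabilities sum to {total}, not 1"
            )

    @classmethod
    def from_percentages(cls, h, i, e, p, v, pod) -> "OutcomeProfile":
        """Build from printed table percentages; place-of-death is renormalized."""
        pod = np.asarray(pod, dtype=float)
        pod = pod / pod.sum()
        return cls(h / 100, i / 100, e / 100, p / 100, v / 100, tuple(pod))


@dataclass(frozen=True)
class PathwayTemplate:
    """A planted palliative-care pathway archetype.

    ``services`` lists which of PPC/SPHC/IPC/HOSPICE the archetype initiates
    (each at most once, 0-4 entries); the per-service day distributions are
    marginals — the realized order of a sampled pathway follows the sampled
    days, not the list order.  ``simultaneity_prob`` is the chance that two
    adjacent services in the sampled pathway share an initiation day.
    """

    name: str
    services: tuple[str, ...]
    day_distributions: dict[str, DayDistribution]
    outcomes: OutcomeProfile
    simultaneity_prob: float = 0.0

    def __post_init__(self) -> None:
        if len(self.services) > 4:
            raise ConfigError("PathwayTemplate.services: more than 4 services")
        if len(set(self.services)) != len(self.services):
            raise ConfigError("PathwayTemplate.services: repeated service")
        unknown = set(self.services) - set(PALLIATIVE_SERVICES)
        if unknown:
            raise ConfigError(f"PathwayTemplate.services: unknown {sorted(unknown)}")
        missing = set(self.services) - set(self.day_distributions)
        if missing:
            raise ConfigError(
                f"PathwayTemplate.day_distributions: missing {sorted(missing)}"
            )
        if not 0.0 <= self.simultaneity_prob <= 1.0:
            raise ConfigError("PathwayTemplate.simultaneity_prob: not in [0, 1]")

    def sample_days(self, rng: np.random.Generator) -> dict[str, int]:
        """Sample one initiation day per service and apply simultaneity."""
        days = {s: self.day_distributions[s].sample(rng) for s in self.services}
        ordered = sorted(days, key=lambda s: -days[s])
        for prev, cur in zip(ordered, ordered[1:]):
            if self.simultaneity_prob and rng.random() < self.simultaneity_prob:
                days[cur] = days[prev]
        return days


#: End-of-life outcome profile for individuals without any palliative care.
NO_CARE_OUTCOMES = OutcomeProfile.from_percentages(
    60.3, 19.7, 52.0, 6.3, 19.8, (53.5, 0.7, 14.5, 0.0, 32.0)
)

#: Diagnosis prevalences of the six tracked chronic conditions (full cohort).
DEFAULT_COMORBIDITY_PREVALENCES = {
    "cardiovascular": 0.846,
    "respiratory": 0.677,
    "cerebrovascular": 0.324,
    "dementia": 0.300,
    "kidney": 0.245,
    "liver": 0.135,
}

# Representative ICD-10 codes used to plant each tracked condition.
CONDITION_CODES = {
    "cardiovascular": "I50.0",
    "cerebrovascular": "I63.9",
    "kidney": "N18.5",
    "liver": "K74.6",
    "respiratory": "J44.9",
    "dementia": "F03",
}

#: Mixture weights of the nine default archetypes (cluster shares, %).
DEFAULT_TEMPLATE_SHARES = (28.2, 20.4, 11.9, 10.6, 7.2, 6.3, 5.8, 5.5, 4.0)


def _ln(median: float, sigma: float = 0.35) -> DayDistribution:
    return DayDistribution("lognormal", median=median, sigma=sigma)


def default_templates() -> list[PathwayTemplate]:
    """Nine archetypes mirroring the reported pathway clusters.

    Compositions and initiation-day medians follow the published per-cluster
    utilization table (PPC only at median 126.5 days, SPHC only at 31 days,
    PPC then SPHC, SPHC then PPC, hospice-final, IPC only at 5.5 days,
    outpatient then IPC, PPC/hospice-final, SPHC-final); 30-day indicator
    rates and place-of-death distributions follow the same table.
    """
    rows = [
        ("ppc_only", ("PPC",), {"PPC": _ln(126.5)},
         (41.8, 9.7, 38.3, 4.1, 6.6, (32.1, 1.0, 24.5, 0.0, 43.4)), 0.0),
        ("sphc_only", ("SPHC",), {"SPHC": _ln(31.0)},
         (28.9, 1.4, 28.9, 4.2, 1.4, (9.9, 0.7, 18.3, 0.0, 71.8)), 0.0),
        ("ppc_then_sphc", ("PPC", "SPHC"),
         {"PPC": _ln(156.0), "SPHC": _ln(31.0)},
         (22.9, 6.0, 25.3, 3.6, 2.4, (8.4, 1.2, 15.7, 0.0, 75.9)), 0.1),
        ("sphc_then_ppc", ("SPHC", "PPC"),
         {"SPHC": _ln(96.5), "PPC": _ln(60.5)},
         (31.1, 8.1, 27.0, 6.8, 8.1, (12.2, 0.0, 18.9, 1.4, 67.5)), 0.1),
        ("hospice_final", ("PPC", "SPHC", "HOSPICE"),
         {"PPC": _ln(172.0), "SPHC": _ln(145.0), "HOSPICE": _ln(20.0, 0.25)},
         (20.0, 2.0, 16.0, 2.0, 4.0, (0.0, 0.0, 8.0, 90.0, 2.0)), 0.05),
        ("ipc_only", ("IPC",), {"IPC": _ln(5.5, 0.5)},
         (95.5, 11.4, 40.9, 15.9, 6.8, (93.2, 45.5, 0.0, 0.0, 6.8)), 0.0),
        ("outpatient_then_ipc", ("PPC", "SPHC", "IPC"),
         {"PPC": _ln(107.5), "SPHC": _ln(67.0), "IPC": _ln(6.5, 0.5)},
         (87.5, 2.5, 40.0, 10.0, 5.0, (77.5, 30.0, 2.5, 0.0, 20.0)), 0.05),
        ("ppc_hospice_final", ("IPC", "PPC", "HOSPICE"),
         {"IPC": _ln(98.5), "PPC": _ln(31.0), "HOSPICE": _ln(28.0, 0.25)},
         (18.4, 5.3, 15.8, 0.0, 2.6, (10.5, 2.6, 23.7, 57.9, 7.9)), 0.1),
        ("sphc_final", ("PPC", "IPC", "SPHC"),
         {"PPC": _ln(83.5), "IPC": _ln(70.0), "SPHC": _ln(26.0, 0.25)},
         (17.9, 0.0, 3.6, 0.0, 3.6, (0.0, 0.0, 14.3, 42.9, 42.8)), 0.1),
    ]
    return [
        PathwayTemplate(
            name=name,
            services=services,
            day_distributions=dists,
            outcomes=OutcomeProfile.from_percentages(*probs),
            simultaneity_prob=sim,
        )
        for name, services, dists, probs, sim in rows
    ]


def three_archetype_templates(sigma: float = 0.25) -> list[PathwayTemplate]:
    """Three well-separated, mutually symmetric archetypes for recovery tests.

    The trio (PPC->SPHC, SPHC->IPC, IPC->PPC) is cyclically symmetric under
    the alignment scoring: each pair of archetypes shares exactly one service
    symbol, so the three between-archetype distance distributions are
    identical while within-archetype distances stay small.  The true 3-way
    partition is then sharply defined, but any 2-way merge is ambiguous —
    exactly the regime in which bootstrap stability discriminates the
    planted number of clusters.
    """
    profiles = [
        OutcomeProfile.from_percentages(
            22.9, 6.0, 25.3, 3.6, 2.4, (8.4, 1.2, 15.7, 0.0, 75.9)
        ),
        OutcomeProfile.from_percentages(
            95.5, 11.4, 40.9, 15.9, 6.8, (93.2, 45.5, 0.0, 0.0, 6.8)
        ),
        OutcomeProfile.from_percentages(
            20.0, 2.0, 16.0, 2.0, 4.0, (0.0, 0.0, 8.0, 90.0, 2.0)
        ),
    ]
    pairs = [("PPC", "SPHC"), ("SPHC", "IPC"), ("IPC", "PPC")]
    return [
        PathwayTemplate(
            name=f"arch_{a.lower()}_{b.lower()}",
            services=(a, b),
            day_distributions={a: _ln(150.0, sigma), b: _ln(40.0, sigma)},
            outcomes=prof,
        )
        for (a, b), prof in zip(pairs, profiles)
    ]


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort draw."""

    n_individuals: int
    templates: list[PathwayTemplate] = field(default_factory=default_templates)
    template_weights: list[float] | None = None
    frac_no_palliative_care: float = 0.463
    frac_cancer_contaminant: float = 0.204
    comorbidity_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCES)
    )
    sex_ratio_female: float = 0.561
    age_mean: float = 72.0
    age_sd: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ConfigError("n_individuals: must be >= 0")
        if self.template_weights is None:
            self.template_weights = [1.0 / len(self.templates)] * len(self.templates)
        if len(self.template_weights) != len(self.templates):
            raise ConfigError("template_weights: length differs from templates")
        if any(w < 0 for w in self.template_weights):
            raise ConfigError("template_weights: negative weight")
        if not math.isclose(sum(self.template_weights), 1.0, abs_tol=1e-6):
            raise ConfigError(
                f"template_weights: sum to {sum(self.template_weights)}, not 1"
            )
        for name in ("frac_no_palliative_care", "frac_cancer_contaminant",
                     "sex_ratio_female"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}: {v} not in [0, 1]")
        for cond, p in self.comorbidity_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"comorbidity_prevalences[{cond!r}]: not in [0, 1]")


def archetype_config(n: int = 300, seed: int = 0, sigma: float = 0.25) -> SimulationConfig:
    """Three-archetype recovery configuration: everyone has palliative care."""
    return SimulationConfig(
        n_individuals=n,
        templates=three_archetype_templates(sigma),
        frac_no_palliative_care=0.0,
        frac_cancer_contaminant=0.0,
        seed=seed,
    )


def demo_config(n: int = 600, seed: int = 0) -> SimulationConfig:
    """Nine-archetype demo configuration mirroring the reported cohort mix."""
    shares = np.asarray(DEFAULT_TEMPLATE_SHARES, dtype=float)
    return SimulationConfig(
        n_individuals=n,
        templates=default_templates(),
        template_weights=list(shares / shares.sum()),
        seed=seed,
    )


def generate_claims(config: SimulationConfig) -> ClaimsDataset:
    """Draw one synthetic claims dataset; deterministic given the config seed.

    Every individual carries at least one G12.2 diagnosis; a configurable
    fraction additionally carries a C00-C97 cancer code (to exercise the
    exclusion filter) and a fraction receives no palliative care at all.
    Ground-truth archetype labels are returned in the ``truth`` sidecar only.
    """
    rng = np.random.default_rng(config.seed)
    diag_rows: list[tuple] = []
    svc_rows: list[tuple] = []
    person_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    weights = np.asarray(config.template_weights, dtype=float)

    for i in range(config.n_individuals):
        pid = f"P{i:05d}"
        sex = "female" if rng.random() < config.sex_ratio_female else "male"
        age = int(np.clip(round(config.age_mean + config.age_sd
                                * rng.standard_normal()), 30, 105))

        # ALS diagnosis records (everyone), in one or both settings
        for _ in range(int(rng.integers(1, 4))):
            setting = "outpatient" if rng.random() < 0.7 else "inpatient"
            diag_rows.append((pid, "G12.2", setting, int(rng.integers(0, 366))))

        if rng.random() < config.frac_cancer_contaminant:
            diag_rows.append((pid, "C34.1",
                              "outpatient" if rng.random() < 0.5 else "inpatient",
                              int(rng.integers(0, 366))))

        for cond, prev in config.comorbidity_prevalences.items():
            if rng.random() < prev:
                diag_rows.append((pid, CONDITION_CODES[cond],
                                  "outpatient", int(rng.integers(0, 366))))

        if config.templates and rng.random() >= config.frac_no_palliative_care:
            template = config.templates[int(rng.choice(len(weights), p=weights))]
            outcomes = template.outcomes
            label = template.name
            for service, day in template.sample_days(rng).items():
                svc_rows.append((pid, service, day))
        else:
            outcomes = NO_CARE_OUTCOMES
            label = "none"

        # 30-day end-of-life utilization, conditional on the archetype
        for event, p in (("HOSPITAL", outcomes.hospital), ("ICU", outcomes.icu),
                         ("EMERGENCY", outcomes.emergency), ("PEG", outcomes.peg),
                         ("VENTILATION", outcomes.ventilation)):
            if rng.random() < p:
                svc_rows.append((pid, event, int(rng.integers(0, 31))))
        # background hospitalizations outside the 30-day window
        if rng.random() < 0.25:
            svc_rows.append((pid, "HOSPITAL", int(rng.integers(31, 366))))

        pod = PLACES_OF_DEATH[int(rng.choice(5, p=outcomes.place_of_death))]
        person_rows.append((pid, sex, age, pod))
        truth_rows.append((pid, label))

    dataset = ClaimsDataset(
        diagnoses=pd.DataFrame(
            diag_rows,
            columns=["individual_id", "icd10_code", "setting", "day_before_death"],
        ),
        services=pd.DataFrame(
            svc_rows, columns=["individual_id", "service", "day_before_death"]
        ),
        persons=pd.DataFrame(
            person_rows,
            columns=["individual_id", "sex", "age_at_death", "place_of_death"],
        ),
        truth=pd.DataFrame(truth_rows, columns=["individual_id", "template_name"]),
    )
    return dataset.validate()
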