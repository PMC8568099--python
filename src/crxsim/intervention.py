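"""In-silico referral-list (HealtheRx) generation and clinic delivery.

At a clinic visit an agent receives a personalized list of up to 40
community resources matched to their conditions, age/sex statuses and home
address. Each listed resource delivers one knowledge dose whose strength
depends on who hands the list over (physician > nurse > clerk).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .knowledge import KnowledgeParams, KnowledgeStore
from .world import ConfigurationError, World, age_band, nearest_resources

__all__ = [
    "ConditionCatalog",
    "HealtheRx",
    "DeliveryConfig",
    "DELIVERY_SOURCES",
    "default_condition_catalog",
    "assign_conditions",
    "indicated_services",
    "generate_healtherx",
    "deliver",
]

MAX_ITEMS = 40

DELIVERY_SOURCES = {"physician": "Doctor", "nurse": "Nurse", "clerk": "ClinicalStaff"}

# Synthetic condition catalog: ~10 common chronic/social conditions with
# age-graded prevalences (stand-in for a clinical catalog of 30+). Columns:
# condition, base prevalence, per-band multipliers, sex filter, services.
_DEFAULT_CONDITIONS_CSV = """\
condition_code,base_prevalence,m16_30,m31_45,m46_65,m66_94,sex,indicated_services
hypertension,0.25,0.3,0.8,1.6,2.4,any,fresh_produce;nutrition_counseling;fitness
diabetes,0.12,0.3,0.8,1.8,2.5,any,nutrition_counseling;fresh_produce;fill_prescriptions
obesity,0.30,0.8,1.1,1.2,0.9,any,weight_management;fitness;group_exercise
asthma,0.10,1.2,1.0,0.9,0.8,any,fill_prescriptions;medical_supplies
depression,0.15,1.2,1.1,1.0,0.8,any,mental_health_counseling;support_group
smoking,0.18,0.9,1.2,1.2,0.7,any,smoking_cessation
food_insecurity,0.20,1.3,1.1,0.9,0.8,any,food_pantry;fresh_produce
arthritis,0.15,0.2,0.6,1.6,2.6,any,walking_group;group_exercise;home_care
pregnancy,0.06,1.8,1.0,0.05,0.0,female,fresh_produce;support_group
copd,0.06,0.1,0.5,1.6,2.8,any,smoking_cessation;home_care;medical_supplies
"""

# Age/sex statuses always indicate a base service set, so every generated
# list is non-empty even for agents with no recorded conditions.
_BASE_SERVICES = {
    "16-30": ("fitness", "fresh_produce"),
    "31-45": ("fitness", "fresh_produce"),
    "46-65": ("fresh_produce", "walking_group"),
    "66-94": ("senior_services", "home_care", "walking_group"),
}

DEFAULT_LANGUAGE_WEIGHTS = {"english": 0.92, "spanish": 0.08}


@dataclass
class ConditionCatalog:
    """Condition prevalences (by age band and sex) and indicated services."""

    table: pd.DataFrame  # condition_code, age_band, sex, prevalence
    services: dict[str, tuple[str, ...]]  # condition_code -> indicated services
    language_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LANGUAGE_WEIGHTS)
    )
    base_services: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_BASE_SERVICES)
    )

    def __post_init__(self):
        bad = self.table[(self.table["prevalence"] < 0) | (self.table["prevalence"] > 1)]
        if len(bad):
            raise ConfigurationError("prevalences must lie in [0, 1]")


def default_condition_catalog() -> ConditionCatalog:
    raw = pd.read_csv(io.StringIO(_DEFAULT_CONDITIONS_CSV))
    bands = ("16-30", "31-45", "46-65", "66-94")
    mult_cols = ("m16_30", "m31_45", "m46_65", "m66_94")
    rows = []
    services = {}
    for r in raw.itertuples(index=False):
        services[r.condition_code] = tuple(r.indicated_services.split(";"))
        for band, mc in zip(bands, mult_cols):
            prev = min(1.0, r.base_prevalence * getattr(r, mc))
            for sex in ("female", "male"):
                if r.sex != "any" and sex != r.sex:
                    prev_sex = 0.0
                else:
                    prev_sex = prev
                rows.append((r.condition_code, band, sex, prev_sex))
    table = pd.DataFrame(rows, columns=["condition_code", "age_band", "sex", "prevalence"])
    return ConditionCatalog(table=table, services=services)


def assign_conditions(agents: pd.DataFrame, catalog: ConditionCatalog, rng) -> pd.DataFrame:
    """Fill the conditions and preferred_language columns.

    Independent Bernoulli draw per (agent, condition) at the agent's
    stratum prevalence; language drawn from the catalog weights. Returns a
    copy of the agent table.
    """
    agents = agents.copy()
    n = len(agents)
    bands = age_band(agents["age"].to_numpy())
    cond_lists = [[] for _ in range(n)]
    prev = catalog.table.set_index(["condition_code", "age_band", "sex"])["prevalence"]
    for code in catalog.services:
        p = prev.loc[code].loc[list(zip(bands, agents["sex"]))].to_numpy()
        hits = rng.random(n) < p
        for i in np.flatnonzero(hits):
            cond_lists[i].append(code)
    agents["conditions"] = [";".join(c) for c in cond_lists]
    langs = list(catalog.language_weights)
    w = np.array([catalog.language_weights[k] for k in langs], dtype=float)
    w = w / w.sum()
    agents["preferred_language"] = np.array(langs)[rng.choice(len(langs), size=n, p=w)]
    return agents


def indicated_services(agent, catalog: ConditionCatalog) -> list[str]:
    """Sorted union of base (age/sex status) and condition-indicated services."""
    band = str(age_band(int(agent["age"])))
    services = set(catalog.base_services.get(band, ()))
    conds = [c for c in str(agent.get("conditions", "") or "").split(";") if c]
    for c in conds:
        services.update(catalog.services.get(c, ()))
    return sorted(services)


@dataclass(frozen=True)
class HealtheRx:
    rx_id: int
    agent_id: int
    clinic_id: int
    hour: int
    delivery_mode: str  # physician | nurse | clerk
    items: tuple[int, ...]  # resource_ids, <= 40, unique


def generate_healtherx(agent, clinic, world: World, catalog: ConditionCatalog,
                       rx_id: int = 0, hour: int = 0,
                       delivery_mode: str = "physician") -> HealtheRx:
    """Deterministically match an agent to up to 40 resources.

    For every indicated service type, resources nearest the agent's
    household are ranked nearest-first; the list is filled round-robin
    across services (guaranteeing service coverage), de-duplicated and
    truncated at 40 items.
    """
    if clinic is not None and clinic["kind"] != "clinic":
        raise ValueError("HealtheRx must be issued at a clinic")
    services = indicated_services(agent, catalog)
    home = world.places.set_index("place_id").loc[int(agent["household_id"])]
    ranked = [
        nearest_resources(world, home, s, MAX_ITEMS)["resource_id"].tolist()
        for s in services
    ]
    items: list[int] = []
    seen: set[int] = set()
    depth = 0
    while len(items) < MAX_ITEMS and any(depth < len(r) for r in ranked):
        for r in ranked:
            if depth < len(r) and r[depth] not in seen:
                items.append(r[depth])
                seen.add(r[depth])
                if len(items) == MAX_ITEMS:
                    break
        depth += 1
    return HealtheRx(
        rx_id=rx_id,
        agent_id=int(agent["agent_id"]),
        clinic_id=int(clinic["place_id"]) if clinic is not None else -1,
        hour=hour,
        delivery_mode=delivery_mode,
        items=tuple(items),
    )


@dataclass
class DeliveryConfig:
    delivery_mode: str = "physician"
    mode_sources: dict[str, str] = field(default_factory=lambda: dict(DELIVERY_SOURCES))
    trigger_activity_codes: tuple[str, ...] = ("medical_visit",)

    def __post_init__(self):
        if self.delivery_mode not in self.mode_sources:
            raise ConfigurationError(f"unknown delivery mode {self.delivery_mode!r}")

    @property
    def dose_source(self) -> str:
        return self.mode_sources[self.delivery_mode]


def deliver(rx: HealtheRx, store: KnowledgeStore, cfg: DeliveryConfig,
            params: KnowledgeParams) -> list[tuple[int, int, int, str]]:
    """Apply one clinical dose per listed resource to the recipient's store.

    Every touched entry is flagged referral-derived. Returns one dosing
    event tuple (hour, agent_id, resource_id, source) per item.
    """
    if rx.agent_id != store.owner:
        raise ValueError("prescription does not belong to this store's owner")
    source = cfg.mode_sources[rx.delivery_mode]
    events = []
    for rid in rx.items:
        store.dose(rid, source, rx.hour, rx_flag=True)
        events.append((rx.hour, rx.agent_id, rid, source))
    return events
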