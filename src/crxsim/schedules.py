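"""Activity schedules: catalogs, demographically keyed template pools and
information-sharing propensities.

Each agent follows a 24-hour schedule (one activity per hour) drawn fresh
every simulated day from a pool of templates keyed on (age band, sex, race,
ethnicity) and day type (weekday/weekend), emulating the structure of a
national time-use survey. Activities are classified as daily-living or
health-maintenance; health-maintenance activities map to service types and
face a use/continue decision. Each activity also carries an ordinal
information-receiving propensity (p-score level: none/low/medium/high) that
the pool converts to numeric rates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .world import AGE_BANDS, ConfigurationError, age_band

__all__ = [
    "ActivityDef",
    "ScheduleTemplate",
    "SchedulePool",
    "PoolConfig",
    "default_catalog",
    "build_synthetic_pool",
    "draw_daily_schedule",
    "p_score",
    "service_exposure_minutes",
    "read_catalog_csv",
    "write_pool",
    "read_pool",
]

P_LEVELS = ("none", "low", "medium", "high")
DEFAULT_P_RATES = {"none": 0.0, "low": 0.05, "medium": 0.15, "high": 0.30}

LOCATION_POLICIES = ("home", "work", "school", "out_of_home", "service_site", "clinic")


@dataclass(frozen=True)
class ActivityDef:
    activity_code: str
    label: str
    activity_class: str  # daily_living | health_maintenance
    p_level: str  # none | low | medium | high
    decision_type: str  # AB | none
    mapped_services: frozenset[str]
    location_policy: str

    def __post_init__(self):
        if self.p_level not in P_LEVELS:
            raise ConfigurationError(f"bad p_level {self.p_level!r}")
        if self.location_policy not in LOCATION_POLICIES:
            raise ConfigurationError(f"bad location_policy {self.location_policy!r}")
        if self.decision_type == "AB" and not self.mapped_services:
            raise ConfigurationError(
                f"{self.activity_code}: AB decision requires mapped services"
            )


# Default activity catalog: a compact stand-in for an expert-informant
# mapping of time-use activities to referral-list service types. Columns:
# code, label, class, p_level, decision, services(;), location.
_DEFAULT_CATALOG_CSV = """\
activity_code,label,activity_class,p_level,decision_type,mapped_services,location_policy
sleeping,Sleeping,daily_living,none,none,,home
grooming,Washing and grooming,daily_living,none,none,,home
eating_home,Eating at home,daily_living,low,none,,home
housework,Housework,daily_living,none,none,,home
phone_calls,Talking on the phone,daily_living,low,none,,home
tv_leisure,Television and relaxing,daily_living,none,none,,home
helping_adults,Helping household adults,daily_living,medium,none,,home
work,Working,daily_living,low,none,,work
job_social,"Socializing, relaxing and leisure as part of job",daily_living,high,none,,work
school_attend,Attending school,daily_living,low,none,,school
commuting,Travel and commuting,daily_living,low,none,,out_of_home
grocery,Grocery shopping,daily_living,medium,none,,out_of_home
errands,Shopping and errands,daily_living,medium,none,,out_of_home
socializing,Socializing with friends,daily_living,high,none,,out_of_home
religious,Religious and spiritual practice,health_maintenance,medium,AB,spiritual_services,service_site
fitness,Fitness and exercise,health_maintenance,medium,AB,fitness;group_exercise;walking_group,service_site
weight_program,Weight management program,health_maintenance,medium,AB,weight_management;nutrition_counseling,service_site
counseling,Counseling and support group,health_maintenance,medium,AB,mental_health_counseling;support_group,service_site
quit_smoking,Smoking cessation program,health_maintenance,low,AB,smoking_cessation,service_site
food_assist,Obtaining food assistance,health_maintenance,medium,AB,food_pantry;fresh_produce,service_site
child_care_medical,Providing medical care to household children,health_maintenance,medium,AB,fill_prescriptions;medical_supplies;home_care,service_site
senior_center,Senior services and programs,health_maintenance,medium,AB,senior_services,service_site
medical_visit,Obtaining medical and care services,health_maintenance,high,none,,clinic
"""


def read_catalog_csv(source) -> dict[str, ActivityDef]:
    """Parse an activity catalog CSV (path or file-like) into ActivityDefs."""
    df = pd.read_csv(source, keep_default_na=False)
    catalog = {}
    for row in df.itertuples(index=False):
        services = frozenset(s for s in str(row.mapped_services).split(";") if s)
        catalog[row.activity_code] = ActivityDef(
            activity_code=row.activity_code,
            label=row.label,
            activity_class=row.activity_class,
            p_level=row.p_level,
            decision_type=row.decision_type,
            mapped_services=services,
            location_policy=row.location_policy,
        )
    return catalog


def default_catalog() -> dict[str, ActivityDef]:
    return read_catalog_csv(io.StringIO(_DEFAULT_CATALOG_CSV))


@dataclass(frozen=True)
class ScheduleTemplate:
    template_id: int
    demographic_key: tuple[str, str, str, str]  # (age band, sex, race, ethnicity)
    day_type: str  # weekday | weekend
    hourly_activities: tuple[str, ...]

    def __post_init__(self):
        if len(self.hourly_activities) != 24:
            raise ConfigurationError("a template must cover exactly 24 hours")


@dataclass
class PoolConfig:
    """Knobs for the synthetic schedule-pool generator.

    Rates are per free hour except ``medical_visit_weekday_rate``, which is
    the chance that a given weekday template contains a clinic visit hour
    (default 0.015 ~ a handful of ambulatory visits per person-year).
    """

    sex_labels: tuple[str, ...] = ("female", "male")
    race_labels: tuple[str, ...] = ("black", "white", "other")
    ethnicity_labels: tuple[str, ...] = ("non_hispanic", "hispanic")
    min_templates: int = 2
    max_templates: int = 40
    health_maintenance_rate: float = 0.06
    medical_visit_weekday_rate: float = 0.015
    out_of_home_rate: float = 0.25
    p_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_P_RATES))


@dataclass
class SchedulePool:
    catalog: dict[str, ActivityDef]
    templates: list[ScheduleTemplate]
    p_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_P_RATES))

    def __post_init__(self):
        rates = [self.p_rates[k] for k in P_LEVELS]
        if rates[0] != 0:
            raise ConfigurationError("p rate for level 'none' must be 0")
        if any(b < a for a, b in zip(rates, rates[1:])) or rates[-1] > 1:
            raise ConfigurationError("p rates must satisfy 0=none<=low<=medium<=high<=1")
        self._index: dict[tuple, list[ScheduleTemplate]] = {}
        for t in self.templates:
            self._index.setdefault((t.demographic_key, t.day_type), []).append(t)
        for v in self._index.values():
            v.sort(key=lambda t: t.template_id)

    def matched_templates(self, agent_key: tuple[str, str, str, str], day_type: str) -> list[ScheduleTemplate]:
        """Templates for a demographic key; fallback drops ethnicity, then race."""
        exact = self._index.get((agent_key, day_type))
        if exact:
            return exact
        band, sex, race, eth = agent_key
        drop_eth = [
            t for (k, d), ts in self._index.items()
            if d == day_type and k[0] == band and k[1] == sex and k[2] == race
            for t in ts
        ]
        if drop_eth:
            return sorted(drop_eth, key=lambda t: t.template_id)
        drop_race = [
            t for (k, d), ts in self._index.items()
            if d == day_type and k[0] == band and k[1] == sex
            for t in ts
        ]
        if drop_race:
            return sorted(drop_race, key=lambda t: t.template_id)
        raise ConfigurationError(
            f"no schedule template for stratum {agent_key} ({day_type})"
        )


def agent_demographic_key(agent) -> tuple[str, str, str, str]:
    band = str(age_band(int(agent["age"])))
    return (band, agent["sex"], agent["race"], agent["ethnicity"])


def _stratum_templates(band, sex, race, eth, day_type, n_templates, cfg, catalog, rng, next_id):
    """Generate templates for one (stratum, day_type)."""
    lo, hi = (int(x) for x in band.split("-"))
    mid_age = (lo + hi) // 2
    in_school = mid_age <= 18
    working_age = 18 < mid_age <= 65
    senior = lo >= 66
    hm_codes = [
        c for c, a in catalog.items()
        if a.activity_class == "health_maintenance" and a.decision_type == "AB"
    ]
    if not senior and "senior_center" in hm_codes:
        hm_codes.remove("senior_center")
    home_fill = ["eating_home", "housework", "tv_leisure", "phone_calls", "helping_adults"]
    out_fill = ["grocery", "errands", "socializing", "commuting"]
    templates = []
    for _ in range(n_templates):
        hours = [""] * 24
        sleep_start = 21 + int(rng.random() * 3)  # 21..23
        sleep_len = 7 + int(rng.random() * 3)  # 7..9 (>= 6h required)
        for s in range(sleep_len):
            hours[(sleep_start + s) % 24] = "sleeping"
        # wake-up grooming hour
        wake = (sleep_start + sleep_len) % 24
        hours[wake] = "grooming"
        if day_type == "weekday" and in_school:
            for h in range(8, 15):
                if not hours[h]:
                    hours[h] = "school_attend"
        elif day_type == "weekday" and working_age:
            for h in range(9, 17):
                if not hours[h]:
                    hours[h] = "job_social" if rng.random() < 0.08 else "work"
        if day_type == "weekday" and cfg.medical_visit_weekday_rate > 0 and rng.random() < cfg.medical_visit_weekday_rate:
            slot = 10 + int(rng.random() * 7)  # 10..16
            hours[slot] = "medical_visit"
        for h in range(24):
            if hours[h]:
                continue
            u = rng.random()
            if hm_codes and u < cfg.health_maintenance_rate:
                hours[h] = hm_codes[int(rng.random() * len(hm_codes))]
            elif u < cfg.health_maintenance_rate + cfg.out_of_home_rate:
                hours[h] = out_fill[int(rng.random() * len(out_fill))]
            else:
                hours[h] = home_fill[int(rng.random() * len(home_fill))]
        templates.append(
            ScheduleTemplate(
                template_id=next_id + len(templates),
                demographic_key=(band, sex, race, eth),
                day_type=day_type,
                hourly_activities=tuple(hours),
            )
        )
    return templates


def build_synthetic_pool(config: PoolConfig | None = None, seed: int = 0,
                         catalog: dict[str, ActivityDef] | None = None) -> SchedulePool:
    """Generate a schedule pool covering every demographic stratum.

    Every (age band x sex x race x ethnicity, day type) stratum receives
    between ``min_templates`` and ``max_templates`` templates. Templates
    contain a 7-9 h sleep block, weekday work or school blocks for the
    relevant ages, and health-maintenance activities at the configured
    per-hour rate.
    """
    cfg = config or PoolConfig()
    if cfg.min_templates < 2:
        raise ConfigurationError("every stratum needs at least 2 templates")
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(seed)
    bands = [f"{lo}-{hi}" for lo, hi in AGE_BANDS]
    templates: list[ScheduleTemplate] = []
    next_id = 0
    for band in bands:
        for sex in cfg.sex_labels:
            for race in cfg.race_labels:
                for eth in cfg.ethnicity_labels:
                    for day_type in ("weekday", "weekend"):
                        k = cfg.min_templates + int(
                            rng.random() * (cfg.max_templates - cfg.min_templates + 1)
                        )
                        ts = _stratum_templates(
                            band, sex, race, eth, day_type, k, cfg, catalog, rng, next_id
                        )
                        templates.extend(ts)
                        next_id += len(ts)
    return SchedulePool(catalog=catalog, templates=templates, p_rates=dict(cfg.p_rates))


def draw_daily_schedule(agent, day_type: str, pool: SchedulePool, rng) -> ScheduleTemplate:
    """Uniform draw over the agent's matched templates (fresh every day).

    The draw consumes exactly one uniform from ``rng`` (canonical protocol:
    index = floor(u * n_matched) over templates sorted by template_id).
    """
    matched = pool.matched_templates(agent_demographic_key(agent), day_type)
    return matched[int(rng.random() * len(matched))]


def p_score(activity: ActivityDef, pool: SchedulePool) -> float:
    """Numeric information-receiving propensity for an activity."""
    return pool.p_rates[activity.p_level]


# Reporting age groups (<31, 31-45, 46-65, 65+). The printed third and
# fourth groups overlap at 65; we break at 65 so that 65 counts as "65+".
REPORT_GROUPS = (("<31", 16, 30), ("31-45", 31, 45), ("46-65", 46, 64), ("65+", 65, 200))


def _report_group(age: int) -> str:
    for label, lo, hi in REPORT_GROUPS:
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age} outside modeled range")


def service_exposure_minutes(pool: SchedulePool, agents: pd.DataFrame) -> pd.DataFrame:
    """Mean minutes/week of service-usable activity time by age group.

    For each agent, weekly minutes for an activity = 60 x (5 x mean weekday
    hours + 2 x mean weekend hours) averaged across the agent's matched
    templates; a service's minutes sum over the activities mapped to it.
    Returns a service_type x age-group table of means over agents.
    """
    if agents is None or not len(agents):
        raise ValueError("non-empty agent table required")
    services = sorted({s for a in pool.catalog.values() for s in a.mapped_services})
    svc_idx = {s: i for i, s in enumerate(services)}
    # cache per (demographic key): minutes per service
    cache: dict[tuple, np.ndarray] = {}
    groups = [g[0] for g in REPORT_GROUPS]
    sums = {g: np.zeros(len(services)) for g in groups}
    counts = {g: 0 for g in groups}
    for _, agent in agents.iterrows():
        key = agent_demographic_key(agent)
        if key not in cache:
            mins = np.zeros(len(services))
            for day_type, wt in (("weekday", 5.0), ("weekend", 2.0)):
                ts = pool.matched_templates(key, day_type)
                per_act: dict[str, float] = {}
                for t in ts:
                    for code in t.hourly_activities:
                        per_act[code] = per_act.get(code, 0.0) + 1.0
                for code, tot in per_act.items():
                    mean_hours = tot / len(ts)
                    for s in pool.catalog[code].mapped_services:
                        mins[svc_idx[s]] += 60.0 * wt * mean_hours
            cache[key] = mins
        g = _report_group(int(agent["age"]))
        sums[g] += cache[key]
        counts[g] += 1
    out = pd.DataFrame(
        {g: (sums[g] / counts[g] if counts[g] else np.zeros(len(services))) for g in groups},
        index=pd.Index(services, name="service_type"),
    )
    return out


def write_pool(pool: SchedulePool, out_dir) -> None:
    """Serialize the catalog and templates to activities.csv / schedules.csv."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    cat = pd.DataFrame(
        [
            {
                "activity_code": a.activity_code,
                "label": a.label,
                "activity_class": a.activity_class,
                "p_level": a.p_level,
                "decision_type": a.decision_type,
                "mapped_services": ";".join(sorted(a.mapped_services)),
                "location_policy": a.location_policy,
            }
            for a in pool.catalog.values()
        ]
    )
    cat.to_csv(os.path.join(out_dir, "activities.csv"), index=False)
    rows = []
    for t in pool.templates:
        row = {
            "template_id": t.template_id,
            "age_band": t.demographic_key[0],
            "sex": t.demographic_key[1],
            "race": t.demographic_key[2],
            "ethnicity": t.demographic_key[3],
            "day_type": t.day_type,
        }
        row.update({f"h{h:02d}": t.hourly_activities[h] for h in range(24)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "schedules.csv"), index=False)
    pd.Series(pool.p_rates).rename("rate").rename_axis("p_level").to_csv(
        os.path.join(out_dir, "p_rates.csv")
    )


def read_pool(in_dir) -> SchedulePool:
    import os

    catalog = read_catalog_csv(os.path.join(in_dir, "activities.csv"))
    df = pd.read_csv(os.path.join(in_dir, "schedules.csv"), keep_default_na=False)
    templates = [
        ScheduleTemplate(
            template_id=int(r.template_id),
            demographic_key=(r.age_band, r.sex, r.race, r.ethnicity),
            day_type=r.day_type,
            hourly_activities=tuple(getattr(r, f"h{h:02d}") for h in range(24)),
        )
        for r in df.itertuples(index=False)
    ]
    p_path = os.path.join(in_dir, "p_rates.csv")
    p_rates = dict(DEFAULT_P_RATES)
    if os.path.exists(p_path):
        pr = pd.read_csv(p_path)
        p_rates = dict(zip(pr["p_level"], pr["rate"]))
    return SchedulePool(catalog=catalog, templates=templates, p_rates=p_rates)
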