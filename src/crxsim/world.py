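"""Synthetic world generation: agents, places and resources.

The world is the static environment of the simulation: a demographically
heterogeneous population of agents aged 16+ anchored to households (and
optionally workplaces/schools), plus geolocated clinics and resource sites.
A *resource* is a specific service offered at a specific place; agents later
accumulate and exchange knowledge about resources.

Everything is table-backed (pandas) and fully deterministic under a fixed
seed. Coordinates live either on a planar km frame (default, a 16 km x 16 km
box standing in for a ~106 mi^2 urban region) or on WGS84 lat/lon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AGE_BANDS",
    "DemographicConfig",
    "World",
    "generate_world",
    "distance",
    "pairwise_distance",
    "nearest_resources",
    "age_band",
    "write_world",
    "read_world",
]

# Age bands partitioning [16, 94]; weights chosen so that uniform ages within
# bands give a population mean age of ~44.5 (16-30:23, 31-45:38, 46-65:55.5,
# 66-94:80 -> 0.30*23 + 0.28*38 + 0.27*55.5 + 0.15*80 = 44.5).
AGE_BANDS: tuple[tuple[int, int], ...] = ((16, 30), (31, 45), (46, 65), (66, 94))
DEFAULT_AGE_WEIGHTS = {"16-30": 0.30, "31-45": 0.28, "46-65": 0.27, "66-94": 0.15}

PLACE_KINDS = ("household", "workplace", "school", "clinic", "resource_site")

DEFAULT_SERVICE_TYPES = (
    "spiritual_services",
    "fitness",
    "group_exercise",
    "walking_group",
    "weight_management",
    "nutrition_counseling",
    "smoking_cessation",
    "mental_health_counseling",
    "support_group",
    "food_pantry",
    "fresh_produce",
    "fill_prescriptions",
    "home_care",
    "medical_supplies",
    "senior_services",
)


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check_proportions(name: str, mapping: dict[str, float]) -> None:
    total = sum(mapping.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{name} proportions sum to {total}, expected 1")
    if any(v < 0 for v in mapping.values()):
        raise ConfigurationError(f"{name} proportions must be non-negative")


@dataclass
class DemographicConfig:
    """Marginal distributions and environment counts for world generation.

    Defaults emulate a predominantly African American/Black, majority-female
    urban community (56% female, 84% non-Hispanic, 59% Black; ages 16-94 with
    mean ~44).
    """

    n_agents: int = 10_000
    sex_proportions: dict[str, float] = field(
        default_factory=lambda: {"female": 0.56, "male": 0.44}
    )
    ethnicity_proportions: dict[str, float] = field(
        default_factory=lambda: {"non_hispanic": 0.84, "hispanic": 0.16}
    )
    race_proportions: dict[str, float] = field(
        default_factory=lambda: {"black": 0.59, "white": 0.28, "other": 0.13}
    )
    age_band_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_WEIGHTS)
    )
    # Planar bounding box, km. (x_min, y_min, x_max, y_max).
    bounding_box: tuple[float, float, float, float] = (0.0, 0.0, 16.0, 16.0)
    coordinate_frame: str = "planar_km"
    n_households: int | None = None
    n_workplaces: int | None = None
    n_schools: int | None = None
    n_clinics: int | None = None
    n_resource_sites: int | None = None
    # services per resource site drawn uniformly from this inclusive range
    services_per_site: tuple[int, int] = (1, 3)
    service_types: tuple[str, ...] = DEFAULT_SERVICE_TYPES
    employment_rate: float = 0.65
    school_age_max: int = 18
    working_age_max: int = 65
    # activation alpha_i ~ Beta(a, b); inertia gamma_j ~ Uniform(lo, hi)
    activation_beta_params: tuple[float, float] = (2.0, 2.0)
    inertia_range: tuple[float, float] = (0.5, 1.0)

    def resolved_counts(self) -> dict[str, int]:
        """Environment counts, scaled from n_agents where not set explicitly."""
        n = max(self.n_agents, 1)
        return {
            "household": self.n_households if self.n_households is not None else max(1, round(n / 2.5)),
            "workplace": self.n_workplaces if self.n_workplaces is not None else max(1, n // 25),
            "school": self.n_schools if self.n_schools is not None else max(1, n // 500),
            "clinic": self.n_clinics if self.n_clinics is not None else max(1, n // 1000),
            "resource_site": self.n_resource_sites if self.n_resource_sites is not None else max(10, n // 20),
        }

    def validate(self) -> None:
        if self.n_agents < 0:
            raise ConfigurationError("n_agents must be >= 0")
        _check_proportions("sex", self.sex_proportions)
        _check_proportions("ethnicity", self.ethnicity_proportions)
        _check_proportions("race", self.race_proportions)
        _check_proportions("age_band", self.age_band_weights)
        bands = sorted(
            tuple(int(x) for x in k.split("-")) for k in self.age_band_weights
        )
        if bands[0][0] != 16 or bands[-1][1] != 94:
            raise ConfigurationError("age bands must span [16, 94]")
        for (_, hi), (lo2, _) in zip(bands, bands[1:]):
            if lo2 != hi + 1:
                raise ConfigurationError("age bands must partition [16, 94]")
        if self.coordinate_frame not in ("planar_km", "wgs84"):
            raise ConfigurationError(f"unknown frame {self.coordinate_frame!r}")


@dataclass
class World:
    """Static simulation environment: agent, place and resource tables."""

    agents: pd.DataFrame
    places: pd.DataFrame
    resources: pd.DataFrame
    frame: str = "planar_km"
    seed: int | None = None
    config: DemographicConfig | None = None

    def validate(self) -> None:
        """Referential-integrity check across id columns."""
        place_ids = set(self.places["place_id"])
        if len(self.agents):
            if not set(self.agents["household_id"]).issubset(place_ids):
                raise ValueError("agent household_id not resolvable")
            for col in ("workplace_id", "school_id"):
                refs = set(self.agents.loc[self.agents[col] >= 0, col])
                if not refs.issubset(place_ids):
                    raise ValueError(f"agent {col} not resolvable")
        if len(self.resources):
            if not set(self.resources["place_id"]).issubset(place_ids):
                raise ValueError("resource place_id not resolvable")
            kinds = self.places.set_index("place_id")["kind"]
            rk = kinds.loc[self.resources["place_id"]].values
            if not np.isin(rk, ("resource_site", "clinic")).all():
                raise ValueError("resources must live at resource sites or clinics")
            dup = self.resources.duplicated(subset=["place_id", "service_type"])
            if dup.any():
                raise ValueError("(place_id, service_type) must be unique")

    def place_coords(self) -> np.ndarray:
        return self.places[["x", "y"]].to_numpy(float)


def age_band(age: int | np.ndarray) -> np.ndarray:
    """Label ages with the generation band they fall in (16-30 ... 66-94)."""
    edges = np.array([b[0] for b in AGE_BANDS[1:]])
    labels = np.array([f"{lo}-{hi}" for lo, hi in AGE_BANDS])
    return labels[np.searchsorted(edges, np.asarray(age), side="right")]


def generate_world(config: DemographicConfig, seed: int) -> World:
    """Generate a synthetic world from demographic marginals.

    Agents are drawn independently from the configured marginals (ages
    uniform within weighted bands), assigned a household uniformly at random,
    and — depending on age — a school (<= school_age_max) or, with
    probability ``employment_rate``, a workplace (<= working_age_max).
    Places are scattered uniformly in the bounding box.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_agents
    counts = config.resolved_counts()

    # --- places ---
    rows = []
    next_id = 0
    for kind in PLACE_KINDS:
        c = counts[kind]
        x0, y0, x1, y1 = config.bounding_box
        xs = rng.uniform(x0, x1, c)
        ys = rng.uniform(y0, y1, c)
        rows.append(
            pd.DataFrame(
                {
                    "place_id": np.arange(next_id, next_id + c),
                    "kind": kind,
                    "x": xs,
                    "y": ys,
                }
            )
        )
        next_id += c
    places = pd.concat(rows, ignore_index=True)

    by_kind = {k: places.loc[places["kind"] == k, "place_id"].to_numpy() for k in PLACE_KINDS}

    # --- agents ---
    band_labels = list(config.age_band_weights)
    band_bounds = {k: tuple(int(x) for x in k.split("-")) for k in band_labels}
    weights = np.array([config.age_band_weights[k] for k in band_labels])
    band_idx = rng.choice(len(band_labels), size=n, p=weights)
    los = np.array([band_bounds[k][0] for k in band_labels])[band_idx]
    his = np.array([band_bounds[k][1] for k in band_labels])[band_idx]
    ages = los + np.floor(rng.random(n) * (his - los + 1)).astype(int)

    def _cat(props: dict[str, float]) -> np.ndarray:
        labels = list(props)
        return np.array(labels)[rng.choice(len(labels), size=n, p=np.array([props[k] for k in labels]))]

    sex = _cat(config.sex_proportions)
    race = _cat(config.race_proportions)
    eth = _cat(config.ethnicity_proportions)
    household = rng.choice(by_kind["household"], size=n) if n else np.array([], dtype=int)

    school_id = np.full(n, -1, dtype=int)
    work_id = np.full(n, -1, dtype=int)
    in_school = ages <= config.school_age_max
    if in_school.any():
        school_id[in_school] = rng.choice(by_kind["school"], size=int(in_school.sum()))
    can_work = (~in_school) & (ages <= config.working_age_max)
    employed = can_work & (rng.random(n) < config.employment_rate)
    if employed.any():
        work_id[employed] = rng.choice(by_kind["workplace"], size=int(employed.sum()))

    activation = rng.beta(*config.activation_beta_params, size=n)

    agents = pd.DataFrame(
        {
            "agent_id": np.arange(n),
            "age": ages,
            "sex": sex,
            "race": race,
            "ethnicity": eth,
            "household_id": household,
            "workplace_id": work_id,
            "school_id": school_id,
            "preferred_language": "",
            "conditions": "",
            "activation": activation,
        }
    )

    # --- resources: each resource site offers 1..k distinct services ---
    lo, hi = config.services_per_site
    sites = by_kind["resource_site"]
    n_services = rng.integers(lo, hi + 1, size=len(sites))
    svc = np.array(config.service_types)
    r_place, r_service = [], []
    for pid, k in zip(sites, n_services):
        chosen = rng.choice(len(svc), size=min(k, len(svc)), replace=False)
        for c in sorted(chosen):
            r_place.append(pid)
            r_service.append(svc[c])
    resources = pd.DataFrame(
        {
            "resource_id": np.arange(len(r_place)),
            "place_id": np.array(r_place, dtype=int),
            "service_type": r_service,
            "inertia": rng.uniform(*config.inertia_range, size=len(r_place)),
        }
    )

    world = World(agents=agents, places=places, resources=resources,
                  frame=config.coordinate_frame, seed=seed, config=config)
    world.validate()
    return world


_EARTH_RADIUS_KM = 6371.0088


def _haversine(lat1, lon1, lat2, lon2):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def distance(a, b, frame: str = "planar_km") -> float:
    """Distance in km between two places (rows or (x, y) pairs).

    Euclidean on the planar frame; haversine on wgs84 where x=lat, y=lon.
    """
    ax, ay = (a["x"], a["y"]) if hasattr(a, "__getitem__") and not isinstance(a, (tuple, list)) else (a[0], a[1])
    bx, by = (b["x"], b["y"]) if hasattr(b, "__getitem__") and not isinstance(b, (tuple, list)) else (b[0], b[1])
    if frame == "planar_km":
        return math.hypot(ax - bx, ay - by)
    if frame == "wgs84":
        return float(_haversine(ax, ay, bx, by))
    raise ValueError(f"unknown or mixed coordinate frame {frame!r}")


def pairwise_distance(origin_xy: np.ndarray, coords: np.ndarray, frame: str = "planar_km") -> np.ndarray:
    """Distances (km) from one origin to an (n, 2) array of coordinates."""
    coords = np.asarray(coords, dtype=float)
    if frame == "planar_km":
        d = coords - np.asarray(origin_xy, dtype=float)
        return np.hypot(d[:, 0], d[:, 1])
    if frame == "wgs84":
        return _haversine(origin_xy[0], origin_xy[1], coords[:, 0], coords[:, 1])
    raise ValueError(f"unknown coordinate frame {frame!r}")


def nearest_resources(world: World, origin, service_type: str, k: int) -> pd.DataFrame:
    """The k resources of ``service_type`` nearest to ``origin``.

    Ascending distance, ties broken by resource_id; an unknown service type
    yields an empty frame. ``origin`` is a place row or an (x, y) pair.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    sub = world.resources[world.resources["service_type"] == service_type]
    if k == 0 or sub.empty:
        return sub.iloc[0:0].assign(distance_km=pd.Series(dtype=float))
    coords = world.places.set_index("place_id").loc[sub["place_id"], ["x", "y"]].to_numpy(float)
    if hasattr(origin, "__getitem__") and not isinstance(origin, (tuple, list, np.ndarray)):
        oxy = (origin["x"], origin["y"])
    else:
        oxy = (origin[0], origin[1])
    d = pairwise_distance(np.asarray(oxy, float), coords, world.frame)
    order = np.lexsort((sub["resource_id"].to_numpy(), d))[:k]
    out = sub.iloc[order].copy()
    out["distance_km"] = d[order]
    return out.reset_index(drop=True)


def write_world(world: World, out_dir) -> None:
    """Serialize a world to agents.csv / places.csv / resources.csv + meta."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    world.agents.to_csv(os.path.join(out_dir, "agents.csv"), index=False)
    world.places.to_csv(os.path.join(out_dir, "places.csv"), index=False)
    world.resources.to_csv(os.path.join(out_dir, "resources.csv"), index=False)
    meta = {"frame": world.frame, "seed": world.seed}
    if world.config is not None:
        cfg = asdict(world.config)
        cfg["bounding_box"] = list(cfg["bounding_box"])
        cfg["service_types"] = list(cfg["service_types"])
        meta["config"] = cfg
    with open(os.path.join(out_dir, "world_meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_world(in_dir) -> World:
    """Load a world from CSV tables written by :func:`write_world` (or
    externally supplied tables with the same schemas)."""
    import os

    agents = pd.read_csv(os.path.join(in_dir, "agents.csv"), keep_default_na=False)
    places = pd.read_csv(os.path.join(in_dir, "places.csv"))
    resources = pd.read_csv(os.path.join(in_dir, "resources.csv"))
    frame, seed = "planar_km", None
    meta_path = os.path.join(in_dir, "world_meta.yaml")
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
        frame = meta.get("frame", frame)
        seed = meta.get("seed")
    w = World(agents=agents, places=places, resources=resources, frame=frame, seed=seed)
    w.validate()
    return w
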