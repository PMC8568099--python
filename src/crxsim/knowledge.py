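"""Per-agent resource knowledge: dosing boosts, decay, seeding and capped
memory.

An agent's knowledge about resource j is a score beta in [0, 1]. A dose of
information from source x updates it as

    beta' = lambda * beta**eps_x * (1 - beta) + beta

where smaller eps_x means a stronger source (Doctor 0.05 < Nurse 0.15 <
Use 0.2 < ClinicalStaff 0.25 < Peer 0.9). Between doses knowledge recedes.
Because the update with eps_None = 1 *grows* beta rather than shrinking it,
the default decay mode is geometric (beta <- lambda**dt * beta per idle
hour, applied lazily); the literal per-hour application of the update with
eps_None is retained as ``as_printed`` for fidelity experiments.

Stores hold at most ``capacity`` entries (default 200, a bounded-memory
assumption); at capacity, a new entry displaces the current minimum-beta
entry only if it beats it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .world import World, pairwise_distance

__all__ = [
    "DOSE_SOURCES",
    "DoseSourceTable",
    "KnowledgeParams",
    "KnowledgeEntry",
    "KnowledgeStore",
    "SeedingParams",
    "boost",
    "decay",
    "seed_knowledge",
    "upsert",
    "snapshot_frame",
    "beta_trajectory",
]

DOSE_SOURCES = ("Doctor", "Nurse", "ClinicalStaff", "Use", "Peer", "None")
_DEFAULT_EPS = {
    "Doctor": 0.05,
    "Nurse": 0.15,
    "ClinicalStaff": 0.25,
    "Use": 0.2,
    "Peer": 0.9,
    "None": 1.0,
}


@dataclass
class DoseSourceTable:
    """Source -> epsilon exponent; smaller epsilon = stronger boost."""

    eps: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_EPS))

    def __post_init__(self):
        for src, e in self.eps.items():
            if not (0 < e <= 1):
                raise ValueError(f"eps[{src}] must be in (0, 1], got {e}")

    def __getitem__(self, source: str) -> float:
        try:
            return self.eps[source]
        except KeyError:
            raise KeyError(f"unknown dose source {source!r}") from None


@dataclass
class KnowledgeParams:
    lambda_decay: float = 0.991
    sources: DoseSourceTable = field(default_factory=DoseSourceTable)
    capacity: int = 200
    decay_mode: str = "geometric"  # geometric | as_printed
    # beta assigned to a resource first learned of through a dose
    # (0 is a fixed point of the boost, so doses about unknown resources
    # must start from a non-zero floor)
    novel_beta: float = 0.1

    def __post_init__(self):
        if not (0.991 - 1e-12 <= self.lambda_decay <= 0.9994 + 1e-12):
            raise ValueError("lambda must lie in the allowable range [0.991, 0.9994]")
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")
        if self.decay_mode not in ("geometric", "as_printed"):
            raise ValueError(f"unknown decay_mode {self.decay_mode!r}")


def boost(beta: float, source: str, params: KnowledgeParams) -> float:
    """One information dose from ``source``: lambda*beta^eps*(1-beta)+beta.

    Monotone non-decreasing in beta with fixed points at 0 and 1.
    """
    if not (0.0 <= beta <= 1.0):
        raise ValueError(f"beta out of [0,1]: {beta}")
    eps = params.sources[source]
    b = params.lambda_decay * beta**eps * (1.0 - beta) + beta
    return min(b, 1.0)


def decay(beta: float, dt_hours: int, params: KnowledgeParams) -> float:
    """Knowledge recession over ``dt_hours`` idle hours.

    geometric: beta * lambda**dt. as_printed: dt applications of the dosing
    update with the 'None' source (note this *raises* beta; kept for
    fidelity with the printed functional form).
    """
    if dt_hours < 0:
        raise ValueError("dt_hours must be >= 0")
    if dt_hours == 0 or beta == 0.0:
        return beta
    if params.decay_mode == "geometric":
        return beta * params.lambda_decay**dt_hours
    for _ in range(dt_hours):
        beta = boost(beta, "None", params)
    return beta


@dataclass
class KnowledgeEntry:
    resource_id: int
    beta: float
    last_update: int = 0
    rx_derived: bool = False


class KnowledgeStore:
    """Capped mapping resource_id -> KnowledgeEntry with lazy decay.

    Stored betas are the values at ``last_update``; reads at a later hour
    decay them on the fly. Under geometric decay all entries shrink by the
    same factor per hour, so the beta ordering (hence the argmax used when
    sharing, and the argmin used when evicting) is invariant over time.
    """

    __slots__ = ("owner", "params", "entries", "_top")

    def __init__(self, owner: int, params: KnowledgeParams):
        self.owner = owner
        self.params = params
        self.entries: dict[int, KnowledgeEntry] = {}
        self._top: int | None = None  # resource_id of max-beta entry

    def __len__(self) -> int:
        return len(self.entries)

    def current_beta(self, resource_id: int, t: int) -> float:
        e = self.entries[resource_id]
        return decay(e.beta, t - e.last_update, self.params)

    def _beats(self, beta_a: float, rid_a: int, beta_b: float, rid_b: int) -> bool:
        return beta_a > beta_b or (beta_a == beta_b and rid_a < rid_b)

    def top_entry(self, t: int) -> tuple[int, float, bool] | None:
        """(resource_id, current beta, rx_derived) of the max-beta entry."""
        if self._top is None:
            return None
        e = self.entries[self._top]
        return (e.resource_id, self.current_beta(e.resource_id, t), e.rx_derived)

    def top_entries(self, t: int, k: int) -> list[tuple[int, float, bool]]:
        """The k highest-beta entries, descending (ties by resource_id)."""
        cur = [(self.current_beta(r, t), -r) for r in self.entries]
        order = sorted(cur, reverse=True)[:k]
        return [(-nr, b, self.entries[-nr].rx_derived) for b, nr in order]

    def _recompute_top(self, t: int) -> None:
        best, best_b = None, -1.0
        for rid, e in self.entries.items():
            b = decay(e.beta, t - e.last_update, self.params)
            if best is None or self._beats(b, rid, best_b, best):
                best, best_b = rid, b
        self._top = best

    def upsert(self, resource_id: int, new_beta: float, t: int,
               rx_flag: bool = False) -> int | None:
        """Insert/replace an entry; returns the evicted resource_id if any.

        At capacity a new resource enters only if its beta beats the current
        minimum (ties broken toward the smaller resource_id surviving).
        """
        if not (0.0 <= new_beta <= 1.0):
            raise ValueError("beta out of [0,1]")
        entries = self.entries
        e = entries.get(resource_id)
        if e is not None:
            old_cur = decay(e.beta, t - e.last_update, self.params)
            e.beta, e.last_update = new_beta, t
            e.rx_derived = e.rx_derived or rx_flag
            if self._top == resource_id:
                if new_beta < old_cur:
                    self._recompute_top(t)  # replacement lowered the top
            else:
                top = entries[self._top]
                if self._beats(new_beta, resource_id,
                               decay(top.beta, t - top.last_update, self.params), top.resource_id):
                    self._top = resource_id
            return None
        evicted = None
        if len(entries) >= self.params.capacity:
            worst, worst_b = None, 2.0
            for rid, ent in entries.items():
                b = decay(ent.beta, t - ent.last_update, self.params)
                if worst is None or b < worst_b or (b == worst_b and rid > worst):
                    worst, worst_b = rid, b
            if not (new_beta > worst_b):
                return None  # discarded: does not beat the current minimum
            del entries[worst]
            evicted = worst
            if self._top == worst:
                self._recompute_top(t)
        entries[resource_id] = KnowledgeEntry(resource_id, new_beta, t, rx_flag)
        if self._top is None:
            self._top = resource_id
        else:
            top = entries[self._top]
            if self._beats(new_beta, resource_id,
                           decay(top.beta, t - top.last_update, self.params), top.resource_id):
                self._top = resource_id
        return evicted

    def dose(self, resource_id: int, source: str, t: int,
             rx_flag: bool = False) -> float:
        """Apply one dose at hour t (decaying first), return the new beta."""
        if resource_id in self.entries:
            b = self.current_beta(resource_id, t)
        else:
            b = self.params.novel_beta
        b2 = boost(b, source, self.params)
        self.upsert(resource_id, b2, t, rx_flag=rx_flag)
        return b2


def upsert(store: KnowledgeStore, resource_id: int, new_beta: float,
           rx_flag: bool, params: KnowledgeParams, t: int = 0) -> int | None:
    """Functional alias for :meth:`KnowledgeStore.upsert`."""
    assert store.params is params or store.params == params
    return store.upsert(resource_id, new_beta, t, rx_flag=rx_flag)


@dataclass
class SeedingParams:
    """Distance-stratified initial knowledge seeding around the household.

    Defaults: 10-100 resources within 1 mile, 1-5 within 1-3 miles, 1-5
    beyond 3 miles; initial beta ~ Uniform(0.1, 0.5).
    """

    low_radius_km: float = 1.609
    mid_radius_km: float = 4.83
    low_count_range: tuple[int, int] = (10, 100)
    mid_count_range: tuple[int, int] = (1, 5)
    far_count_range: tuple[int, int] = (1, 5)
    initial_beta_range: tuple[float, float] = (0.1, 0.5)

    def __post_init__(self):
        if not (0 < self.low_radius_km < self.mid_radius_km):
            raise ValueError("radii must be strictly increasing")
        for r in (self.low_count_range, self.mid_count_range, self.far_count_range):
            if r[0] > r[1]:
                raise ValueError("count range min must be <= max")


def household_distance_strata(world: World, sp: "SeedingParams") -> dict[int, tuple]:
    """Per-household (low, mid, far) resource-id arrays by distance stratum.

    Vectorized precomputation shared by the engine and seeding utilities.
    """
    out: dict[int, tuple] = {}
    if not len(world.resources):
        empty = np.empty(0, dtype=np.int64)
        for hid in world.agents["household_id"].unique():
            out[int(hid)] = (empty, empty, empty)
        return out
    places = world.places.set_index("place_id")
    coords = places.loc[world.resources["place_id"], ["x", "y"]].to_numpy(float)
    rids = world.resources["resource_id"].to_numpy(np.int64)
    for hid in np.unique(world.agents["household_id"].to_numpy()):
        home = places.loc[int(hid)]
        d = pairwise_distance(np.array([home["x"], home["y"]], float), coords, world.frame)
        out[int(hid)] = (
            rids[d < sp.low_radius_km],
            rids[(d >= sp.low_radius_km) & (d < sp.mid_radius_km)],
            rids[d >= sp.mid_radius_km],
        )
    return out


def _sample_without_replacement(pool: np.ndarray, k: int, rng) -> list[int]:
    """Partial Fisher-Yates over ``pool`` consuming k uniforms (canonical)."""
    idx = list(range(len(pool)))
    out = []
    for j in range(min(k, len(idx))):
        r = j + int(rng.random() * (len(idx) - j))
        idx[j], idx[r] = idx[r], idx[j]
        out.append(int(pool[idx[j]]))
    return out


def seed_knowledge(agent, world: World, sp: SeedingParams,
                   params: KnowledgeParams, rng,
                   _dist_cache: dict | None = None) -> KnowledgeStore:
    """Seed an agent's store with resources stratified by household distance.

    Counts are drawn uniformly from each stratum's range (clipped to the
    stratum size); sampling is without replacement within each stratum;
    initial betas are uniform in ``initial_beta_range``; nothing is flagged
    as referral-derived.
    """
    store = KnowledgeStore(int(agent["agent_id"]), params)
    if not len(world.resources):
        return store
    hid = int(agent["household_id"])
    if _dist_cache is not None and hid in _dist_cache:
        strata = _dist_cache[hid]
    else:
        home = world.places.set_index("place_id").loc[hid]
        coords = world.places.set_index("place_id").loc[
            world.resources["place_id"], ["x", "y"]
        ].to_numpy(float)
        d = pairwise_distance(np.array([home["x"], home["y"]], float), coords, world.frame)
        rids = world.resources["resource_id"].to_numpy()
        strata = (
            rids[d < sp.low_radius_km],
            rids[(d >= sp.low_radius_km) & (d < sp.mid_radius_km)],
            rids[d >= sp.mid_radius_km],
        )
        if _dist_cache is not None:
            _dist_cache[hid] = strata
    t = 0
    lo_b, hi_b = sp.initial_beta_range
    for pool, (cmin, cmax) in zip(
        strata, (sp.low_count_range, sp.mid_count_range, sp.far_count_range)
    ):
        count = cmin + int(rng.random() * (cmax - cmin + 1))
        for rid in _sample_without_replacement(pool, count, rng):
            b = lo_b + rng.random() * (hi_b - lo_b)
            store.upsert(rid, b, t, rx_flag=False)
    return store


def snapshot_frame(stores: dict[int, KnowledgeStore] | list[KnowledgeStore],
                   t: int) -> pd.DataFrame:
    """Flatten stores into (agent_id, resource_id, beta, rx_derived, last_update)."""
    if isinstance(stores, dict):
        stores = [stores[k] for k in sorted(stores)]
    agent_ids, rids, betas, rx, last = [], [], [], [], []
    for s in stores:
        for rid in sorted(s.entries):
            e = s.entries[rid]
            agent_ids.append(s.owner)
            rids.append(rid)
            betas.append(decay(e.beta, t - e.last_update, s.params))
            rx.append(e.rx_derived)
            last.append(e.last_update)
    return pd.DataFrame(
        {
            "agent_id": np.array(agent_ids, dtype=int),
            "resource_id": np.array(rids, dtype=int),
            "beta": np.array(betas, dtype=float),
            "rx_derived": np.array(rx, dtype=bool),
            "last_update": np.array(last, dtype=int),
        }
    )


def beta_trajectory(dose_events: pd.DataFrame, params: KnowledgeParams,
                    t_end: int, beta0: float = 0.0) -> pd.DataFrame:
    """Hourly beta series for one (agent, resource) pair from its dose log.

    ``dose_events`` needs columns (hour, source), ascending. Reproduces the
    piecewise dynamic: a boost at each dose hour, decay in between.
    """
    events = dose_events.sort_values("hour")
    beta = beta0
    series = np.empty(t_end + 1)
    it = events.itertuples(index=False)
    nxt = next(it, None)
    for t in range(t_end + 1):
        if t > 0:
            beta = decay(beta, 1, params)
        while nxt is not None and int(nxt.hour) == t:
            if beta == 0.0:
                beta = params.novel_beta
            beta = boost(beta, nxt.source, params)
            nxt = next(it, None)
        series[t] = beta
    return pd.DataFrame({"hour": np.arange(t_end + 1), "beta": series})
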