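# Methods

`crxsim` is a desk-scale agent-based model of how community-resource
information, delivered to patients at clinical encounters as a personalized
referral list, diffuses through a population via face-to-face co-location
and drives resource-use decisions. This note documents the model, its
parameters, the synthetic data generators, and the numerical and design
choices behind the implementation.

## Model overview

The simulated world contains a static population of agents aged 16–94 and a
static environment of geolocated places: households, workplaces, schools,
clinics, and resource sites. A *resource* is one service type (e.g.
`fitness`, `food_pantry`) offered at one place. Time advances in one-hour
steps; runs default to 28 days, with the first 14 days flagged as burn-in
(events are flagged, never dropped) and week 3 used as the default
measurement window, where behaviour has typically stabilized.

Each hour, five things happen in a fixed order:

1. **Movement.** Every agent performs the activity given by that day's
   schedule template and moves to its location (home, workplace, school,
   clinic, or a uniformly drawn non-household place within 5 km of home for
   out-of-home activities). Health-maintenance activities are held pending
   until step 4.
2. **Clinical dosing.** An agent whose activity is a clinic-visit trigger
   moves to the nearest clinic; at most once per simulated day they receive
   a referral list of up to 40 resources, each item applying one knowledge
   dose whose strength depends on the configured delivery mode
   (physician → Doctor, nurse → Nurse, clerk → ClinicalStaff).
3. **Social exchange.** At each place with at least two occupants, each
   *receiver* whose current activity has a positive sharing propensity
   tests up to `m = 10` potential givers; each test fires independently
   with probability equal to the receiver's activity p-score. Firing pairs
   are matched to distinct co-located givers sampled uniformly without
   replacement; each giver transmits their best-known resource (highest
   knowledge score; a `beta_weighted` sampling policy is also available),
   and the receiver gets a Peer dose. Receiver characteristics other than
   the activity never modulate the probability.
4. **Use/continue decisions.** For a pending health-maintenance activity
   the agent scores every known resource matching the activity's services
   and uses the best one if the score exceeds their activation threshold
   (decision A: move there, log a use event, receive a Use dose);
   otherwise they continue the previous hour's activity in place
   (decision B).
5. **Decay bookkeeping.** Knowledge decay is applied lazily (below).

## Knowledge dynamics

Agent *i*'s knowledge of resource *j* is a score β ∈ [0, 1]. A dose from
source *x* updates it as

    β' = λ · β^ε_x · (1 − β) + β

with λ = 0.991 (allowable range 0.991–0.9994) and source exponents
ε = {Doctor 0.05, Nurse 0.15, ClinicalStaff 0.25, Use 0.2, Peer 0.9,
None 1.0}; smaller exponents give stronger boosts, so the source-influence
ordering Doctor > Nurse > Use > ClinicalStaff > Peer holds at every
interior β. The update has fixed points at 0 and 1.

**Decay.** The printed functional form applied with ε_None = 1 *increases*
β, which contradicts λ's role as a decay parameter. The default decay mode
is therefore geometric — β ← λ^Δt · β per idle hour — applied lazily at
read/update time from each entry's `last_update` stamp (composing one-hour
steps and a single Δt-hour step agree to 1e-12). The literal per-hour
application of the ε_None update is retained as `decay_mode="as_printed"`
for fidelity experiments; the choice is config-exposed and the original
intent is not guessed.

**Novel resources.** Because β = 0 is a fixed point, a dose about an
unknown resource could never create knowledge; new entries created by any
dose therefore start at `novel_beta = 0.1` before the boost is applied.

**Bounded memory.** Stores hold at most 200 entries. At capacity a new
entry displaces the current minimum-β entry only if it beats it; ties
break toward the smaller resource id. Eviction is the model's notion of
forgetting: "retained" knowledge means present in the store.

**Seeding.** At initialization each agent knows 10–100 resources within
1 mile (1.609 km) of their household, 1–5 within 1–3 miles, and 1–5 beyond
3 miles (counts drawn uniformly, clipped to stratum size; sampling without
replacement). Seeded β is Uniform(0.1, 0.5) — the seeding *counts* are
prescribed by the design, the seeded β level is our choice (knowledge you
merely start with should be weaker than a fresh clinical dose, stronger
than nothing).

## Decisions

The use/continue decision compares `β_ij · δ_ij · γ_j` against the agent's
activation threshold α_i. As printed, the decision rule multiplies by
"distance", which would make farther resources more attractive; since the
narrative describes distance as effort to overcome, δ is implemented as a
decreasing distance factor δ = exp(−d/d₀) ∈ (0, 1] with d₀ = 2 km.
α_i ~ Beta(2, 2) (a unimodal activation distribution centred at 0.5; no
distribution is published) and resource inertia γ_j ~ Uniform(0.5, 1.0);
all three are config-exposed.

## Referral-list generation

An agent's indicated service types are the union of a base set keyed to
age band (so every list is non-empty) and the services indicated by their
assigned conditions. Conditions come from a synthetic catalog of ten
common chronic and social conditions with age-graded, sex-specific
prevalences (independent Bernoulli draws per agent and condition);
preferred language is drawn from configured weights. For each indicated
service, resources are ranked by distance from the agent's household
(ties by resource id); the 40-item list is filled round-robin across
services, nearest first, de-duplicated and truncated. The in-vivo ranking
rule is not published; round-robin nearest-first is a documented stand-in
that guarantees service coverage and full determinism.

## Synthetic data generators

**World.** Agents are drawn i.i.d. from configurable marginals; defaults
emulate the study community: 56% female, 59% Black, 84% non-Hispanic, ages
uniform within bands 16–30/31–45/46–65/66–94 weighted 0.30/0.28/0.27/0.15.
The implied mean age is 44.5 (band means 23/38/55.5/80), verified
analytically against the target of 44 ± 1 before the defaults were locked.
Places are uniform on a 16 km × 16 km planar box (a stand-in for a
~106 mi² urban region; WGS84 is supported for real coordinates). Default
counts scale with n: one household per 2.5 agents, one workplace per 25,
one clinic per 1,000, one resource site per 20 with 1–3 services each.
Agents aged ≤ 18 attend a school; older agents up to 65 are assigned a
uniformly random workplace with probability 0.65 (the source data's
workplace assignment method is unpublished; this is flagged and
config-exposed).

**Schedules.** Templates are generated per stratum (age band × sex × race
× ethnicity × weekday/weekend), 2–40 per stratum (the source pools ranged
from 2 to ~1,500 schedules; a too-small pool makes rare activities, like
clinic visits, lumpy across strata). Each template has a 7–9 h sleep
block, work or school blocks on weekdays for the relevant ages,
health-maintenance activities at 0.06 per free hour, and a clinic-visit
hour in 1.5% of weekday templates (≈ 3–4 ambulatory visits per
person-year). Agents redraw a template uniformly from their matched set
every simulated day; matching falls back by dropping ethnicity, then race.
Seasonality is deliberately omitted.

**Sharing propensities.** Activities carry ordinal p-levels elicited in
the original study (sleeping → none; grocery shopping → medium; obtaining
medical care → high); the numeric rates are ours: none 0, low 0.05,
medium 0.15, high 0.30, config-exposed and swept in the propensity
experiment.

What the generators do *not* emulate: household co-residence structure
beyond a shared id, real street geography and travel time, schedule
seasonality and autocorrelation (each day is drawn independently), real
condition comorbidity structure, and digitally mediated sharing. Passing
tests therefore demonstrate the mechanisms and their emergent direction,
not calibrated real-world magnitudes.

## Experiments

*Dosing reach*: replicate runs count, at the end of week 3, agents
retaining referral-derived knowledge who were clinically dosed versus
reached by social exchange alone (disjoint sets by construction; both the
retaining-clinical and ever-clinical denominators are reported, since the
source description is ambiguous). *Delivery mode*: the same measurement
across physician/nurse/clerk delivery, with a descriptive Kruskal-Wallis
rank test. *Propensity sweep*: scaled p-rates with matched seeds, measured
by week-3 exchange-network degree distributions. Networks are directed
multigraphs (one edge per event); a simple-graph collapse is an export
option.

At the default desk scale (10,000 agents, 28 days, 5 replicates — chosen
so a full experiment runs on a laptop; the original study simulated
802,191 agents on an HPC cluster) the social-only/clinical ratio comes out
around 3, reproducing the direction (social ≫ clinical) though not the
absolute reach counts of the full-scale calibrated model, which depend on
the real population, schedule and resource-inventory data.

## Numerical and implementation notes

- All run-time randomness comes from one seeded `numpy.random.Generator`
  consuming uniform doubles in a documented canonical order (see
  `crxsim.engine`); discrete choices are `floor(u·k)` and
  without-replacement samples use a partial Fisher–Yates. This makes the
  optimized engine's event log reproducible draw-for-draw by a naive
  straight-line implementation, which the test suite asserts.
- Identical (world, pool, config, seed) gives byte-identical logs.
- Exchange fire-tests are drawn receiver-major per place, then giver
  sampling only for firing receivers — statistically identical to
  sample-then-test, but allows vectorizing the common no-fire case.
- Argmax/argmin tie-breaks (sharing, eviction, decisions, nearest queries)
  always resolve by resource/place id, never by dict order.
- Under geometric decay all entries at a store shrink by the same hourly
  factor, so β orderings are time-invariant; the store exploits this to
  keep an O(1) top-entry cache. The location policy vocabulary adds
  `clinic` for visit-trigger activities.
- Degenerate inputs: empty worlds refuse to simulate; empty resource
  tables seed empty stores; agents without a workplace fall back to home
  (counted in run metadata); empty exchange groups and unknown service
  types yield empty results rather than errors.

## Known limitations

Calibration to empirical visit data is out of scope, so absolute reach
counts are not comparable to the full-scale study; the contact cap m
truncates full mixing in places with more than ~11 co-located agents;
negative information and misinformation dynamics are not modeled; agent
attributes (including activation) are static; and the expert-elicited
activity→service mapping is replaced by a compact editable stand-in
catalog.
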