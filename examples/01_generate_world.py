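"""Generate a synthetic world and inspect its demographic marginals.

The generator emulates a majority-female, predominantly Black urban
community: agents aged 16-94 (mean ~44), anchored to households on a
16 km x 16 km planar frame, with workplaces, schools, clinics and
service-providing resource sites scattered across the box.
"""

import crxsim as cx

world = cx.generate_world(cx.DemographicConfig(n_agents=20_000), seed=1)

a = world.agents
print(f"agents:            {len(a):,}")
print(f"fraction female:   {(a['sex'] == 'female').mean():.3f}")
print(f"mean age (years):  {a['age'].mean():.1f}  (range {a['age'].min()}-{a['age'].max()})")
print(f"fraction Black:    {(a['race'] == 'black').mean():.3f}")
print(f"places:            {len(world.places):,} "
      f"({(world.places['kind'] == 'resource_site').sum()} resource sites)")
print(f"resources:         {len(world.resources):,} "
      f"across {world.resources['service_type'].nunique()} service types")

# The marginals above should track the configured targets (56% female,
# mean age ~44); each resource is one service at one geolocated place.
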