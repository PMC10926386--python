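"""One untreated season: the seasonal envelope of the simulated population.

Generates a synthetic upper-Midwest temperature year, runs one control
season, and prints the adult census at a few calendar dates. The pattern to
look for: a spring decline from the overwintered stock, summer growth to a
peak on the order of 10^4 adults (in late June or, in cooler weather years,
not until September), and a late-season wind-down once egg laying stops and
October turns cold.
"""

from egisim import LifecycleParams, TemperatureModelParams, run_season
from egisim.synthetic import generate_temperature_series

seed = 1
temps = generate_temperature_series(TemperatureModelParams(seed=seed))
result = run_season(LifecycleParams(), temps, seed=seed)

census = result.census
adult_cols = [c for c in census.columns
              if c.startswith("adult_") and c != "adult_females"]
adults = census[adult_cols].sum(axis=1)

print("date        temp_C  adults  adult_females")
for t in (0, 31, 61, 92, 116, 140, 167, 198, 229, 244):
    print(f"{census['date'][t]}  {temps.temp(t):6.1f} {adults[t]:7d} "
          f"{census['adult_females'][t]:7d}")

peak_t = int(adults.idxmax())
print(f"\nseasonal peak: {adults.max()} adults on {census['date'][peak_t]}")
print(f"cumulative adult-female count (female-days): "
      f"{result.cumulative_adult_females}")
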