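"""Generate a synthetic city and inspect its exposure structure.

Builds the default city — a jittered 12 x 12 street grid with correlated
AQI / noise / GVI surfaces, 20 docking stations and 50,000 gravity-model
trips — and prints basic structure plus edge-level exposure correlations.
"""

import numpy as np
from scipy import stats

from velopath import CityConfig, generate_city

cfg = CityConfig(seed=42)
net, stations, trips = generate_city(cfg)

print(f"nodes: {len(net)}   edges: {net.n_edges}")
print(f"stations: {len(stations)}   trips: {trips.total_trips}")

aqi = np.array([e.aqi for e in net.edges.values()])
noise = np.array([e.noise_db for e in net.edges.values()])
gvi = np.array([e.gvi for e in net.edges.values()])
print(f"mean AQI {aqi.mean():.2f}  mean noise {noise.mean():.1f} dB  "
      f"mean GVI {gvi.mean():.2f}")
print(f"edge-level r(AQI, noise) = {stats.pearsonr(aqi, noise)[0]:+.2f}  "
      f"(configured +0.70: pollution and noise co-occur)")
print(f"edge-level r(GVI, noise) = {stats.pearsonr(gvi, noise)[0]:+.2f}  "
      f"(configured -0.40: greener streets are quieter)")
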