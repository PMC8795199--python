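"""Risk-surface analysis of spatial sampling bias.

Two equally sized site clusters, one dated ten times as intensively:
the ratio of the dates-weighted kernel density to the site density is
above 1 over the heavy cluster (over-sampling) and below 1 over the light
one (under-sampling). Ratio 1 means dates proportional to sites.
"""

import numpy as np

import c14scrub as c

points, weights = c.generate_clustered_sites(
    k=2, sites_per_cluster=60, weights=[1.0, 10.0], seed=7)

grid = c.GridSpec(60, 30, (-2.0, 7.0, -2.0, 2.0))
bandwidth = (0.5, 0.5)
site_density = c.kde2d(points, bandwidth=bandwidth, grid=grid)
date_density = c.kde2d(points, weights=weights, bandwidth=bandwidth, grid=grid)
risk = c.risk_surface(date_density, site_density)

heavy = float(np.nanmean(risk.ratio[:, site_density.x > 3.5]))
light = float(np.nanmean(risk.ratio[:, site_density.x < 1.5]))
print(f"bandwidth {bandwidth} deg, epsilon {risk.epsilon:.4g}")
print(f"mean risk ratio over heavy cluster: {heavy:.2f}  (> 1: over-sampled)")
print(f"mean risk ratio over light cluster: {light:.2f}  (< 1: under-sampled)")
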