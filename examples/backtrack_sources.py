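"""Backtrack source waters from release stations through a synthetic gyre.

Releases 100-particle ensembles at three stations in an analytic gyre
circulation, integrates them backward for 60 days with 2% windage off and
the default eddy diffusivity of 4000 m^2/s, and prints where each ensemble
centroid ends up — the inferred source-water location.
"""

import numpy as np

from gulfweed import (
    BacktrackConfig,
    FieldGenConfig,
    backtrack_ensemble,
    ensemble_centroid,
    gen_field,
    gen_stations,
)

currents, _ = gen_field(FieldGenConfig(kind="gyre", amplitude=0.3))
stations = gen_stations(3, (-65.0, -55.0, 15.0, 25.0), seed=7, release_time=0.0)

config = BacktrackConfig(diffusivity=4000.0, windage=0.0, dt=6 * 3600.0,
                         duration=60 * 86400.0, n_particles=100,
                         direction="backward", seed=7)
for ens in backtrack_ensemble(stations, currents, None, config):
    _, clon, clat, n_active = ensemble_centroid(ens)
    spread = np.hypot(ens.lon[:, -1] - clon[-1], ens.lat[:, -1] - clat[-1]).std()
    print(f"station {ens.station_id}: released ({ens.release_lon:+.2f}, "
          f"{ens.release_lat:+.2f}) -> 60-day source centroid "
          f"({clon[-1]:+.2f}, {clat[-1]:+.2f}), {n_active[-1]} active, "
          f"ensemble spread {spread:.2f} deg")
print("The centroid is the best single guess at the source water; the "
      "spread reflects 60 days of eddy diffusion.")
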