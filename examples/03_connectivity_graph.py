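"""Band-limited connectivity and graph metrics on synthetic EEG.

Computes delta-band wPLI and dPLI across channels of a synthetic
recording, thresholds the wPLI matrix into a binary graph keeping the top
20% of edges, and prints its network summary.  The shared delta chain
drives all channels at zero lag, so wPLI (zero-lag insensitive) stays low
while dPLI sits near 0.5 everywhere.
"""

import numpy as np

from clasdelta import (SynthConfig, dpli, graph_metrics, make_delta_eeg,
                       threshold_adjacency, wpli)
from clasdelta.connectivity import CONNECTIVITY_BANDS

rec = make_delta_eeg(SynthConfig(n_channels=8, duration_s=120.0, seed=2))
band = CONNECTIVITY_BANDS["delta"]

w = wpli(rec.data[None], band, rec.fs)
d = dpli(rec.data[None], band, rec.fs)
off = ~np.eye(rec.n_channels, dtype=bool)
print(f"delta-band wPLI: mean {w.values[off].mean():.3f} "
      f"(zero-lag common drive is suppressed)")
print(f"delta-band dPLI: mean {d.values[off].mean():.3f} "
      "(no consistent lead/lag)")

g = threshold_adjacency(w, keep_proportion=0.2)
gm = graph_metrics(g, n_null=20, seed=0)
print(f"thresholded graph: {g.number_of_edges()} edges, "
      f"efficiency {gm.global_efficiency:.3f}, "
      f"clustering {gm.clustering:.3f}, Q {gm.modularity_q:.3f}, "
      f"sigma {gm.small_worldness_sigma:.2f}")
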