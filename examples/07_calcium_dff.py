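"""Quantify pharmacological suppression of retinal ganglion cell activity
with percentile-baseline ΔF/F.

Synthetic GCaMP traces from hyperactive cells pass through a suppression
protocol (before / drug / recovery).  ΔF/F = 100·(F - F0)/F0 with F0 the
10th percentile of the raw trace during the treatment epoch.
"""

import numpy as np

from retao import CalciumProtocol, dff, make_calcium_series

protocol = CalciumProtocol(depth=0.9, recovery=0.5)
series = make_calcium_series(n_cells=8, protocol=protocol, seed=2)
sl = protocol.epoch_slices(series.f.shape[1])

means = {k: [] for k in ("before", "during", "after")}
for trace in series.f:
    d = dff(trace, percentile=10.0, window=sl["during"])
    for k in means:
        means[k].append(d.dff[sl[k]].mean())

for k, v in means.items():
    print(f"mean dF/F {k:>6s}: {np.mean(v):7.1f} %")
# Suppression collapses dF/F toward its treatment-epoch baseline; partial
# recovery brings it back part way toward the hyperactive pre-drug level.
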