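"""FAIR perfusion mapping from paired global / slice-selective T1 maps.

Perfusion shortens the apparent T1 after a slice-selective inversion
(inflowing blood carries non-inverted spins).  The perfusion map converts
the ratio of the two T1 maps to ml/min/100 g with the blood-tissue
partition coefficient lambda = 0.95 ml/g and blood T1 = 1900 ms.
"""

from hepaflow import make_phantom, simulate_fair_series
from hepaflow.perfusion import ROISet, perfusion_map, roi_mean
from hepaflow.t1fit import fit_t1_map

phantom = make_phantom(matrix=64, perfusion_ml_min_100g=316.0)
maps = {mode: fit_t1_map(simulate_fair_series(phantom, mode, noise_sd=10.0,
                                              seed=1),
                         mask=phantom.liver_mask)
        for mode in ("global", "slice_selective")}

pmap = perfusion_map(maps["global"], maps["slice_selective"])
rois = ROISet.for_phantom(phantom)

print(f"T1 (global)          : {roi_mean(maps['global'], rois):7.1f} ms")
print(f"T1 (slice-selective) : {roi_mean(maps['slice_selective'], rois):7.1f} ms")
print(f"perfusion measured   : {roi_mean(pmap, rois):7.1f} ml/min/100 g")
print(f"perfusion true       : {phantom.mean_perfusion_true:7.1f} ml/min/100 g")
# The slice-selective T1 sits ~120 ms below the global T1; that gap IS the
# perfusion signal. Values are means over three circular parenchymal ROIs.
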