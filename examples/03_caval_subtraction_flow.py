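"""Caval-subtraction TLBF from phase-contrast cines of the two IVC stations.

Velocity is encoded in phase (v = venc * phase / pi), per-frame flow is the
sum of voxel area x velocity over the vessel ROI, the cycle average comes
from periodic trapezoidal integration, and total liver blood flow is the
supra-hepatic minus infra-hepatic caval flow normalised to liver weight.
"""

from hepaflow import make_phantom, simulate_pc_cine
from hepaflow.pcflow import caval_subtraction_from_cines

phantom = make_phantom(liver_weight_g=14.0, perfusion_ml_min_100g=316.0)
infra = simulate_pc_cine(phantom, "infra_IVC", noise_sd_rad=0.02, seed=1)
supra = simulate_pc_cine(phantom, "supra_IVC", noise_sd_rad=0.02, seed=2)
print(f"cines: {infra.n_phases} cardiac phases, venc {infra.venc_cm_s:.0f} "
      f"(infra) / {supra.venc_cm_s:.0f} (supra) cm/s")

result = caval_subtraction_from_cines(infra, supra, phantom.liver_weight_g)
print(f"infra-hepatic IVC flow : {result.infra_flow_ml_min:7.1f} ml/min")
print(f"supra-hepatic IVC flow : {result.supra_flow_ml_min:7.1f} ml/min")
print(f"TLBF measured          : {result.tlbf_ml_min_100g:7.1f} ml/min/100 g")
print(f"TLBF ground truth      : {phantom.tlbf_ground_truth():7.1f} ml/min/100 g")
print(f"partial-volume rule ok : {result.partial_volume_ok} "
      f"(0.208 mm voxels vs 3.5 mm vessel)")
# The supra-minus-infra difference equals the hepatic inflow the phantom was
# built with, up to vessel-disc discretisation (< 5%) and phase noise.
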