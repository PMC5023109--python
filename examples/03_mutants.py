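"""Mutant scenarios: whole-disc parameter changes and tracked clones.

Reduced hh production slows and eventually halts the furrow while the
anterior keeps proliferating (overgrowth); removing the Hh influx entirely
prevents furrow initiation; a clone with increased hth production locally
retards the furrow.
"""

import numpy as np

from eyedisc import ModelParameters, EyeDiscSimulation, Perturbation
from eyedisc.simulator import track_mf

params = ModelParameters(target_edge=6.0)

wt = EyeDiscSimulation(params).run(30.0)
hh = EyeDiscSimulation(params, perturbations=[Perturbation("p_Hh", 0.5)]).run(30.0)
no_influx = EyeDiscSimulation(params, perturbations=[Perturbation("eta", 1e-12)]).run(20.0)

i = -1
print(f"wild type at 30 h : PL = {wt.PL_um[i]:6.1f} um, area = {wt.area_total[i]:8.0f} um^2")
print(f"hh hypomorph      : PL(max) = {hh.PL_um.max():4.1f} um, area = {hh.area_total[i]:8.0f} um^2"
      "   (furrow halts early; the disc overgrows)")
print(f"no Hh influx      : PL = {no_influx.PL_um[-1]:6.1f} um  (no furrow ever forms)")

# hth-overexpressing clone ahead of the furrow: local furrow retardation
clone = Perturbation("p_Hth", 3.0, region={"center": (30.0, 0.0), "radius": 15.0},
                     t_on_h=8.0)
sim = EyeDiscSimulation(params, perturbations=[clone])
res = sim.run(30.0)
pl_mid = track_mf(sim.state, sim.mesh, params, y_offset=0.0)
pl_flank = track_mf(sim.state, sim.mesh, params, y_offset=25.0)
print(f"hth clone on the midline: PL(midline) = {pl_mid:.1f} um vs "
      f"PL(flank) = {pl_flank:.1f} um  (the furrow lags inside the clone)")
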