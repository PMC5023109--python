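"""Wild-type simulation: linear furrow movement and growth termination.

Runs the growing eye disc model at a reduced size (coarse mesh, 45 h) and
prints the furrow speed, the linearity of its trajectory and the growth
summary. The furrow speed in the full-length production configuration is
~3.1-3.4 um/h; the trajectory is approximately linear (RMSE a few percent
of the distance traveled) and total area approaches a plateau as the
anterior progenitor pool is consumed.
"""

import numpy as np

from eyedisc import ModelParameters, EyeDiscSimulation
from eyedisc.analysis import default_fit_window, fit_mf_kinetics, growth_termination_time

params = ModelParameters()  # production resolution, shortened horizon
sim = EyeDiscSimulation(params)
result = sim.run(45.0, output_every_h=1.0)

kin = fit_mf_kinetics(result.times_h, result.PL_um, default_fit_window(result))
traversed = result.PL_um.max() - result.PL_um.min()

print(f"furrow initiation      : {result.events['mf_initiation_h']:.1f} h")
print(f"furrow speed (fit)     : {kin.speed:.2f} um/h on window {kin.window}")
print(f"nonlinearity (RMSE)    : {kin.nonlinearity:.2f} um "
      f"({100 * kin.nonlinearity / traversed:.1f}% of traversed)")
print(f"total area 0 h -> end  : {result.area_total[0]:.0f} -> "
      f"{result.area_total[-1]:.0f} um^2")
term = growth_termination_time(result)
print(f"growth termination     : {term if term else 'not reached'} h "
      "(relative area growth < 1%/h)")
i = np.argmin(np.abs(result.times_h - 30.0))
print(f"areas at 30 h          : anterior {result.area_anterior[i]:.0f}, "
      f"furrow {result.area_mf[i]:.0f}, posterior {result.area_posterior[i]:.0f} um^2")
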