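p_Hh: 6.97e-05
p_Dpp: 6.97e-05
p_pMad: 6.97e-05
p_Eya: 6.97e-05
p_Hth: 6.97e-05
delta_Hh: 0.00067
delta_Dpp: 0.00025
delta_pMad: 0.00018
delta_Eya: 6.97e-05
delta_Hth: 6.97e-05
D_Hh: 0.033
D_Dpp: 0.1
D_intra: 0.00025
K_Hh: 0.01
n_Hh: 2.0
K_Dpp: 0.0003
n_Dpp: 2.0
K_pMad: 0.2
n_pMad: 2.0
hill_overrides: {}
theta_Hth: 0.35
theta_Hh: 0.04
eta: 0.0004
margin_fraction: 0.2
t_on: 36000.0
t_off: 37800.0
k0: 2.8e-05
delta_PL: 0.0107
mu: 1.0
rho: 1.0
a: 55.0
b: 42.0
eps_H_rel: 0.01
dt_max: 250.0
target_edge: 5.0
remesh_quality: 0.3
theta_scheme: 0.5
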