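[circuit]
topology = "TOGGLE"
alpha_tx = 10.0
K_rep = 1.0
n_rep = 2.0
k_tl = 1.0
rbs_lacI = 0.5
rbs_tetR = 0.5
rbs_gfp = 0.5
rbs_mcherry = 0.5
rbs_cI = 0.5
delta_m = 1.0
delta_p = 0.3
K_lac = 10.0
K_ara = 10.0
eta_ind = 2.0
delta_ind = 0.05
K_ahl = 10.0
n_ahl = 2.0
delta_ahl = 0.001
K_cI = 1.0
n_cI = 2.0
delta_cI = 0.3
lux_gain = 6.0

[noise]
sigma_tx = 0.0
sigma_tl = 0.0
enabled = false

[efm]
theta_on = 2.0
rho_dom = 2.0
theta_both = 40.0

[robot]
v_base = 0.5
r_dock = 0.2
r_prox = 1.5
r_hyst = 0.5
A_pulse = 50.0

[arena]
half_width = 10.0
spawn_mode = "vertex_cycle"
min_separation = 2.0
q_dose = 25.0
T_dose = 2.0
depot_budget = 4

[sweep]
grid_points = 10
rbs_min = 0.05
rbs_max = 1.0
walk_points = 24
walk_min = 0.001
walk_max = 0.9

[engine]
dt = 0.01
t_max = 500.0
seed = 0
ara_init = 50.0
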