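# Example run configuration (flat key = value text; '#' starts a comment).
# Unset keys take the hematopoietic defaults.  Pass to the CLI with
#   dediffsim run --config examples/config_example.txt --seed 1 --out out/

model = variable_N            # constant_N | variable_N

# --- stem compartment ---
n_stem = 100                  # N, active stem cells (constant-size model)
stem_cycle_weeks = 20         # tau, weeks between divisions of one cell
stem_mutation_rate = 0.005    # u, per replication
selection_s = 0               # stem-pool advantage of two-mutation cells
dediff_weight = 0             # d in [0, 1] (constant-size model)
dediff_scope = two_mutation_only
carrying_capacity = 100       # K (variable-size model)
asym_prob = 0.5               # q1, probability of asymmetric division
reversion_strength = 3        # z, larger -> smaller size fluctuations
dediff_rate = 0.001           # eta, per two-mutation progenitor per week

# --- progenitor compartment ---
max_age_weeks = 20            # A, maximum progenitor lifespan
age_step_weeks = 0.1          # age grid spacing = transport time step
birth_max = 1.5               # maximal proliferation rate of class 0
progenitor_advantage = 0.13333333333333333   # b_k = birth_max (1 + s k)
death_max = 1.0               # maximal death/removal rate
birth_switch_age = 10         # a_b, proliferation half-off age
death_switch_age = 0          # a_d, apoptosis half-on age (0 = always on)
birth_steepness = 2           # m_b (0 = uniform rate)
death_steepness = 2           # m_d
progenitor_mutation_rate = none   # v per week; 'none' = same as u
competition_mode = none       # none | logistic | local | global
progenitor_capacity = 10000

# --- experiment ---
t_max_weeks = 5000
replicates = 3
base_seed = 1
record_stride = 10
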