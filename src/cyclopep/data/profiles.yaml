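# Size-class profiles: annealing schedule, recording criteria, GA settings.
# The 15/20/24 GA profiles carry the published population schedules
# (constant 500; 750 - 5i; 1000 - 10i over 50 generations); "toy" and
# "predict-small" are desk-scale.

"7":
  n: 7
  sa:
    steps: 5000
    k_start: 40.0
    k_end: 0.5
    layers:
      - {name: rama,   threshold: 14.0, T0: 5.0,  Tf: 0.5}
      - {name: rep,    threshold: 7.0,  T0: 20.0, Tf: 1.0}
      - {name: cyclic, threshold: 0.1,  T0: 10.0, Tf: 0.005}
      - {name: hbond,  threshold: -2.0, T0: 2.0,  Tf: 0.3}
      - {name: misc,   threshold: 0.0,  T0: 2.0,  Tf: 0.3}
  criteria:
    max_cyclic_error: 0.01
    max_rep_energy_per_res: 0.5

"15":
  n: 15
  sa:
    steps: 5000
    k_start: 40.0
    k_end: 0.5
    layers:
      - {name: rama,   threshold: 30.0, T0: 5.0,  Tf: 0.5}
      - {name: rep,    threshold: 15.0, T0: 20.0, Tf: 1.0}
      - {name: cyclic, threshold: 0.1,  T0: 10.0, Tf: 0.005}
      - {name: hbond,  threshold: -2.0, T0: 2.0,  Tf: 0.3}
  criteria:
    max_cyclic_error: 0.01
    max_rep_energy_per_res: 0.5
  ga:
    generations: 50
    population_profile: "15"
    cluster_rmsd_cutoff: 1.5
    init_sa_runs: 100

"20":
  n: 20
  sa:
    steps: 5000
    k_start: 40.0
    k_end: 0.5
    layers:
      - {name: rama,   threshold: 40.0, T0: 5.0,  Tf: 0.5}
      - {name: rep,    threshold: 20.0, T0: 20.0, Tf: 1.0}
      - {name: cyclic, threshold: 0.1,  T0: 10.0, Tf: 0.005}
      - {name: hbond,  threshold: -2.0, T0: 2.0,  Tf: 0.3}
  criteria:
    max_cyclic_error: 0.01
    max_rep_energy_per_res: 0.5
  ga:
    generations: 50
    population_profile: "20"
    cluster_rmsd_cutoff: 1.5
    init_sa_runs: 100

"24":
  n: 24
  sa:
    steps: 5000
    k_start: 40.0
    k_end: 0.5
    layers:
      - {name: rama,   threshold: 48.0, T0: 5.0,  Tf: 0.5}
      - {name: rep,    threshold: 24.0, T0: 20.0, Tf: 1.0}
      - {name: cyclic, threshold: 0.1,  T0: 10.0, Tf: 0.005}
      - {name: hbond,  threshold: -2.0, T0: 2.0,  Tf: 0.3}
  criteria:
    max_cyclic_error: 0.01
    max_rep_energy_per_res: 0.5
  ga:
    generations: 50
    population_profile: "24"
    cluster_rmsd_cutoff: 1.5
    init_sa_runs: 100

# desk-scale GA profile used by the tests and toy fixtures
toy:
  n: 6
  sa:
    steps: 1500
    k_start: 40.0
    k_end: 0.5
  criteria:
    max_cyclic_error: 0.01
    max_rep_energy_per_res: 1.0
    min_strong_hbonds: 0
  ga:
    generations: 15
    n_ga: 50
    cluster_rmsd_cutoff: 0.5
    offspring_factor: 1.5
    mutation_radius: 45.0
    init_sa_runs: 30
    sa_steps: 2000
    relax_maxfev: 600

# sequence-only prediction at desk scale
predict-small:
  n: 7
  sa:
    steps: 3000
  criteria:
    max_cyclic_error: 0.01
    max_rep_energy_per_res: 0.5
  ga:
    generations: 10
    n_ga: 30
    cluster_rmsd_cutoff: 1.5
    init_sa_runs: 30
    sa_steps: 2000
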