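# Study profile for the numbered analysis scripts.
#
# 100 nodes keeps a full end-to-end run (simulate -> clean -> connectomes ->
# permutation regression) in the low minutes on one CPU while preserving the
# design: 40 sessions over 30 days (20 AM / 20 PM), serum analytes on 30
# sessions, B = 2000 permutations, and five ground-truth hormone-coupled
# edges for the recovery check. For a full-scale 415-node run, set
# study.n_nodes to 415 and expect a correspondingly longer edgewise stage.
study:
  n_nodes: 100
  n_sessions: 40
  n_days: 30
  frames_per_session: 1250
  n_serum_sessions: 30
  coupled_edges:
    - {i: 0, j: 1, beta: 0.15}
    - {i: 2, j: 3, beta: -0.15}
    - {i: 4, j: 5, beta: 0.15}
    - {i: 6, j: 7, beta: -0.15}
    - {i: 8, j: 9, beta: 0.15}
hormones:
  - testosterone_saliva
  - estradiol
  - cortisol_saliva
# BH resolution rule: the permutation floor 1/B must sit below the BH
# cutoff ~ k*q/m (k true edges among m). With m = 4,950 edges, q = 0.05 and
# ~5 couplable edges that requires B >= m/(k*q) ~ 20,000.
n_permutations: 20000
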