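# Full experiment on a synthetic 28-element web (for the shelf model,
# use `web: {fixture: data/wss28}` with scenario elements
# [Phytoplankton, Small pelagics, Seals, Fishery]).
web:
  synthetic:
    n_groups: 28
    n_trophic_levels: 4
    connectance: 0.5
    seed: 7
scenario_elements: [Producer1, Consumer1_L2, Consumer22_L4]
directions: [1, -1]
n_sims: 200          # 1000 reproduces the published setup but is slow
seed: 1
run_dynamic: true
out_dir: scratch/demo-run
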