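# Demo run: F9 intercross over the 3.1 Mb focal region with three planted
# shared Q sub-haplotype intervals, plus the multi-breed panel.
# Run:  ailmap run-all --config examples/demo.yaml
seed: 1
out_dir: ailmap_demo

sim:
  generation_sizes: [100, 100, 100, 100, 100, 100, 100, 100, 300]
  q_intervals:
    - [168700000, 168760000]
    - [169100000, 169200000]
    - [169500000, 169560000]

popgen:
  xpehh_core_step: 25
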