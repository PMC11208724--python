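# Example configuration for `olbac simulate`.
# The planted rule: an S at the marked site is worth +2 log units over an O,
# so every paired scaffold forms a true >=10-fold MMP-cliff.
fixture.n_scaffolds: 135
fixture.site_elements: [O, S]
fixture.effects: {O: 0.0, S: 2.0}
fixture.base_range: [5.0, 7.0]     # scaffold base pActivity, uniform
fixture.noise_sigma: 0.2           # assay noise, log10 units
fixture.singleton_fraction: 0.519  # share of scaffolds emitting one variant
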