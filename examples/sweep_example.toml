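# Example: oxygen-consumption response map (Model II).
# Run with:  gliovasc sweep --config examples/sweep_example.toml --outdir map
variant = "II"

[sweep]
D_values = [2.73e-3, 1.66e-2, 4.49e-2, 2.73e-1]
b_values = [2.73e-4, 1.66e-3, 4.49e-3, 2.73e-2]
varied_name = "h2"
varied_values = [5.73e-4, 5.73e-2]
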