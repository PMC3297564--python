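"""End-to-end transient-complex mapping on the synthetic lock-and-key complex.

Builds the toy 1:2 complex with the low-phi obstruction, samples clash-free
rigid-body placements of the mobile receptor, locates the transient-complex
ensemble at the midpoint of the sigma_chi vs N_c transition, and summarizes
the activation-angle asymmetry.
"""

import json

import tcomplex as tc

config = tc.RunConfig(
    outdir="toy_run",
    toy={"obstruction": True},
    sampling={"target_clashfree": 30_000},   # desk scale; production uses 8e6
    profile_min_count=30,
    seed=11,
)
report = tc.run_pipeline(config)

print(json.dumps({k: report[k] for k in ("r_cut", "interface", "transition", "angles")},
                 indent=2, default=float))
print()
print("N_c(native) counts the interaction-locus contacts in the crystal-like "
      "placement; N_c* is the contact count at the rotational-freedom "
      "transition midpoint, and the configurations at exactly N_c* form the "
      "transient-complex ensemble.")
print("frac_phi_above_native > 0.5 shows the obstruction biases the transient "
      "ensemble toward scissor angles above the native value, so reaching the "
      "native complex requires a phi-decreasing (scissor-closing) rotation.")
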