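# tcomplex

Transient-complex mapping and activation geometry for 1:2 cytokine-receptor
assemblies.

## The problem

Class I cytokines (growth hormone, erythropoietin, prolactin) activate their
receptors by recruiting a second receptor ectodomain (R2) onto a preformed
1:1 cytokine-receptor complex. The crystal structures show only the end
state; the signal-generating event is the *orientational rearrangement* of
the two receptors during the last step of binding. That rearrangement can be
read off the **transient complex** — the late on-pathway intermediate with
near-native separation and orientation but none of the short-range native
contacts — because the transient complex sits at the rim of the native
energy well and is shaped almost entirely by interface geometry.

`tcomplex` maps this intermediate for any two-subunit complex and quantifies
the two rotations that carry the dimer from transient to native geometry:
the **self-rotation** angle γ (between the projections of the N1 and N2
subdomain long axes on the membrane plane) and the **scissor** angle φ
(signed, between the C1 and C2 long-axis projections in the vertical plane).
It also implements the helical-wheel arithmetic linking transmembrane-helix
(TMH) indels to the reorientation of the receptor-associated JAK2 kinases.

## The method

With the 1:1 complex fixed in space, rigid-body placements of R2 are drawn
uniformly in six coordinates: the displacement **r** between the two
binding-surface centroids (|**r**| ≤ r_cut, uniform in the ball), a
body-fixed unit vector **e** (the interface least-squares-plane normal;
uniform on the sphere) and a spin angle χ about **e** (uniform, χ = 0 at
native). Configurations with any cross-subunit heavy-atom pair closer than
the clash distance (2.8 Å default) are rejected exhaustively; r_cut is the
smallest 1 Å grid value whose clash-free fraction reaches 1e-4.

Each clash-free configuration gets a surrogate interaction energy N_c: the
number of contacts, native or nonnative, formed by a greedily thinned set of
*interaction-locus* atoms (native cross-interface pairs < 5 Å, scanned in
ascending distance, a pair eliminated if within 3.5 Å of a retained pair on
either side). A native pair counts while its distance is at most its native
distance + 3.5 Å; any other locus pair counts when closer than the sum of
the two contact radii (half the native distance each) + 2.5 Å.

Binning the spread of χ per integer N_c yields a sharp rotational-freedom
transition, fitted with the two-state form used for denaturation data,

σ_χ(N_c) = σ_n + (σ_u − σ_n) / (1 + exp((N_c − N_c\*)/w)),

whose midpoint N_c\* defines the transient-complex ensemble: all sampled
configurations with N_c exactly equal to round(N_c\*). Their (γ, φ)
distributions, compared with the native values, expose the activation
rotations and their steric asymmetries.

## Worked example

A desk-scale end-to-end run on the built-in synthetic lock-and-key complex
(a rigid toy 1:2 assembly with an aperiodic contact-stud interface, known
native angles γ = 160°, φ = 0°, and an obstruction wall on the low-φ side):

```bash
python examples/toy_pipeline.py
```

prints (30 000 clash-free configurations, seed 11):

```
{
  "r_cut": 8.0,
  "interface": {"pair_count": 23, "retained_native_pairs": 11, "nc_native": 11},
  "transition": {"sigma_n": 0.0, "sigma_u": 109.0, "nc_star": 6.85,
                 "nc_star_rounded": 7, "width": 1.34, "ensemble_size": 145, ...},
  "angles": {"native_gamma": 159.73, "native_phi": 0.06,
             "gamma_median": 161.86, "phi_median": 7.87,
             "frac_gamma_above_native": 0.55, "frac_phi_above_native": 0.67, ...}
}
```

Reading this: the native interface thins to 11 interaction loci forming
N_c = 11 contacts; rotational freedom collapses from σ_χ ≈ 109° (unbound)
to ≈ 0° (native well) with the two-state midpoint at N_c\* ≈ 6.9, so the
145 configurations with N_c = 7 form the transient ensemble. Two thirds of
that ensemble sits at φ above the native value — the obstruction blocks the
low-φ side — so reaching the native complex requires a φ-decreasing,
scissor-closing rotation, exactly the activation motion the analysis is
designed to detect.

Other examples: `wheel_table.py` (TMH indel → JAK2 orientation; three
deletions or four insertions restore facing), `interface_loci.py`,
`sampling_laws.py`, `transition_fit.py`, and two network-dependent scripts,
`native_angles_pdb.py` and `paper_scale_gh.py`, that fetch the five
deposited 1:2 complexes (3HHR, 1EER, 3NPZ, 1EBP, 1EBA) and reproduce the
native angles and the production-scale GH run.

A thin CLI wraps the same library calls:

```bash
tcomplex run --seed 11 --out toy_run          # default toy pipeline
tcomplex wheel                                # helical-wheel table
tcomplex prepare 3HHR.pdb --config gh.yaml --out gh_norm.pdb
```

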