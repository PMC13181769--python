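# sprgamma

Quantify interface-induced solute concentration enhancement in aqueous
solutions from surface plasmon resonance (SPR) angle scans and from
molecular-dynamics-style density profiles.

Solutions of small molecules such as glycine do not stay homogeneous up
to a solid wall: van der Waals interactions can concentrate solute into
a nanometre-scale layer at the interface. The package implements the
two complementary analyses used to detect and quantify this effect:

1. **SPR optics.** In the Kretschmann configuration a reflectivity
   angle scan shows two characteristic features: the total-internal-
   reflection edge θ_TIR, which depends only on the bulk refractive
   index of the liquid, and the plasmon coupling minimum θ_SPR, which
   is additionally sensitive to any nanoscale layer at the metal-liquid
   interface. Pairing a solution with an index-matched solvent (equal
   θ_TIR) isolates the interfacial layer: any θ_SPR difference must
   come from it. The package forward-models p-polarized multilayer
   reflectivity with the transfer-matrix method, extracts both angles,
   and inverts scans in two stages — ε_bulk from the edge via
   ε_bulk = ε_prism · sin²θ_TIR, then ε_interf of an assumed-thickness
   (default 1 nm) interfacial layer by least squares over the
   plasmon-minimum region.

2. **Composition chain.** Fitted permittivities map to glycine mass
   fraction x through the Clausius–Mossotti relation

       (ε − 1)/(ε + 2) = ρ(x) · [x·r_gly + (1 − x)·r_water],

   with ρ(x) interpolated from a packaged property table of aqueous
   glycine at 22 °C (extended above saturation toward the crystal
   density 1.607 g/cm³). The excess interfacial mass density is

       Γ = t · [ρ(x_interf)·x_interf − ρ(x_bulk)·x_bulk]   (ng/cm²),

   which is approximately invariant to the assumed thickness t because
   the optical fit trades (ε_interf − ε_bulk) against t.

3. **Density-profile analysis.** Species-resolved density profiles of
   a solution film against a wall (0.05 nm bins) are analyzed for film
   width (solvent density falling below 0.1 g/cm³), near-wall
   interfacial averages, and profile-based surface excess.

A synthetic-data module generates every input with known ground truth
(randomized sensor chips, noisy index-matched scan pairs, wall-enriched
film profiles), so the whole pipeline is testable end to end by
parameter recovery.

## Worked example

Generate a noisy synthetic index-matched pair on a randomized gold chip
(ground truth: ε_bulk = 1.8489, ε_interf = 2.1070, t = 1 nm) and invert
it:

```sh
$ sprgamma synth --outdir demo --seed 7
$ sprgamma fit demo/sample.csv --stack demo/stack.yaml \
      --partner demo/reference.csv --reference-eps 1.8489
{
  "eps_bulk": 1.8489,
  "eps_interf": 2.1071140584216432,
  ...
}
```

The fitted interfacial permittivity recovers the generating 2.1070 to
within the noise. Convert a fitted permittivity pair to an excess
interfacial mass density:

```sh
$ sprgamma gamma --eps-interf 2.0717 --eps-bulk 1.8489
{
  "gamma_ng_cm2": 47.08393439608285,
  "gamma_ng_nm2": 4.708393439608285e-13,
  "x_interf": 0.5063388546750185,
  "x_bulk": 0.14770454469665148,
  "excess_molecules_per_nm3": 3.777089123056035,
  "layer_thickness_nm": 1.0
}
```

Read: a 1 nm interfacial layer at ε = 2.0717 over a bulk at ε = 1.8489
implies a local glycine mass fraction of ~0.51 (far above the ~0.15 of
the bulk, and above saturation), an excess of ~47 ng of glycine per cm²
of surface, i.e. roughly 4 extra molecules in every interfacial nm³ —
to be compared with ~1.7 molecules/nm³ in the bulk solution and ~13 in
the glycine crystal.

Density profiles are analyzed the same way:

```sh
$ sprgamma synth --kind profile --film-width 12.95 --outdir demo-film
$ sprgamma profile-analyze demo-film/profile.txt
{
  "film_width_nm": 12.95...,
  "interfacial_average_g_cm3": {"solute": 1.0, ...}
}
```

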