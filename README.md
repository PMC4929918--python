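# nanoadhere

Multiscale Monte Carlo of functionalized-nanocarrier (NC) adhesion to a
fluctuating cell membrane, with downstream conversion of binding avidities
into organ-level tissue-targeting predictions.

## The scientific problem

Antibody-coated nanocarriers (for example ~100 nm particles carrying
anti-ICAM1) bind the endothelium through many simultaneous receptor–ligand
bonds. How strongly they bind — and therefore which organ accumulates them —
depends not only on receptor expression (*N*<sub>ant</sub>) and ligand count
(*N*<sub>ab</sub>) but on the *mechanics* of the target membrane: its bending
rigidity κ and excess area A<sub>ex</sub> = 100·(A − A<sub>p</sub>)/A.
`nanoadhere` implements the full chain needed to quantify this:

1. **Membrane**: a dynamically triangulated, periodic patch with discrete
   Helfrich energy
   H<sub>m</sub> = Σ<sub>v</sub> [κ/2 (c₁+c₂)² A<sub>v</sub> + σ A<sub>v</sub>],
   self-avoiding tethers, and link flips for fluidity.
2. **Molecules**: receptors as flexural rods
   (H<sub>f</sub> = κ<sub>f</sub>θ²/2) diffusing on the mesh; a rigid
   spherical carrier with radial ligand rods; receptor–ligand bonds via the
   Bell potential H<sub>b</sub> = H₀ + κ<sub>b</sub>(d − d\*)²/2 for
   d ≤ d\*.
3. **Sampling**: Metropolis MC with seven moves (vertex, link flip, NC
   translation/rotation, receptor diffusion, Rosenbluth receptor flexure,
   configurational-bias bond make/break), umbrella sampling along the
   order parameter ΔR = |**R**<sub>CM</sub> − **R**<sub>NC</sub>|, WHAM
   reconstruction and thermodynamic-integration anchoring of the potential
   of mean force W(ΔR).
4. **Avidity**: the association constant

   K<sub>a</sub> = [N<sub>ant</sub>!/((N<sub>ant</sub>−n<sub>b</sub>)! n<sub>b</sub>!)]
   · C(N<sub>ab</sub>, n<sub>b</sub>)
   · (ΔφΔθΔψ / 8π²)
   · (A<sub>R</sub><sup>b</sup>/A<sub>R</sub><sup>u</sup>)<sup>n<sub>b</sub></sup>
   · A<sub>N</sub><sup>b</sup>/(L<sub>z</sub>(L<sub>z</sub>−r\*))
   · ∫₀<sup>r\*</sup> e<sup>−βW(r)</sup> dr,

   assembled in log space from simulation observables, with
   K<sub>d</sub> = K<sub>a</sub>⁻¹ and log-linear interpolation of K<sub>a</sub>
   between simulated receptor densities.
5. **Targeting**: a steady-state pharmacokinetic partitioning model turning
   K<sub>EC</sub> (and optionally macrophage K<sub>M</sub>) plus the
   non-targeted coefficient K<sub>p</sub> into per-organ %id/g, reported as
   η = (%id/g)<sub>organ</sub>/(%id/g)<sub>lung</sub>, with Gaussian-bootstrap
   r² statistics and a null-model t-test.

Audience: biophysicists and drug-delivery modellers who want absolute
(zero-fit) binding avidities for carrier design, and a reproducible reference
implementation of the membrane-MC + WHAM + PK pipeline.

## Worked example

Fit the effective elastic constants of a thermalized membrane patch from its
height-fluctuation spectrum, ⟨|h<sub>q</sub>|²⟩ = k<sub>B</sub>T/(A<sub>p</sub>(κq⁴+σq²)):

```python
from nanoadhere.mesh import MembraneParams
from nanoadhere.spectrum import sample_membrane_spectrum, fit_helfrich

params = MembraneParams(kappa=20.0, sigma=0.0, L=240.0)   # kBT, kBT/nm^2, nm
spec, mesh, aex = sample_membrane_spectrum(params, n_steps=4_000_000,
                                           seed=3, grid_n=24)
fit = fit_helfrich(spec, a0=10.0)
print(f"kappa_eff = {fit.kappa_eff:.2f} +- {fit.kappa_err:.2f} kBT, "
      f"Aex = {aex:.2f}%")
```

```
kappa_eff = 19.49 +- 1.80 kBT, Aex = 1.24%
```

The input rigidity (20 k<sub>B</sub>T) is recovered within the fit error,
and the thermal excess area of a tense-free 240 nm patch comes out near 1%.
The same run with 6–12% of vertices pinned (the mean-field cytoskeleton)
raises the fitted tension σ_eff from ≈ −0.01 to ≈ 0.10–0.24 k<sub>B</sub>T/nm²
while shifting κ_eff — the renormalization that lets measured cell
mechanotypes be used directly in the Helfrich model.

A full adhesion run at the literature parameter set (κ = 160 k<sub>B</sub>T,
N<sub>ab</sub> = 162, 2000 receptors/μm², H₀ = −7.98×10⁻²⁰ J) yields a
unimodal multivalency distribution peaked at n<sub>b</sub> = 8; the flexible
large-excess-area membrane (κ = 20 k<sub>B</sub>T, buckled to
A<sub>ex</sub> ≈ 57%) peaks at n<sub>b</sub> = 10.

A command-line interface mirrors the library:

```bash
nanoadhere simulate --steps 200000 --seed 3 --out run1
nanoadhere spectrum --steps 1000000 --seed 3 --out spec1
nanoadhere pmf --steps-per-window 100000 --seed 7 --out pmf1
nanoadhere pk --contexts organs.tsv --out eta1
nanoadhere fixtures --kind icosphere --out fix1
```

Every subcommand writes a `manifest.json` recording the config snapshot,
seeds and output files.

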