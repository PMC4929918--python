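# Methods

This note documents the model, the numerical choices and their rationale,
what the synthetic inputs emulate, and the known limitations. All internal
units are nanometres and k_B T at the configured temperature (default
300 K); SI literature values are converted once at the configuration
boundary (H0 = −7.98×10⁻²⁰ J → βH0 ≈ −19.27; κ_b = 1 N/m ≈ 241.4
k_BT/nm²; κ_f = 7000 pN·nm ≈ 1690 k_BT/rad²).

## Membrane model

The membrane patch is a dynamically triangulated surface with periodic
in-plane boundaries (torus topology, N_m + T_m − L_m = 0), evolved in the
constant-(T, A_p, σ) ensemble. The elastic energy is the discrete
Helfrich form

    H_m = Σ_v [ κ/2 (c1_v + c2_v)² A_v + σ A_v ],

with A_v one third of the incident triangle areas and the curvature sum
(c1+c2) evaluated from the cotangent Laplace–Beltrami operator (the energy
needs only |Δx|, so no normal-orientation bookkeeping enters the MC
kernel). The *analysis* operation `vertex_curvature` uses a per-vertex
quadric fit instead, because splitting mean curvature into principal
components via the angle-deficit Gaussian curvature is too noisy to pass
the sphere/cylinder oracles at practical resolutions; the quadric fit
recovers c1 = c2 = 1/R on an icosphere to < 1% and (1/R, 0) on a cylinder
to < 2%. Both estimators agree on (c1+c2) to discretization error.

**Self-avoidance and the tether window.** Link lengths are constrained to
[l_min, l_max] with l_max = √3·a0 (the tether-and-bead convention; the
source text's "between a0 and 3a0" is read as a lost radical). The regular
initial grid has lattice constant a0 = 10 nm, i.e. it sits exactly at the
printed lower bound — a hard core at a0 would jam every vertex move. The
excluded-volume core is therefore exposed as `link_min_factor`·a0 with
default 0.75, keeping a0 as the discretization scale. Both factors are
config knobs.

**Excess area.** A_ex = 100(A − A_p)/A is an output of the ensemble, not a
control. At κ = 20 k_BT and σ = 0 a 240 nm patch equilibrates near
A_ex ≈ 1%. The buckling threshold |σ_c| = κ(2π/L)² is ≈ 0.013 k_BT/nm² on
a 250 nm patch, so any appreciably negative tension drives the patch to the
tether-saturated excess area (≈ 57% with the default window). The
"flexible, large-A_ex" study condition is realized there (σ = −0.6
k_BT/nm²); intermediate A_ex values are not continuously reachable with σ
alone in this small-patch ensemble, which we accept rather than add an
area-constraint term foreign to the model.

**Cytoskeletal pinning** immobilizes a uniformly random fraction (0–12%,
seeded) of vertices; pinned vertices keep their energies and links (and may
carry receptors) but are excluded from vertex-move proposals. This is the
mean-field stand-in for a cortical mesh of size l_c ≈ 150–500 nm.

## Molecules

Receptors are rigid rods of length L_an = 19 nm anchored at mesh vertices
(at most one per vertex), tilted by (θ, φ) from the local area-weighted
vertex normal in a deterministic tangent frame, with flexural energy
κ_f θ²/2 and θ ∈ [0, π/2] (the rod cannot penetrate the surface). The
carrier is a rigid sphere (r_NC = 50 nm) with N_ab radial ligand rods
(L_ab = 15 nm) placed on a deterministic Fibonacci lattice; its orientation
is a unit quaternion, reported as ZXZ Euler angles.

Bonds are a discrete matching (each receptor ≤ 1 ligand and vice versa).
A pair within tip–tip distance d ≤ d* can form a bond; an *established*
bond interacts through the harmonic branch H0 + κ_b(d−d*)²/2 at any d
(a tether reading of the Bell potential), so membrane and carrier moves
strain bonds smoothly instead of crossing an energy discontinuity. d* is
not printed in the source parameter table; the default is 1 nm
(configurable), small against both rod lengths so that "bond" means
near-contact of tips.

## Monte Carlo engine

One MC step is one attempted elementary move. The default mix assigns half
the attempts equally to the five canonical moves (vertex, link flip, NC
translation, NC rotation, receptor hop) and splits the other half between
flexure and bond moves 2 : 5. Canonical moves use plain Metropolis with
full local energy differences: a vertex move re-evaluates the energies of
the vertex and its one-ring plus any bonds anchored there; a link flip
re-evaluates the four quad vertices *including* bonds anchored on them
(the flip rotates their normals); carrier moves re-evaluate all bond
energies and the spherical excluded volume against every vertex. Receptor
hops carry the deg(v)/deg(v′) proposal-asymmetry factor.

**Rosenbluth flexure** draws k = 8 trial orientations uniformly on the
upper-hemisphere solid angle, selects one by Boltzmann weight and accepts
with the new/old Rosenbluth-weight ratio. This passes a sup-norm < 0.02
comparison against the quadrature Boltzmann density and reproduces the
small-angle equipartition limit ⟨θ²⟩ → 2/(βκ_f) within 5%.

**Bond make/break** is a configurational-bias move. For a random receptor,
the option set is {unbound} ∪ {geometrically reachable free ligands}
(reachable: ||A_t − a_b| − L_an| ≤ d*), plus the current bond if strained
out of reach (a source-only option, never a target). Binding proposals draw
the receptor tip uniformly on the spherical cap of directions that land
within d* of the ligand tip (density 1/Ω_cap per steradian, Ω_cap
analytic); unbinding proposals draw the orientation from the flexural
Boltzmann density (exact rejection sampler; normalization by quadrature).
The Hastings ratio combines the energy change, the two generation
densities and the option-set sizes. Detailed balance was validated against
a two-state partition-function quadrature (bound-fraction agreement within
2 s.e. at ~10⁶ steps).

Step sizes for vertex/NC moves are auto-tuned during burn-in to 30–50%
acceptance and then frozen (tuning during production would break detailed
balance; frozen values are stored in checkpoints so resumed runs replay
bit-identically). All randomness derives from one integer seed; production
is chunked with derived sub-seeds, which is also the checkpoint/restart
granularity. The kernel maintains a running total energy; after every run
it is compared against a full independent recomputation (tolerance 10⁻⁶
relative) and any drift is a hard failure.

## Fluctuation spectrum and elastic-constant fits

Heights are extracted in the Monge gauge by barycentric interpolation of
the projected triangulation onto a periodic grid (projected triangle
inversions raise a gauge error). With Fourier-series coefficients
h_q = FFT(h)/N², the spectrum obeys ⟨|h_q|²⟩ = k_BT/(A_p(κq⁴+σq²)) and
Parseval (Σ_q |h_q|² = spatial variance) holds exactly under this
normalization, which the tests enforce. Radial shells group identical |q|
values of the discrete grid. The fit is weighted least squares of 1/⟨|h_q|²⟩
against A_p(κq⁴+σq²), weights from the χ² sampling variance of shell means;
the lowest shell (frame-constrained) and shells beyond q = π/(2a0)
(discretization-dominated) are excluded by default. The estimator is
validated by generator–estimator closure: fields synthesized directly from
the spectrum return κ ∈ {20, 160} k_BT and σ within 10%, and membrane-only
MC at κ = 20 k_BT returns the input within 15%. Note that σ is resolvable
only when σq² is comparable to κq⁴ somewhere in the fit band; closure tests
use σ values chosen accordingly.

Pinning renormalization is tabulated by running the MC + spectrum + fit
pipeline per pinning fraction with replicate seeds; quoted errors combine
fit covariance and replica scatter. The observed behaviour matches the
mean-field expectation: σ_eff always increases with pinning (≈ −0.01 →
0.10 → 0.24 k_BT/nm² at fractions 0/0.06/0.12 for κ = 20), while κ_eff can
shift in either direction.

## Free energy: umbrella sampling, WHAM, TI

The order parameter is ΔR = |R_CM − R_NC| with R_CM the centre of mass of
membrane vertices within 2r_NC of the carrier (minimum-image). Windows sit
on a ladder with spacing δR = 2 nm and spring k_bias = 2 k_BT/δR²
(= 0.5 k_BT/nm²), sampled outside-in with warm starts. Histograms share
one grid (bin width δR/10); WHAM iterates the window free energies to
10⁻⁸ k_BT (≤ 10⁵ iterations) and refuses non-overlapping ladders.
Uncertainties come from a multinomial bootstrap over window histograms.

The additive constant is fixed by thermodynamic integration of the mean
restraint force, dF/dΔR₀ = −k_bias(⟨ΔR⟩ − ΔR₀), integrated inward from the
outermost (unbound) window which is assigned zero; the single constant is
the mean discrepancy between this ladder profile and the WHAM curve. A
plateau-zeroing anchor is provided as an independent cross-check; the two
agree within combined error on the toy systems (harmonic potential
recovered within 0.2 k_BT over the ladder interior; a 5 k_BT Gaussian well
anchored to −5.0 ± 0.3 k_BT). r* is detected as the smallest ΔR beyond
which |W| stays below a tolerance (default 0.5 k_BT), with a 100 nm
fallback for curves that never settle.

## Avidity assembly

K_a is assembled in log space (log-Γ combinatorics), so all components are
finite up to thousands of receptors and hundreds of ligands. The plug-in
multivalency n_b is the mode of P(n_b) (switchable to the rounded mean).
Entropy estimators: A_R^b and A_N^b are covariance-ellipse areas
(π·coverage²·√det Σ, coverage factor configurable, default 1σ) of the
bound-receptor tangent coordinates relative to the carrier axis and of the
carrier's lateral position, accumulated as streaming moments during the
run; the rotational volume is the product of the three Euler-angle standard
deviations; A_R^u = A/N_ant. The tangent frame is the reference plane of
the patch (the mean bound-receptor orientation coincides with its normal
for the geometries simulated here). These estimator choices are held fixed
across all comparisons, which is what ratio-based reporting requires; K_a
itself carries internal nm-based units and every downstream quantity
(η, K_d/K_d†) is a ratio in which the units cancel.

The assembly is validated against a brute-force Monte Carlo integration of
the two-state configurational integral on a toy system with a prescribed
harmonic PMF (agreement ≈ 1%, budget 10%), and the combinatorial factor
against direct small-count enumeration. The density interpolation
K_a* = K_a1^{(n2−n*)/(n2−n1)}·K_a2^{(n*−n1)/(n2−n1)} is exact at the knots
and log-linear in between; extrapolation is gated behind an explicit flag.

## Pharmacokinetic targeting

%id/g is modelled as {Kp·K_EC·C_out + φ_EC·K_EC·L_EC,b·D_EC·C_out}
·(L_cap/L_EC,b) + φ_M·K_M·L_M,b·D_M·C_out·(L_cap/L_M,b). The printed
grouping of this expression is ambiguous; the implementation fixes the
reading above and treats the dominant-term limit
η ≈ (Kp·K_EC)_org/(Kp·K_EC)_lung as the contract (verified to 1% in the
Kp-dominated regime). η is normalized by the lung value at the central
K_EC; its spread comes from evaluating at K_EC ∓ ΔK_EC. The shipped organ
table carries the literature-stated receptor densities for lung
(≈ 2000 μm⁻²) and heart (≈ 50 μm⁻²) and flags Kp and the remaining organ
densities as `user-must-supply` (they are published only as figure data,
which we do not encode as ground truth). The four model scenarios (flat
substrate, EC membrane, EC + resting macrophages, EC + activated
macrophages) differ only in which K values the same context table carries
and whether the macrophage term is enabled. The null model sets %id/g ∝ Kp.
Model-vs-experiment r² uses the Gaussian bootstrap (five sets × 2000
draws; sd = 0 collapses to a point mass) and the null comparison an
unpaired two-sided t-test on the per-set r² values (identical
zero-variance groups return p = 1).

## Synthetic data and what passing tests show

The fixtures module generates every test input: icosphere/cylinder meshes
with analytic curvatures, sinusoid patches with quadrature excess areas,
Gaussian height fields drawn exactly from the Helfrich spectrum, a 1-D
umbrella toy sampled by inverse-CDF (no Markov-chain error), and the
two-state binding toy with an embedded integral oracle. These validate the
estimators, the free-energy machinery and the avidity assembly exactly;
they do not emulate real-membrane features such as lipid heterogeneity,
glycocalyx repulsion, shear flow or active cytoskeletal dynamics, so
passing tests certify the statistical mechanics of the model, not
biological completeness.

## Problem sizes and study conditions

Desk-scale defaults used throughout the tests and the acceptance script:
240 nm membrane-only patches (24×24 vertices) with ~10⁶–4×10⁶ attempted
moves for spectrum work, and a 250 nm patch (625 vertices, 125 receptors
at 2000 μm⁻², N_ab = 162) with 2×10⁷ attempted moves for the adhesion
runs; the production-scale settings of the underlying study (0.25 μm²
patches, ~10⁹ steps per umbrella window, 32-way parallel ladders) remain
configurable. At ~10⁷ steps the multivalency distribution is close to
but not fully equilibrated — bonds are ~19 k_BT deep, so individual chains
can quench in a metastable bond arrangement, and independent replicas
scatter the modal n_b by roughly ±2 around the converged values (8 stiff,
10 flexible/large-A_ex). Mode estimates are therefore reported as the
median over four replicate chains of 2×10⁷ steps (independent placement
and run seeds), using the final third of each chain — the region the
convergence diagnostics place on the plateau.

## Known limitations

- No hydrodynamics, shear flow, glycocalyx energetics or kinetic
  (time-mapped) interpretation of MC steps; equilibrium constants only,
  no on/off rates; ICAM1-mediated internalization is excluded.
- No adaptive remeshing or topology changes; closed meshes are fixtures.
- The bond move's cap-sampling construction is our own (validated against
  equilibrium oracles), not a procedural reproduction of any particular
  published variant.
- With βH0 ≈ −19.3 production bonds are effectively irreversible on desk
  timescales; equilibration of the bond set proceeds through make/rebind
  moves and strain-assisted breakage, which is the slowest mode of the
  simulation (see the replica note above).
- K_a is reported in internal units; only ratios are meaningful outputs.
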