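# Methods

This note documents the physics model, its fixed constants, the
numerical choices, and the limitations of `xpdtsim`.  It is written for
a reader who wants to know what the simulation does and does not
capture before trusting its numbers.

## Photon cross sections

Elemental mass attenuation coefficients for H, O, F, Na, Gd, Tb, Lu,
Be and W are bundled as plain-text tables on a log-energy grid covering
1–200 keV, generated once by `scripts/generate_xsec_tables.py`:

* **photoelectric** from the relativistic Cromer–Liberman imaginary
  anomalous-scattering factor, σ_pe = 2 r_e λ f″ (the compilation
  behind standard crystallographic software, via `gemmi`);
* **coherent (Rayleigh)** from the Thomson cross section modulated by
  squared International Tables atomic form factors f₀(q);
* **incoherent (Compton)** from Klein–Nishina with the
  incoherent-scattering-function approximation
  S(q,Z) ≈ Z(1 − (f₀/Z)²), which suppresses forward incoherent
  scattering at low energy;
* **total** is the sum of the three (no pair production below
  200 keV), so the channel decomposition is exactly consistent;
* **mu_en** is a *kerma-style energy-transfer* coefficient:
  photoelectric plus the energy-weighted Klein–Nishina incoherent
  part.  Fluorescence escape is deliberately not subtracted here,
  because the transport model handles K-fluorescence explicitly (see
  below) and deposits everything else locally; the tabulated
  coefficient and the transport therefore describe the same physics.

Absorption edges (M/L/K of the lanthanides and tungsten, K of sodium)
appear as duplicated grid energies at edge ± 5 eV; log–log linear
interpolation consequently never bridges an edge and is exact at grid
nodes.  Assembled water coefficients agree with standard published
values to within ~3 % over 10–150 keV (asserted in the test suite).

Materials follow the mixture rule (μ/ρ)ₘᵢₓ = Σ wᵢ(μ/ρ)ᵢ.  The
nanoprobe is interpreted as Na(Lu₀.₆₅Gd₀.₂₀Tb₀.₁₅)F₄ — the
20 %/15 % Gd/Tb doping substitutes Lu sites, the standard reading of
doped-nanocrystal nomenclature — and its aqueous suspension at
c mg/mL uses the volume-additive convention: nanoparticle mass
fraction c/(1000·ρ_water + c) and density ρ_water + c/1000
(1.010 g/cm³ at the default 10 mg/mL).  The organic coating is ignored
(low-Z, trace mass).  The suspension is treated as a homogeneous
medium, which is accurate when single particles are small enough that
intra-particle self-absorption is negligible.

## Tube spectrum model

The spectrum generator is semi-empirical, not an electron-in-target
Monte Carlo.  Its components:

* continuum N(E) ∝ (E₀ − E)/E^p with p = 0.79.  p = 1 is the
  thin-target Kramers photon-fluence law; the smaller default exponent
  damps the soft-photon divergence and stands in for anode
  self-absorption of soft photons in a thick target.
* anode self-filtration through an effective tungsten path:
  the Katz–Penfold CSDA range of the incident electrons, halved (mean
  production depth) and projected along the 20° take-off direction,
  scaled by 2.13 and capped at 8.9 µm.  The cap engages at ≥60 kV, so
  low-kV spectra are filtered only lightly (1.1 µm at 20 kV) while all
  higher settings share one effective hardening path.
* Beer–Lambert attenuation through each external filter (0.8 mm Be by
  default).
* tungsten characteristic lines as single-bin peaks: L series at
  8.40/9.67/9.96 keV (branching 0.60/0.25/0.15) above the L₃ edge, and
  K series at 57.98/59.32/67.15/69.07 keV (0.29/0.50/0.17/0.04) above
  the K edge at 69.525 keV.  Line intensity relative to the unfiltered
  continuum is scale·(E₀/E_edge − 1)^exponent with (200, −4.4) for L
  and (0.2, 4.5) for K, and the total line share of fluence saturates
  at 55 %.

The five scalar constants (p, self-filtration scale/cap, line
amplitudes) were calibrated **once** against the reference tube's
fluence-weighted mean energies at 20–160 kVp and then frozen as the
`TubeConfig` defaults; `scripts/calibrate_tube_model.py` is the
calibration record.  The line-share cap is a physicality constraint
added during calibration: an unconstrained fit reproduces the very low
20–40 kV mean energies only by making those spectra almost pure
L-lines, which then over-attenuates in the probe-loaded tumor and
distorts deep-layer enhancement ratios.  With the cap, the shipped
defaults reproduce all eight reference means within ±15 % (±25 % at
20–40 kV, where the reference values imply a strongly line-dominated
beam and any semi-empirical model is coarse).

## Voxel Monte Carlo transport

Photons are sampled from the binned spectrum (bin centers), enter on a
rectangular parallel field that exactly covers the 5 × 5 mm tumor face,
and travel along −z.  Free paths are sampled from the local linear
attenuation coefficient with an exact distance-to-boundary (DDA) voxel
walk — no Woodcock tracking — so heterogeneous phantoms are handled
without bias.  At an interaction the channel is drawn from the partial
cross sections at the local energy:

* **photoelectric** — the photon terminates.  If the absorbing
  material contains Gd, Tb or Lu and the photon energy exceeds that
  element's K edge, the event re-emits a K-fluorescence photon
  isotropically with probability (element's share of μ_pe) × (K-shell
  fraction from the table's edge jump) × ω_K, carrying the
  line-weighted mean K energy (43.9/45.4/55.2 keV for Gd/Tb/Lu,
  ω_K = 0.930/0.933/0.950); the residual energy is deposited locally
  and the fluorescence photon is transported further.  This matters:
  K-fluorescence of these elements has a mean free path of several
  centimetres in tissue and mostly leaves the 5 mm tumor, so
  depositing it locally would roughly double the apparent enhancement
  above 63 keV.
* **Compton** — scattered photon sampled from the free-electron
  Klein–Nishina law by rejection (envelope 2 at cos θ = 1); the recoil
  energy E − E′ is deposited locally.
* **Rayleigh** — direction resampled from the Thomson angular law
  (1 + cos²θ)/2 without atomic form factors (config-switchable
  channel); no energy deposit.

All electron energy is deposited in the interaction voxel (the *kerma
approximation*): CSDA electron ranges below 160 keV in water are under
~0.35 mm, commensurate with the 0.2 mm voxels, so this mainly blurs
sub-voxel gradients.  Histories terminate on phantom exit, below the
1 keV cutoff (residual deposited locally), or at the scatter-count
safety bound.  Per-history energy conservation
(deposited + escaped = initial) is tracked exactly and asserted in the
tests.

In-kernel cross sections live on a 2048-point uniform-log-energy grid
(1–200 keV) per material, linearly interpolated; at that resolution an
absorption edge is smeared by under 0.1 keV near the Lu K edge.

**Reproducibility and uncertainty.**  One master seed feeds
`numpy.random.SeedSequence`; the requested histories are split into
`n_batches` equal batches (default 10) with derived sub-seeds, each run
single-threaded, so results are independent of batch grouping.  The
per-voxel relative standard error of the batch mean is the reported
uncertainty; it follows the expected 1/√N scaling (asserted within
10 %).  The "maximum relative uncertainty" summary statistic is taken
over tumor voxels receiving more than 50 % of the peak tumor-voxel
dose, the common practice of excluding low-dose voxels.

## Phantoms and endpoints

Model A: 5 mm water cube (tumor) centered and flush on the top
6 × 3 cm face of a 6 × 3 × 3 cm water slab; the beam passes through the
tumor into 3 cm of backing tissue.  Model B replaces the cube's
material with the 10 mg/mL suspension.  Models C/D are the bare cubes
with the identical beam.  Voxels are 0.2 mm (the voxel size must
divide 5 mm); the world outside is vacuum.

Depth endpoints average over each 25-voxel-thick tumor layer
(cross-field mean; a central-axis option exists), with layer depth
(k + ½)·0.2 mm from the entry face.  PDD normalizes a depth-dose curve
to its maximum in percent.  DER is the pointwise with/without ratio
with uncertainties combined in quadrature; "excluding the deepest
layer" interprets the customary caveat that the outermost point may
fall below unity from probe self-shielding.  AAD is the mean dose over
all 15 625 tumor voxels.  Dose is linear in fluence, so normalizing a
run to a prescribed entry-layer dose (3 Gy by default in the pipeline)
is an exact global rescale that leaves every PDD and DER unchanged;
enhancement ratios are always computed at equal incident fluence,
while the surface-dose normalization is applied only where the
in-vivo irradiation condition (fixed surface dose per group) is being
emulated.

## Analytic slab oracle

`slab_deposited_energy` evaluates D = Σ NᵢEᵢ(1 − e^(−μ(Eᵢ)t)) for any
material and thickness, with either the attenuation or the
energy-absorption coefficient (the customary formulation is ambiguous
about which; both are exposed).  On 5 mm of elemental lutetium
(ρ = 9.841 g/cm³) the slab is optically thick for every energy below
200 keV (μt ≳ 7), so D degenerates to the spectrum's total energy and
the scan across tube potentials reduces to ranking mean energies —
a structural property of the formula worth knowing before using it as
an optimality check.  `beer_lambert_depth_profile` provides the
primary-beam-only depth profile used as the no-scatter reference in
the transport tests.

## Synthetic in-vivo cohort

The cohort generator emulates the study design it stands in for — one
control plus four irradiated groups (40/80/120/160 kV, five mice each,
3 Gy surface dose), start volumes uniform in 70–125 mm³ — with known
ground truth: exponential growth at g = 0.20/day over 14 days
(a doubling time of ~3.5 days, typical of an aggressive syngeneic
mammary carcinoma), treated growth rate g(1 − s·AAD_norm) clipped at
zero with default effect slope s = 0.8, and multiplicative lognormal
measurement noise with CV 0.15 on every measured volume.  Tumor volume
from caliper measurements uses T = 0.5·L·W as printed in this
experimental tradition (dimensionally an area; the conventional
0.5·L·W² variant is available behind a flag).  TGI follows
(1 − (V_TE − V_TS)/(V_NE − V_NS))·100 % on group-mean volumes,
baseline-normalized so that randomization of start volumes does not
bias the endpoint; a per-mouse variant exists.  In the zero-noise
limit TGI is monotone in AAD_norm, and inverting the growth model
recovers the generative slope exactly (asserted to 1e−6).

What the synthetic cohort does **not** emulate: pharmacokinetics and
probe clearance, heterogeneous intratumoral probe distribution,
hypoxia and oxygen-dependent photodynamic yield, immune effects, and
inter-animal growth-rate heterogeneity beyond measurement noise.
Passing its tests therefore demonstrates that the dose→outcome
pipeline (normalization, interpolation over kV, correlation) is
correct, not that real tumor control is predicted.

## Numerical choices and degenerate inputs

* Log–log interpolation of cross sections; out-of-grid energies raise
  a range error naming the element and bounds.
* Spectrum bins default to 0.5 keV; fluence at/above the tube
  potential is identically zero; generated spectra are normalized to
  unit total fluence.
* Peak finding on depth curves takes the plain maximum (no smoothing);
  ties resolve to the shallower depth.
* Zero-thickness filters and zero-concentration suspensions reduce
  exactly to identities (pure water).
* DER raises on a zero reference layer rather than returning inf.
* Dose conversion refuses energy deposited in a zero-density voxel.
* All randomness flows from explicit integer seeds; every simulation
  entry point is deterministic given its configuration.

## Problem sizes

The shipped defaults aim at a single core: the test suite transports
0.2–1.2 × 10⁶ histories per check, and the reproduction script uses
10⁷ histories per arm for the 40/60 kV enhancement ratios and 10⁶ per
arm for the eight-setting survey — enough for sub-percent AAD-ratio
precision and few-percent layer-DER precision, as the batch
uncertainties themselves report.

## Known limitations

* No electron transport: sub-voxel dose gradients (e.g. nanoscale dose
  kernels around particles) are out of scope by construction.
* L-shell and M-shell fluorescence is deposited locally; only
  K-fluorescence of Gd/Tb/Lu is transported.  L photons (≤9 keV) have
  millimetre-scale ranges, so tumor-level averages are barely
  affected, but individual shallow-voxel doses are slightly
  overestimated.
* Rayleigh scattering uses the Thomson angular law without form
  factors; the channel is small at these energies and can be disabled.
* The tube model is calibrated to mean energies only; higher spectral
  moments (and hence quantities sensitive to the exact fluence shape,
  such as the kV-dependence of enhancement ratios above ~80 kV) carry
  model uncertainty that the mean-energy agreement does not bound.
* The suspension is homogeneous and the beam is monodirectional and
  unpolarized; no collimator scatter, heel effect, or shielding
  geometry is modelled.
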