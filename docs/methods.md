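# Methods

## Model and procedure

`ppsaxs` computes SAXS intensity spectra of point models by the binned Debye
sum. A model is a cloud of N pseudo-electrons, point particles carrying the
local electron-density contrast w (electrons/Å³, signed). The chain is:

1. **Generation.** For the core-shell benchmark, N points are placed
   uniformly in the ball of radius Rₑ: radius by inverse CDF r = Rₑ·U^(1/3),
   direction by a normalized 3D Gaussian triple. This sampler is exact (no
   rejection) and deterministic for a given seed. A point with r < Rᵢ gets
   the core contrast ρᵢ, otherwise the shell contrast ρₑ; the boundary
   r = Rᵢ (probability zero) is assigned to the shell so the rule is a fixed
   half-open partition. Number density is uniform throughout — core and
   shell differ only in per-point weight. The point density implied by N and
   Rₑ may be far below real electron densities (water ≈ 330 electrons/nm³);
   that realism constraint is intentionally not enforced, since the analytic
   comparison only requires uniform sampling.
2. **Encoding (optional).** Coordinates are converted to picometers
   (×10¹² from meters), shifted per axis by the ceiling of the largest
   absolute negative coordinate so all values are non-negative, and rounded
   half-up to the nearest integer, giving unsigned 16-bit values 0…65,535.
   The shift cancels in coordinate differences, so pairwise distances are
   preserved up to rounding. Clouds whose shifted extent exceeds 65,535 pm
   are rejected with a capacity error.
3. **Histogramming.** Every unordered pair i < j contributes the *product*
   w_i·w_j to the bin floor(d_ij / bin_width); bins are left-closed
   half-open, bins hold signed real sums. The product convention is what
   makes the sine transform of the histogram equal the orientation-averaged
   squared scattering amplitude (the Debye sum); a sum convention would not
   reproduce the closed-form benchmark. Self-pairs are excluded: their
   contribution Σw_i² is q-independent (d = 0 means sinc ≡ 1), i.e. a flat
   intensity offset of relative size Σw²/((Σw)²−Σw²) ≈ 4×10⁻⁵ at N = 50,000,
   absorbed into the residual of the scale fit.
4. **Transform.** I(q) = Σ_k H_k·sin(q r_k)/(q r_k) with r_k the bin
   *center* (k+½)·Δr; the center minimizes quantization bias and the
   choice is immaterial at 1-pm bins (see bin robustness below). I(0) is
   the sinc limit Σ_k H_k.
5. **Comparison.** The analytic core-shell intensity is
   I(q) = [ρₑRₑ³A(qRₑ) + (ρᵢ−ρₑ)Rᵢ³A(qRᵢ)]² with A(x) = (sin x − x cos x)/x³.
   Constant volume prefactors (4π/3 per sphere) are omitted: only the shape
   is compared, through a single least-squares multiplying factor
   s = Σ(a·c)/Σ(c²) over a configurable q window. Goodness of fit is
   reported as rel_rms = ‖a − s·c‖₂/‖a‖₂ inside the window — a global
   relative residual, dominated by the low-q region where intensity (and
   the Monte Carlo signal-to-noise) is largest. A pointwise relative
   residual would instead be dominated by the near-zeros of the form
   factor, where any finite-N model diverges relatively while agreeing
   absolutely.

The inverse route, P(r) = (2r/π)∫ q·I(q)·sin(qr) dq by trapezoidal
quadrature on the spectrum's q grid, recovers the distance distribution from
an intensity curve. Distance resolution is limited to ~π/q_max (≈ 393 pm at
q_max = 8×10⁹ m⁻¹) and distances are resolvable only up to ~π/Δq; requests
beyond that set a warning in the result metadata. Any consistent
normalization works here because comparisons with histograms are made
through correlation or a scale fit; P(0) = 0 identically.

## Engine design

The production histogram engine mirrors how such kernels are unrolled on
parallel hardware. The outer loop fixes particle j; the inner loop covers
i > j in groups of `n_partials` lanes, each lane accumulating into its own
partial histogram so lanes never write the same counter; when the remaining
count is not a multiple of the lane count, the leftover pairs are computed
individually in a tail pass (the "dynamic unroll" remainder); the partial
histograms are merged at the end by element-wise addition, which is
order-independent. A separate brute-force oracle (SciPy `pdist` +
`bincount`) defines the result contract; the engine must match it
element-wise.

Numerical choices:

* Accumulation is float64 with Kahan compensation per lane and bin, so the
  result is independent of the `block` dispatch size (a memory/progress
  knob only).
* On integer coordinates, squared distances are exact integers below 2⁵³
  and the correctly-rounded square root makes both engines bit-identical;
  with integer-valued weights the accumulated sums are exact too, so the
  oracle-equivalence checks demand exact element-wise equality there. On
  float clouds, differing summation orders legitimately differ at the
  last-ulp level; agreement is then asserted at 1e-9 relative per bin.
* The bin count is sized from the bounding-box diagonal, a cheap upper
  bound on the largest pair distance, so no pair can overflow the array.
* Mass conservation Σ_k H_k = ((Σw)² − Σw²)/2 holds identically in exact
  arithmetic and is monitored as a global float-path diagnostic.

## Quantization error budget

Rounding moves each coordinate component by at most 0.5 pm, each position by
at most √3/2 pm, hence any pair distance by at most √3 ≈ 1.732 pm (triangle
inequality; the bound is attained only for diagonal displacements). The
observable consequences, verified pair-by-pair against the float path:

* bin indices shift by at most 1 whenever bin_width ≥ √3 pm (asserted at
  2 pm), and by at most 2 at 1-pm bins — a 2-bin shift needs a distance
  error above 1 pm, which occurs for roughly 0.1% of pairs of a random
  cloud;
* the effect on the spectrum is far below the Monte Carlo noise: fitted
  spectra from the two paths agree to ~0.02% RMS for q ≤ 3×10⁹ m⁻¹
  (budgeted at 1%).

## Defaults and parameters

| parameter | default | why |
|---|---|---|
| N | 2,000,000 | reference model size (CLI); analyses here use 50,000 |
| Rᵢ, Rₑ | 5.4, 10.8 nm | reference core-shell geometry |
| ρᵢ, ρₑ | −0.08, +0.07 e/Å³ | reference contrasts (core electron-poor vs water) |
| bin_width | 1 pm | histogram resolution congruent with pm-precision distances |
| q grid | 4,000 linear points to 8×10⁹ m⁻¹ | standard spectrum sampling; dense inverse transforms use 100,000 points |
| fit window | full grid (CLI); 5×10⁷–3×10⁹ m⁻¹ in validation | excludes the high-q tail where finite-N statistical noise dominates |
| n_partials | 8 | lane count; any value ≥ 1 gives identical results |
| block | 65,536 rows | kernel dispatch granularity; memory knob only |

## What the synthetic generator does and does not emulate

The generator reproduces exactly the statistical contract of the benchmark —
uniform density in a sphere, radius-dependent contrast — so passing tests
show that the histogram/transform machinery is correct and that a finite-N
uniform model converges to the analytic form factor. It does not emulate
real experimental data: no solvent structure, no polydispersity, no
instrument smearing, no incoherent background, and point density well below
real electron densities. Agreement here therefore validates the computation,
not any particular structural model of a measured sample.

## Validation problem sizes

The validation runs use reduced model sizes chosen so the statistical bands
are comfortably resolved: N = 50,000 (1.25×10⁹ pairs) for the spectrum and
P(r) comparisons — the relative RMS deviation from the closed form is
~0.2%, two orders inside the 5% band, and the P(r) Pearson correlation is
0.99997 — N = 20,000 for bin-size robustness, N ≤ 2,000 for the exact
engine-equivalence checks, and N = 1,000 clouds for the quantization budget.
Agreement improves monotonically with N (Monte Carlo noise ∝ N⁻¹/²), so
these sizes are conservative stand-ins for the two-million-point reference
model.

## Known limitations

* Single core-shell geometry in the generator; arbitrary multi-shell or
  non-spherical models must be supplied as XYZ/PDB input.
* No cut-off or neighbor-list approximations, deliberately: truncating
  large distances destroys exactly the low-q information SAXS is about.
* The compact path requires model extent < 65,536 pm.
* No instrument effects and no iterative fitting to experimental spectra;
  the single scale factor is the only fitted quantity.
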