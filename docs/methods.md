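# Methods

## Problem and model

RF currents induced in wire-like implants (pacemaker or deep-brain-
stimulation leads) during MRI can heat the tissue at the electrode
contacts. The current near the tip, `I_rms`, is the single scalar that
scales tip heating; measuring it in situ from a short low-SAR prescan
allows a per-patient exposure limit instead of a worst-case one.

The package implements the full measurement chain:

1. **Field model.** An infinite straight wire at angle ξj to B0 crossing
   the axial slice at (x0, y0) carries a constant RF current. The
   transverse (in-plane) component of its quasi-static field is exactly
   azimuthal about the crossing point, with magnitude

       B1j(r, θr) = μ0 μr I cos ξj / (2π r (1 − sin²ξj cos²(θr − θj))).

   The denominator factor is the square of the ratio of the 3-D distance
   to the wire to the in-plane radius. The published rendering of this
   expression is typographically ambiguous; the form above was re-derived
   from the cross-product algebra (the transverse component of a tilted
   wire's field stays azimuthal) and is verified in the test suite
   against a numerically integrated Biot–Savart oracle for a ±1 m
   segment, agreeing to better than 0.1% out to r = 12 mm for
   ξj ∈ {0°, 20°, 45°}.

   The total relative transmit field adds the background and the
   left-circular half of the linear wire field:

       λ(r, θr) = λb(x, y) · sqrt(1 + b² − 2 b sin(θr − φj′)),
       b = B1j / (2 λb B1,rms),

   with λb expanded to first spatial order about the patch center and
   φj′ the wire-current phase relative to the background B1+ phase. The
   assembly is verified against an independent circular-polarization
   decomposition (complex arithmetic in the B1+ = (Bx − iBy)/2
   convention). Only φj′ = φj − φb is identifiable from magnitude images,
   so the fit carries 9 free parameters; φb is kept as an inert field for
   completeness. The model is blind perpendicular to B0: below
   |cos ξj| = 0.1 fits are flagged unidentifiable.

2. **Signal model.** The dual-angle high-dynamic-range AFI sequence
   acquires two interleaved spoiled gradient-echo pairs with different
   flip angles and TRs, twice ((a) and (b)), for four magnitude images.
   Defaults: αa = 45.2°/69.3°, TRa = 23.7/61.5 ms, αb = 21.9°/39.0°,
   TRb = 26.5/188.5 ms, B1,rms = 2.29 µT (the sequence the current is
   referenced to). Per-voxel normalization of the 4-vector to unit
   Euclidean norm removes receive-field, proton-density and T2* factors;
   T1 (a fixed known input, default 1000 ms for gel) is the only
   remaining nuisance, to which the normalized signals are only weakly
   sensitive (verified: ±30% T1 mismatch perturbs fitted currents by
   < 5%).

3. **Slice profile.** A dictionary maps center-of-slice λ (grid 0–30,
   step 0.01) to the four signals averaged over 201 through-plane
   positions spanning ±2 slice thicknesses, using the flip-angle profile
   of a Hann-windowed sinc (time–bandwidth 4) from a hard-pulse Bloch
   simulation at a small reference angle, rescaled linearly to the
   nominal angles. The pulse shape is a package choice (the standard
   product excitation); the dictionary interface isolates it. Linear
   interpolation reproduces direct through-plane averaging to < 2e-5
   absolute; signed through-plane means are kept so intra-voxel
   cancellation near the hotspot is modeled.

4. **Patch forward model.** 12×12 voxels of 2×2 mm (one 2-mm slice,
   576 scalar signals). Each voxel is split into 3×3 in-plane sub-voxels
   (sampled at sub-voxel centers); λ → dictionary → signed sub-voxel
   signals → voxel mean → magnitude → per-voxel normalization. Voxels
   with centers within 2 mm of the wire, or with sub-voxel λ beyond the
   dictionary range, are flagged degenerate and masked rather than
   propagated as NaN.

5. **Inversion.** Differential evolution (population 61, 122 iterations,
   best/1/bin, dithered mutation 0.5–1, crossover 0.7, Latin-hypercube
   initialization) minimizes the RMS difference between modeled and
   observed normalized signals, with a dynamic 4-mm circular mask around
   each candidate's wire position (whole voxels by center distance).
   rand/1/bin was tried first and stalls at ~3–4% current error within
   this budget; best/1/bin converges to ≲0.2% on noiseless data at the
   same budget, matching the expected few-seconds-per-patch behavior, so
   it is the default. Circular parameters (φj′, θj) are searched on a
   doubly covered interval [−2π, 2π] to avoid artificial boundaries at
   ±π; reported values are wrapped to (−π, π] and the (ξj, θj) ↔
   (−ξj, θj+π) degeneracy is resolved toward ξj ≥ 0. An optional polish
   step (off by default, reported in diagnostics) runs a trust-region
   least-squares refinement on the residual vector with a finite-
   difference step spanning several dictionary cells, which the
   piecewise-linear interpolation would otherwise stall.

6. **Heating calibration and exposure limit.** Tip heating obeys
   dT = c_implant·I² with c_implant an implant property at a stated
   reference B1,rms and slice-to-tip distance. c_implant is fitted by
   zero-intercept least squares on I² (closed form c = Σ dT I² / Σ I⁴),
   as the quadratic law has no offset. Probe recordings are
   baseline-corrected (mean over a 5-min baseline) and, because weakly
   heating configurations have noisy peaks, each configuration's peak is
   obtained by scaling the strongest configuration's peak with the
   least-squares scalar between the two curves over the first 20 s of
   exposure (the estimator for the 20-s relative scale is a package
   choice). The exposure limit is
   B1,rms_thresh = B1,rms_seq · sqrt(dT_thresh / (c·I²)); predicting
   heating at the rescaled current returns dT_thresh exactly (tested to
   machine precision). Leave-one-out evaluation refits c from N−1 pairs
   per held-out observation.

## Synthetic data

The generator emulates the phantom experiments, not real tissue: a
straight wire in homogeneous gel, uniform T1, no B0 inhomogeneity,
readout blurring, motion or in-flow. Noise is Gaussian (optionally
Rician) on the raw voxel magnitudes before normalization, with
σ = 0.05 × the strongest background-λb signal, i.e. a null-region voxel
SNR of 20 on the strongest of the four images — emulating body-coil
reception. Synthetic thermometry is a saturating exponential
c·I²·(1 − exp(−t/τ)) (τ = 60 s) plus drift and noise; its initial slope
is proportional to c·I², the short-time inert-phantom regime. Over a
139-s exposure the observable peak constant is
c_eff = c·(1 − exp(−139/60)) ≈ 0.90·c, which is what calibration
recovers. Passing tests therefore demonstrate correctness of the model
chain and inversion under these idealized conditions; they do not
establish in-vivo validity (heterogeneous T1, B1 phase gradients,
implant geometry effects).

Default study sizes: the oversampling study samples 10,000 parameter
vectors (currents 10–300 mA, ξ 0–45°, λb 0.8–1.2 with gradients up to
±0.01/mm, wire within the central 2×2 voxels, uniform phases); parameter
recovery uses 20 noiseless scenes; the noisy end-to-end study uses 9
configurations spanning 50–300 mA with c = 100 K/A². The test suite runs
reduced variants (1,000 draws) of the oversampling study.

## Accuracy observed on synthetic data

Noiseless patches: current recovered within 2% (typically exactly), wire
position within 0.2 mm, RMS residual < 1e-4. At body-coil SNR the
median relative current error across 50–300 mA is ~6%; individual
low-current (50 mA) scenes can err by several tens of percent — this is
the statistical limit (the fitted cost is at or below the cost at the
true parameters), matching the few-to-tens-of-mA absolute errors seen in
real phantom data. Calibration from 9 noisy configurations achieves
R² ≳ 0.95 and recovers the heating constant within ~6%; the realized
heating when scanning at the derived B1,rms limit deviates from the 2-K
target by ≲ 0.4 K over configurations where 2 K is attainable.

## Numerical choices and edge cases

- μr fixed at 1 (nonmagnetic gel/tissue); μ0 exact.
- r = 0 (a point exactly on the wire) is singular: scalar evaluation
  raises, vectorized synthesis returns λ = ∞ and flags the voxel.
- λ values beyond the dictionary grid flag the voxel degenerate rather
  than extrapolating.
- Candidates whose background field goes nonpositive at a patch corner
  are penalized with a large finite cost instead of aborting the
  optimizer run.
- All randomness (sampler, noise, optimizer) flows from explicit seeds;
  identical inputs and seeds give bit-identical outputs.

## Known limitations

- Constant-current, infinite straight wire: invalid for strongly curved
  conductors near the tip (e.g. cochlear implants) and perpendicular to
  B0.
- Single-slice, magnitude-only; no multi-slice joint fitting, no
  phase-image information.
- c_implant is valid only at its calibration slice-to-tip distance and
  reference B1,rms.
- The background B1+ phase is assumed constant over the 24-mm patch.
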