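# rfcurrent

**Measure the RF current induced in a wire-like implant from low-SAR MRI
signals, and turn it into a per-patient RF-heating exposure limit.**

During MRI, the transmit RF field induces a current in wire-like implants
such as deep-brain-stimulation (DBS) or pacemaker leads. That current
deposits power at the electrode contacts and can heat the adjacent tissue.
Because the induced current depends on the lead path and the patient, a
worst-case safety limit is overly restrictive for most patients — and
leaves patients with nonstandard configurations (abandoned or damaged
leads) without access to MRI at all. `rfcurrent` is for MR physicists and
implant-safety researchers who want to *measure* the tip current in situ
from a short, low-SAR B1-mapping prescan and derive an individual exposure
limit for the rest of the session.

## The model

A straight wire at angle ξj to B0, crossing the axial slice at (x0, y0)
and carrying an RMS current I, perturbs the relative transmit field
λ = |B1+|/B1,nom as

```
λ(r, θr) = λb √(1 + b² − 2 b sin(θr − φj′)),

b(r, θr) = μ0 μr I cos ξj / (4π r λb B1,rms (1 − sin²ξj cos²(θr − θj))),
```

where (r, θr) are in-plane polar coordinates about the crossing point,
λb the smooth background field (with linear spatial gradients) and φj′
the wire-current phase relative to the background B1+. The dual-angle
high-dynamic-range AFI sequence (two interleaved spoiled-GRE pairs with
different flip angles and TRs, acquired twice) yields four magnitude
images per slice whose per-voxel unit-norm 4-vector depends only on λ
and T1 — receive field, proton density and T2* cancel. A forward model
(3×3 sub-voxel oversampling, Bloch-simulated slice-profile dictionary)
maps the 10 sample parameters to a 12×12-voxel patch of normalized
signals; differential evolution inverts it, recovering I together with
the nuisance geometry and background parameters.

Heating follows `dT = c_implant · I²`; once `c_implant` is calibrated
for an implant (against thermometry, or EM simulation), a measured
current gives both a heating prediction and the maximum allowable
exposure

```
B1,rms_thresh = B1,rms_seq √(dT_thresh / (c_implant · I²)).
```

## Worked example

Simulate a noisy acquisition around a wire carrying 150 mA at 20° to B0,
fit the current back, and derive the exposure limit:

```python
import numpy as np
from rfcurrent import *

seq = SequenceParams()                    # nominal da-hdrAFI protocol
dictionary = default_dictionary(seq)      # slice-profile dictionary

truth = WireModelParams(
    i_rms=0.150, phi_j_prime=0.8,
    geometry=WireGeometry(np.deg2rad(20), 1.0, 0.7, -0.4),
    background=BackgroundField(1.05),
)
scene = SceneSpec(params=truth, seq=seq, noise_sigma=0.05, seed=2)
patch, _ = generate_patch(scene, dictionary)   # body-coil SNR

fitter = WireCurrentFitter(sequence=seq, dictionary=dictionary,
                           seed=0, polish=True).fit(patch)
print(f"fitted current : {1e3 * fitter.i_rms_:.1f} mA")

cal = ImplantCalibration(c_implant=90.0, b1_rms_ref=2.29)
print(f"predicted heating at 2.29 uT : {predict_dt(cal, fitter.i_rms_):.2f} K")
print(f"B1,rms limit for dT <= 2 K   : "
      f"{b1_threshold(cal, fitter.i_rms_, 2.29, 2.0):.2f} uT")
```

Output:

```
fitted current : 153.1 mA
predicted heating at 2.29 uT : 2.11 K
B1,rms limit for dT <= 2 K   : 2.23 uT
```

The fitted 153.1 mA (truth: 150 mA) is the RMS tip current referenced to
the sequence's B1,rms of 2.29 µT. With a calibration of 90 K/A² this
configuration would heat ~2.1 K during the measurement sequence itself,
so the session should stay below 2.23 µT B1,rms to keep heating under
2 K. On noiseless data the fit recovers the current to better than 2%
and the wire position to 0.2 mm; at body-coil SNR the median error
across 50–300 mA is about 6%.

A command-line workflow mirrors the library
(`rfcurrent build-dict | simulate | fit | calibrate | predict | limit`),
consuming NIfTI images, CSV tables and YAML configs; see `rfcurrent
--help`.

`WireCurrentFitter` and `ImplantHeatingModel` follow the scikit-learn
estimator contract (`get_params`/`set_params`, fitted attributes with
trailing underscores) and compose with sklearn utilities.

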