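# polchip

Quantitative polarized-light microscopy (QPLM) for lensless, on-chip
imaging: a wavelength-resolved Jones-calculus model of a crossed-polarizer +
full-waveplate train, CIE colorimetry of the transmitted spectra, and the
inverse path that turns observed interference colors back into phase shift
and birefringence by CIEDE2000 color matching — including the ±45° waveplate
test that identifies negatively birefringent needles (monosodium urate, the
gout marker) by sign.

## Who this is for

People building or analyzing compact polarization microscopes — crossed
polarizer films, a one-wave (full) waveplate, a broadband LED, and a bare
CMOS sensor — who want *numbers* (retardance in nm, birefringence Δn) out of
the colorful images such devices produce, plus synthetic scenes with ground
truth to validate the whole chain.

## The model in brief

A birefringent sample of thickness *d* and birefringence Δn imposes a phase
φ(λ) = 2π·d·Δn/λ between its fast and slow waves. Between crossed polarizers
the transmitted spectrum of a broadband source I(λ) becomes an interference
color (the Michel-Lévy correspondence); integrating it against the CIE 1931
observer gives XYZ → CIELAB. The package tabulates this forward map on a
dense retardance grid, then inverts observed pixel colors by minimizing the
CIEDE2000 distance ΔE to the table. Because the source is broadband, the
band-averaged phase

    φ̄ = 2π·(d·Δn)·ln(λf/λi) / (λf − λi)

summarizes the match, and at known thickness inverts to

    Δn = (λf − λi)·φ̄ / (2π·d·ln(λf/λi)).

## Worked example

A mica plate of known thickness d = 210 µm with its optic axis at 45°
between crossed polarizers, illuminated by the built-in white-LED model:

```python
import numpy as np
import polchip as pc

source = pc.led_spectrum()                      # two-Gaussian white LED
train = pc.OpticalTrainConfig()                 # LP1 0°, LP2 90°, no FWP
lut = pc.build_color_lut(source, train)         # OPD 0–3000 nm, 1 nm step

plate = pc.make_uniform_plate(opd_nm=1134.0, axis_deg=45.0, shape=(24, 24))
image, truth = pc.render_scene(plate, source, train)

pm = pc.retrieve_phase(image, lut)              # CIEDE2000 argmin per pixel
phi = float(np.median(pm.avg_phase_rad))
est = pc.birefringence_from_phase(phi, thickness_um=210.0)
print(f"retrieved OPD  : {np.median(pm.opd_nm):.0f} nm")
print(f"avg phase      : {phi / np.pi:.3f} pi rad")
print(f"birefringence  : {est.delta_n:.4f}")
```

prints

```
retrieved OPD  : 1134 nm
avg phase      : 4.077 pi rad
birefringence  : 0.0054
```

i.e. the pipeline recovers the literature mica birefringence it was asked to
simulate. The closed-form inversion alone, for a plate whose color sits at
φ̄ = 3.85π:

```python
>>> pc.birefringence_from_phase(3.85 * np.pi, thickness_um=210.0).delta_n
0.00509880557951356
```

→ Δn = 0.0051 at two significant figures.

For the sign test, render the same needle with the waveplate at +45° and
−45°, retrieve both against the crossed-polarizer LUT, and compare:
`pc.sign_from_fwp_pair(pm_plus, pm_minus, object_axis_deg)` returns −1 over
MSU-like needles (long axis fast), +1 for positive birefringence, 0 where
undetermined.

## Command line

```
polchip build-lut --out lut.csv
polchip simulate --config run.yaml --out scenes/
polchip retrieve --image scenes/scene_000_uniform/image.png --lut lut.csv --out ret/
polchip birefringence --phase-tiff ret/avg_phase_rad.tif --thickness-um 210
polchip chart --lut lut.csv --out chart.png
```

Every command writes a resolved config next to its outputs and prints a JSON
summary to stdout; identical configs and seeds reproduce outputs
byte-for-byte.

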