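# quadholo

Simulation and reconstruction for **four-channel synchronous phase-shifting
digital holography** — quantitative phase imaging of transparent objects
(etched phase charts, polymer beads, cells) in which four cameras record
four phase-shifted holograms *simultaneously*, so even moving objects can
be measured.

The modeled instrument is a polarization-based Mach–Zehnder interferometer:
each arm passes a 45° polarizer and a quarter-wave plate, the arms recombine
in a polarizing beamsplitter, and each output port is split once more
through a 45° quarter-wave plate and a second polarizing beamsplitter onto
two cameras.  The four cameras see the same interference pattern with
reference-phase offsets 0, π/2, π and 3π/2:

```
I_CCDi = ¼ [ α²A_O² + A_R² ± 2 α A_O A_R {cos, sin}(Δφ) ]
```

The phase of the object is recovered by the four-step arctangent

```
Δφ(x, y) = atan2( I_CCD3 − I_CCD4 , I_CCD1 − I_CCD2 )
```

and converted to physical thickness through the optical path difference
`Δh = λ·Δφ / (2π (n_s − n_m))`.

The package provides:

* `quadholo.jones` — exact 2×2 Jones calculus for the optical elements;
* `quadholo.samples` — synthetic phase objects with known ground truth
  (USAF 1951 phase chart, PMMA beads, moving-bead sequences);
* `quadholo.forward` — the four-camera forward model, both as an explicit
  Jones chain and in closed form (mutual oracles), plus camera noise
  (Poisson + read + quantization) and per-camera misalignment;
* `quadholo.registration` — one-time intensity-based channel registration
  (correlation-ratio metric, multi-resolution, Powell);
* `quadholo.reconstruct` — arctangent phase retrieval, calibration
  subtraction, minimum-norm (least-squares/DCT) unwrapping, thickness maps;
* `quadholo.metrics` — line widths, three-bar resolvability, ROI step
  heights with repeat statistics, bead peak phase;
* a `quadholo` command line (`simulate`, `reconstruct`, `measure`,
  `pipeline`) working on TIFF holograms + YAML configs.

See `docs/methods.md` for the model, its assumptions and the numerical
choices.

## Worked example

Simulate a phase chart (213.8 nm etch, the manufactured height of a real
200 nm target) through misaligned, noisy cameras, then run the full inverse
pipeline:

```python
from quadholo import *
from quadholo.config import RunConfig
from quadholo.pipeline import simulate_acquisition, reconstruct_maps
from quadholo.metrics import inner_roi

cfg = RunConfig(
    seed=7,
    optics=OpticalConfig(shape=(512, 512), arm_phase_offset=0.4),
    misalignment=MisalignmentModel({
        2: ChannelTransform((3.2, -1.7), 0.3),
        3: ChannelTransform((-2.0, 2.5), -0.2),
        4: ChannelTransform((1.0, 1.0), 0.4),
    }),
    sample={"kind": "usaf", "groups": [[6, 1], [7, 1]],
            "height_um": 0.2138, "n_s": 1.52, "n_m": 1.0},
)
sample, holos, calib = simulate_acquisition(cfg)
result = reconstruct_maps(holos, calib, registration_cfg=cfg.registration,
                          wavelength=0.532, n_s=1.52, n_m=1.0)

est = result["registration"].transforms[2]
print(f"CCD2 misalignment estimate: {est.translation[0]:+.2f}, "
      f"{est.translation[1]:+.2f} px, {est.rotation_deg:+.3f} deg")
feat = sample.features[(6, 1)]
step = step_height(result["thickness"],
                   inner_roi(feat["square"]), inner_roi(feat["substrate"]))
print(f"residues: {result['residues']}")
print(f"recovered step height: {step * 1e3:.1f} nm (truth 213.8 nm)")
print(f"theoretical resolution: {theoretical_resolution(0.532, 0.25):.3f} um")
print(f"group 8 element 4 line width: {usaf_linewidth(8, 4):.3f} um")
```

Output:

```
CCD2 misalignment estimate: +3.21, -1.71 px, +0.298 deg
residues: 0
recovered step height: 210.7 nm (truth 213.8 nm)
theoretical resolution: 1.064 um
group 8 element 4 line width: 1.381 um
```

The injected CCD2 misalignment was (+3.2, −1.7) px at +0.3°: registration
recovers it to ~0.01 px / 0.002°.  The wrapped phase has zero residues, and
the step height of the group-6 square pad comes back within ~3 nm of the
simulated truth under shot noise, read noise and 12-bit quantization.
`theoretical_resolution` is the diffraction limit λ/(2NA) of the default
hardware; 1.381 µm is the line width of USAF group 8, element 4 — the
finest element such a system resolves in practice.

The same pipeline from the shell:

```sh
quadholo pipeline --config run.yaml --seed 7 --out out/
# out/holograms/ccd[1-4].tif, out/calibration/, out/maps/*.tif, out/report.json
```

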