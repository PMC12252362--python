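# flfaquant

Detection and quantification of **weak fluorescence signals in
lateral-flow-assay (LFA) strip images**, for filter-free fluorescence
readers.

Fluorescence LFAs (quantum-dot-labeled test strips) are read by imaging
the strip and quantifying the T/C capture lines. Removing the emission
filter preserves optical flux — crucial for trace detection — but elevates
the background with stray light, leaving target bands at very low
contrast. `flfaquant` implements a continuous-wavelet-transform (CWT)
pipeline that localizes and quantifies such bands reliably down to
contrasts of a few noise standard deviations, together with a seeded
synthetic strip-image generator (so everything is testable without an
instrument) and four-parameter-logistic calibration to map readouts to
analyte concentration.

## Method

Images are reduced to a gray matrix (red plane by default — quantum dots
emit red) and collapsed into directional projection curves

```
Y_j = Σ_{i=1..h} y_ij ,   j = 1..w
```

Each curve is convolved with Mexican Hat (Ricker) wavelets

```
ψ(t) = (1 − t²/σ²) exp(−t²/2σ²)
```

at scales s = 30…37 (kernel support 128 samples, amplitude 1/√s,
truncation-corrected to exact zero mean), and the per-scale coefficient
curves are averaged into a detection curve W. Peaks are located by the
sign changes of the interval derivative

```
W'_j = (W_{j+n} − W_{j−n}) / (2n + 1)
```

and delimited by the nearest flanking troughs; a peak is kept only if its
trough separation exceeds μ = 32 samples and its apex rises sufficiently
above the detection-curve noise level. Positioning is X-then-Y: column
slabs from the X projection, then a Y projection inside each slab decides
strip (no Y peak → full-height band) versus dot-matrix (one spot ROI per Y
peak). Each ROI is scanned line by line; row y contributes its trough
span [dp_l(y), dp_r(y)], baseline `baseval_y = (f(dp_l,y)+f(dp_r,y))/2`,
and background-subtracted area, aggregated into the readout

```
avePix = Σ_y Σ_{x=dp_l(y)}^{dp_r(y)} (f(x,y) − baseval_y)  /  Σ_y (dp_r(y) − dp_l(y))
```

Dose–response calibration uses the 4PL model
`y(x) = D + (A−D) / (1 + (x/C)^B)` with closed-form inversion.

## Worked example

```python
import imageio.v3 as iio
import numpy as np
from flfaquant.pipeline import load_config, run_detect
from flfaquant.simulate import Band, Background, SceneSpec, generate

spec = SceneSpec(
    shape=(200, 600),
    background=Background(base=40.0, slope_x=8 / 600),   # stray-light gradient
    bands=(Band(center=200, sigma=22.0, amplitude=12.0),  # weak T line, 6x noise
           Band(center=420, sigma=22.0, amplitude=60.0)), # C line
    noise_sigma=2.0,
    seed=7,
)
img, truth = generate(spec)
iio.imwrite("strip.png", img.data.astype(np.uint8))
run_detect(["strip.png"], load_config(None), ".")
```

`strip.result.json` then contains (abridged):

```json
{"signals": [
  {"mode": "strip", "x_left": 143, "x_right": 257, "apex_x": 200,
   "avepix": 5.678, "avepix_relative": 0.0223, "n_rows_detected": 200},
  {"mode": "strip", "x_left": 362, "x_right": 478, "apex_x": 420,
   "avepix": 27.938, "avepix_relative": 0.1096, "n_rows_detected": 200}]}
```

Both band apexes are recovered at the true centers (200 and 420); each
record carries the ROI bounds, the mean background-subtracted gray value
per pixel (`avepix`), and the same value normalized by full scale
(`avepix_relative`, the relative fluorescence intensity). The weak band
— only 12 gray levels above a background of ~40 with noise σ = 2 — is
localized exactly and quantified at roughly a fifth of the bright band's
readout, consistent with the 5× amplitude ratio (the readout scales
linearly with band amplitude).

The same pipeline is available from the shell:

```sh
flfaquant simulate --out-dir work --centers 200,420 --amplitude 12 --seed 7
flfaquant detect work/strip_00007.png --out-dir work
flfaquant eval --n-scenes 20 --seed 1          # accuracy on a weak-signal suite
flfaquant fit calibration.csv --out fit.json   # 4PL dose-response fit
```

## Layout

| module | role |
| --- | --- |
| `flfaquant.image_io` | PNG/TIFF loading, channel reduction, JSON/CSV reports |
| `flfaquant.projection` | directional projection curves |
| `flfaquant.wavelet` | Mexican Hat kernels, multi-scale CWT, noise estimation |
| `flfaquant.peaks` | derivative zero-crossing apexes, troughs, μ/SNR validity |
| `flfaquant.quantify` | X-then-Y ROI extraction, per-scanline avePix |
| `flfaquant.calibration` | 4PL fitting (`FourPLResult`) and inversion |
| `flfaquant.simulate` | seeded synthetic strips/dot matrices + ground truth |
| `flfaquant.analytic` | closed-form noise-free pipeline theory (ground truth) |
| `flfaquant.pipeline` / `flfaquant.cli` | orchestration, config, `flfaquant` command |

See `docs/methods.md` for the model, parameter and design notes.
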