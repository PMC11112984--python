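# stereotrack

3D single-particle localization and tracking from parallax stereo-pair
projection microscopy images.

A stereo projection microscope records each volume as two 2D extended-focus
projections along axes tilted by a small parallax angle. A particle's depth is
encoded in its *disparity* — the signed horizontal offset of its image between
the two views — which is linear in depth under parallel projection.
`stereotrack` implements the full computational pipeline:

1. **restoration** — low-pass denoising and Richardson–Lucy deconvolution of
   each view;
2. **detection** — adaptive-threshold segmentation plus circular-Hough (beads)
   or local-maximum (PSF-limited spots) detection, with sub-pixel centroid,
   radius, intensity and encircled-energy features;
3. **stereo matching** — globally optimal left↔right assignment (Hungarian
   algorithm) over a feature-combination cost with an epipolar row gate, then
   disparity→depth conversion to 3D positions in micrometers;
4. **tracking** — frame-to-frame Hungarian linking with a distance gate, plus
   gap closing that bridges track ends to later track starts;
5. **analysis** — time-averaged MSD, drift velocity, localization precision
   and depth-error reports;
6. **synthetic data** — a first-class simulator (scenes, Brownian motion with
   drift, projection rendering with PSF blur, Poisson/read noise and view
   crosstalk) so the whole pipeline is testable without a microscope.

Default geometry: 28.1° full parallax angle, 110 × 110 μm field of view,
100 μm depth of field, 512 × 512 frames, 30 volumes/s.

## Command-line interface

```bash
# simulate a 13-bead stereo frame sequence + ground truth
stereotrack simulate --n-particles 13 --frames 10 --seed 42 --out sim/

# frames -> per-frame 3D positions CSV
stereotrack reconstruct --input sim/ --out particles.csv

# 3D positions -> linked trajectories
stereotrack track --input particles.csv --out trajectories.csv

# trajectories -> MSD/drift reports and plots
stereotrack analyze --input trajectories.csv --out analysis/

# or everything at once
stereotrack run --input sim/ --out results/
```

All subcommands accept `--config optics.yaml` (strict YAML config with
`optics`, `restoration`, `detection`, `matching`, `tracking` blocks; unknown
keys are rejected). Stereo input is two multi-page grayscale TIFF stacks
(`left.tif`/`right.tif`) or one interleaved stack (`--dialect interleaved`,
even pages = left). CSV outputs use micrometers with z relative to the
mid-plane of the depth of field.

## Library example

```python
import stereotrack as st
from stereotrack.config import PipelineConfig
from stereotrack.pipeline import run_pipeline

cfg = PipelineConfig()
cfg.detection.r_min_px, cfg.detection.r_max_px = 7, 14   # 4.46 μm beads

scene = st.make_scene(13, radius_um=2.23, seed=42, min_separation_um=12.0)
pairs, truth = st.simulate_sequence(
    scene, st.MotionModel(diffusion_um2_per_s=0.5),
    cfg.optics, st.NoiseModel(background_photons=10.0, seed=42), n_frames=120,
)
result = run_pipeline(pairs, cfg)
print(len(result.trajectories), "trajectories")
```
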