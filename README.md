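# airseg

Semi-automatic segmentation and volumetry of the nasal airway space in
CBCT-like volumes, together with a synthetic digital-phantom generator for
accuracy validation against an analytic gold standard, and the reliability
statistics (paired t-test, ICC, random error) used to evaluate repeated
measurements.

## What it does

The segmentation pipeline runs in five steps on a grayscale volume:

1. **Smooth** — median filter then Gaussian (both optional, physical units).
2. **Binarize** — air is every voxel with intensity at or below a threshold.
3. **Region of interest** — built from five anatomical landmarks: two
   coronal boundary planes, a natural cubic spline roof extruded laterally,
   and the natural cavity floor (no geometric cut below or sideways).
4. **Block** — user-specified disk-slabs seal sinus connections in the
   binary image so region growing cannot leak into the paranasal sinuses.
5. **Region-grow and measure** — the connected component containing a seed
   (6/18/26-connectivity), converted to mm³ via the exact voxel volume.

For accuracy studies, `max_disconnecting_threshold` finds the highest
threshold that keeps an enclosed air space disconnected from the outside —
by binary search over the discrete intensity set with a connectivity check
per probe.

The `phantom` module generates CBCT-like digital phantoms (air −1000,
soft-tissue mimic 300, bone 800, Gaussian partial-volume blur, detector
noise) whose cavity volumes are known in closed form, plus simulated
repeated-measurement tables.  The `meshing` module exports watertight STL
surfaces and provides an independent divergence-theorem volume oracle.

## CLI

```bash
# generate the default left/right phantom pair (≈1220 / 830 mm³ cavities)
airseg phantom --spacing 0.4 --seed 0 --out out/phantom

# find the highest disconnecting threshold
airseg threshold-find out/phantom/phantom.mha \
    --inner-seed 30.2 18 18 --outer-seed 22 6 18

# segment (landmarks from the phantom's ground-truth manifest)
airseg segment out/phantom/phantom.mha --landmarks landmarks.json \
    --threshold -221 --seed 30.2 18 18 --out out/seg

# reliability statistics from a two-session CSV + full-loop accuracy report
airseg validate --measurements sessions.csv --accuracy --out out/report

# STL export of a segmentation mask
airseg export-stl out/seg/segmentation.mha --out airway.stl
```

Exit codes: 0 success, 2 input error, 3 computation error.  Volumes are read
from DICOM directories or MetaImage/NIfTI files; all randomness is seeded.

## Library example

```python
from airseg import nasal_pair_spec, generate_phantom, SegParams
from airseg import max_disconnecting_threshold, segment_nasal_airway

volume, truth = generate_phantom(nasal_pair_spec(spacing=0.4, rng_seed=0))
t_star = max_disconnecting_threshold(volume, truth.seeds["left"], truth.outer_seed)
params = SegParams(threshold=t_star, seed=truth.seeds["left"],
                   median_radius=0, gaussian_sigma=0.0)
result = segment_nasal_airway(volume, truth.landmarks, (), params)
print(result.volume_mm3, truth.cavity_volumes["left"])
```
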