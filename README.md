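# velogrid

4D (3D + time) measurement of soft-palate motion from stereo-endoscopic
video, with a landmark-free virtual-grid parameterization and principal
component motion modes.

## The problem

Velopharyngeal closure — the soft palate (velum) sealing the nasal from the
oral cavity — is essential to normal speech, and its precise evaluation
matters for cleft-palate therapy. Endoscopy shows the velopharynx but is
qualitative, and the region offers almost no reliable anatomical landmarks,
so tracking a handful of named points cannot characterize how the surface
moves. This toolkit implements the alternative: reconstruct the whole
soft-palate surface per video frame as a *range image* (a raster whose
pixels carry 3D coordinates in mm), parameterize a region of interest with a
fixed virtual grid, and summarize the motion of the grid's 3D samples
statistically.

## The measurement chain

1. **Stereo capture model** (`velogrid.camera`) — Tsai pinhole camera with
   first-order radial distortion: forward projection, closed-form
   undistortion, two-stage calibration (radial alignment constraint +
   Levenberg–Marquardt refinement) from planar or non-coplanar targets, and
   planar rectification so epipolar lines become image rows.
2. **Scanline stereo** (`velogrid.matching`) — per-row dynamic programming
   with the sampling-insensitive (interpolation-interval) pixel
   dissimilarity, minimizing
   `Σ dissimilarity + N_occ·κ_occ − N_match·κ_r` under the ordering
   constraint (defaults κ_occ = 25, κ_r = 5 on the 0–255 scale). Occluded
   pixels are masked, never interpolated.
3. **Range imaging** (`velogrid.ranging`) — composite-video splitting,
   deinterlacing by linear row interpolation, and triangulation
   `z = f·B/(d·dx)` into the left rectified camera frame (mm).
4. **Virtual grid** (`velogrid.grid`) — a quadrangle ROI drawn on the soft
   palate is divided equally into a 5 × 5 grid; its 36 intersections are
   sampled in 3D per frame by bilinear interpolation over valid pixels. The
   centroid ("center of gravity") of the 36 samples and its maximum
   displacement from the rest frame summarize motion magnitude.
5. **Motion statistics** (`velogrid.stats`) — each frame's 36 × 3
   rest-relative coordinates form a 108-vector; PCA over frames yields
   motion modes (12 scores per frame by default), mode shapes are
   reconstructed as `mean + score·loading`, group differences in maximum CoG
   shift are tested with a two-sided Mann–Whitney U (exact when n₁+n₂ ≤ 25
   and tie-free), and a two-class linear discriminant on (PCS1, PCS2)
   quantifies group separability.
6. **Synthetic scenes** (`velogrid.synthetic`) — a textured patch at
   endoscopic working depth (20–60 mm) deforming a few mm in a dominant
   posterior-upper direction, rendered through the full camera model by ray
   casting, with analytic ground truth for every derived quantity. This is
   how the pipeline is validated without hardware.

## Worked example

```bash
velogrid simulate --preset small --seed 3 --out fixtures/
velogrid depth --left-dir fixtures/ --right-dir fixtures/ \
    --calib fixtures/rig.yaml --max-disparity 80 --out range/
velogrid grid --range-dir range/ --roi fixtures/roi.json --out traj.csv
velogrid pca --traj traj.csv --k 4 --out pca/
```

which prints, stage by stage:

```
wrote 6 stereo frames to fixtures/
wrote 6 range images to range/
wrote trajectory (6 frames x 36 nodes)
fit 4 components; leading explained variance: 98.0%, 1.6%, 0.3%
```

The trajectory CSV holds the 36 grid intersections' mm coordinates per
frame; the PCA output says a single mode explains 98% of the variance —
expected, since the synthetic scene injects one dominant motion direction.
`velogrid all --preset small --seed 3 --out run/` runs every stage with a
manifest; reruns are bit-identical. The same chain runs in-process via
`velogrid.experiments.end_to_end_metrology(seed)`, which on the canonical
scene (depth 40 mm, amplitude 4.7 mm, 30 frames) reports a recovered maximum
CoG shift of 2.112 mm against an analytic truth of 2.109 mm (error
0.003 mm) and a first-mode alignment |cos| = 0.9998.

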