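# kinectqa

Quality-assurance metrics for markerless body-tracking recordings made
with an Azure-Kinect-style time-of-flight depth camera.

Studies that track human movement with the Azure Kinect Body Tracking
SDK (gait labs, repeated clinical assessments) need to know whether
recordings made on different days — under different ambient or infrared
light — are comparable. `kinectqa` implements the metrics and the
statistical protocol used to answer that question on static test scenes,
plus a synthetic-data generator so the whole pipeline can be exercised
and validated without camera hardware or multi-gigabyte recordings.

## Metrics

For a static scene recorded over f frames at 30 fps (the first 60 frames
are discarded as tracker convergence):

* **Depth random error** — per pixel p of a region of interest,

  `re[p] = sqrt( Σ_t (d[p,t] − d̄[p])² / n_valid )`,

  the population RMS deviation of the depth samples (mm) from their
  mean, over the frames in which pixel p holds a valid measurement.
  Invalid samples (sentinel 0: weak or mixed fore-/background signal)
  are excluded and counted; a pixel valid in a single frame has re = 0.

* **Mean distance error (MDE)** — per joint j, a sliding centroid
  `c[j,t]` is the mean joint position over the 2N+1 frames `[t−N, t+N]`
  (N = 30, the frame rate; windows clipped and renormalized at the
  sequence ends), and

  `MDE[j] = mean_t ‖ x[j,t] − c[j,t] ‖`

  is the time-average Euclidean distance (mm) of the joint to its own
  centroid — a jitter/precision metric, not accuracy against ground
  truth.  For i.i.d. isotropic Gaussian jitter with SD σ,
  `MDE ≈ σ·√(8/π)·√(2N/(2N+1)) ≈ 1.583 σ`.

* **Inter-joint distance** — per frame, the Euclidean distance between
  two joints; for the ankle pair this is the stance width (static) or
  step width (gait).

* **Comparison protocol** — Kolmogorov–Smirnov (Lilliefors) normality
  screening; Kruskal–Wallis across independent lighting conditions, or
  Friedman across repeated recordings of the same pixels; when the
  omnibus test is significant at α = 0.05, pairwise rank z-tests
  (Dunn's test / within-block rank sums) with Bonferroni correction.

## Worked example

```python
import kinectqa as kq

# a 5-minute synthetic recording: static pose + per-joint jitter at the
# mm scale of a mannequin ~1.9 m from the camera, 60-frame transient
cfg = kq.PoseSimConfig(
    true_positions=kq.default_static_pose(),
    sigma_mm=kq.default_joint_jitter_mm(),
    n_frames=9002, seed=1,
    transient=kq.TransientConfig(),
)
seq = kq.cut_frames(kq.simulate_tracking(cfg), 60)

mde = kq.compute_mde(seq)                 # 18 analysis joints, N = 30
print(round(mde.mde["PELVIS"], 2))        # 0.62
print(round(mde.median, 2), [round(q, 2) for q in mde.iqr])
                                          # 1.03 [0.84, 1.58]
ankles = kq.joint_pair_distance(seq, "ANKLE_LEFT", "ANKLE_RIGHT")
print(round(ankles.summary.median, 1))    # 210.0
```

The pelvis is the steadiest joint (MDE 0.62 mm), the median over the 18
analysis joints is ~1.0 mm, and the stance width of the default pose is
210 mm with sub-millimetre spread — the precision floor one can expect
from this tracking pipeline on a perfectly static subject.

The same API reads real recordings: `kq.read_tracking_json(path)` for
body-tracking JSON in the `offline_processor` dialect, and
`kq.read_depth_stack(manifest)` for depth stacks stored as 16-bit PNG
sequences.  A `kinectqa` command-line tool wraps the common verbs
(`simulate`, `depth-re`, `mde`, `pairdist`, `compare`, `run`).

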