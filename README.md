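# ciliatransport

Quantification of ciliary-membrane-protein transport from fluorescence
time-lapse microscopy, built for the *C. elegans* setting in which
GFP-tagged cargo (e.g. a receptor-type guanylyl cyclase) is imaged moving
along the dendrites of phasmid sensory neurons toward the cilium, and IFT
particles are imaged inside the cilium itself.  Because raw movies of
this kind are rarely deposited, the package ships a synthetic-movie
simulator with exact ground truth that reproduces the statistical
structure of such acquisitions, and every stage of the pipeline is
validated against it.

## What it computes

Movies are acquired at 1 frame / 0.5 s.  The pipeline runs:

1. **Drift registration** — for consecutive frames, the integer
   displacement `d` minimizing the mean square difference
   `MSD(d) = mean_p (I_t(p + d) − I_{t−1}(p))²` over an ROI (exhaustive
   scan; bright moving puncta are masked out of the mean), chained into
   per-frame offsets.
2. **Kymograph** — the movie is resampled along a hand-traced dendrite
   or cilium path at fixed arclength steps; each entry is the maximum
   intensity over a short segment perpendicular to the path, giving a
   distance × time image in which a particle at steady speed *v* is a
   straight ridge of slope *v*.
3. **Event scoring** — per-row peaks (subpixel, parabolic refinement)
   are linked into traces by nearest-neighbour prediction, traces are
   segmented into steady straight runs (RMS residual ≤ ρ about a
   least-squares line, ρ = 0.3 µm by default), and a trace counts as
   **one transport event** iff it contains a steady segment moving
   **more than 3 µm**; its representative speed and direction come from
   the longest such segment.
4. **Statistics** — per direction (anterograde = away from the soma):
   mean velocity ± s.e.m. (sd/√n), velocity histograms, and event
   frequency = events / minutes observed; genotypes are compared with
   Welch's two-sample *t* test.  For intraflagellar transport, steady
   segments are split at a declared middle/distal junction arclength and
   per-region velocities reported.
5. **Ciliary fluorescence** — a confocal z-stack (0.7 µm sections) is
   thresholded and quantified as
   `total = (voxel volume × n supra-threshold voxels) × mean intensity`,
   and genotypes compared as a percentage ratio of totals.

The packaged presets encode the study conditions: wild-type dendritic
transport (anterograde 1.11 µm/s mean, 134 events / 34 min; retrograde
0.80 µm/s, 88 events / 34 min), a transport-impaired mutant (147
anterograde / 67 retrograde events in 64 min, slower fixture
velocities), two-segment IFT (~0.4 µm/s middle, ~1 µm/s distal, junction
at 4 µm), and a paired z-stack fixture with a ground-truth fluorescence
ratio of exactly 26%.

## Worked example

```python
import ciliatransport as ct

session = ct.run_transport_session(ct.load_preset("WT"), seed=7)
a = session.stats.anterograde
print(f"anterograde: n={a.n}  mean={a.mean_velocity_um_s:.3f} "
      f"+- {a.sem_velocity_um_s:.3f} um/s  freq={a.frequency_per_min:.2f}/min")
```

prints (34 simulated minutes, full register → kymograph → detect →
score → stats pipeline):

```
anterograde: n=136  mean=1.085 +- 0.037 um/s  freq=4.00/min
```

i.e. 136 anterograde events were scored in 34 minutes with a mean
velocity of 1.085 ± 0.037 µm/s — within one s.e.m. of the generative
mean of 1.11 µm/s, with the event count matching the Poisson arrival
intensity (134 expected).  The numbered scripts under `analysis/` run
the full set of experiments and write their tables to `results/`:

```sh
python analysis/01_dendritic_transport_wt.py   # WT velocities/frequencies
python analysis/02_mutant_comparison.py        # mutant vs WT, Welch t
python analysis/03_ift_two_segment.py          # middle/distal IFT speeds
python analysis/04_ciliary_fluorescence.py     # 26% z-stack ratio
```

A `ciliatransport` CLI exposes the stages individually
(`simulate`, `register`, `kymo`, `detect`, `stats`, `quantify`, `run`,
`accept`); see `ciliatransport --help`.

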