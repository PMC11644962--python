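# thermoknee

Analysis pipeline for **knee surface-temperature profiles during
sit-to-stand exercise**, combining infrared thermography with a
four-cell balance board.

During repeated sit-to-stand cycles the skin over the medial collateral
ligament region of the knee warms while the patella and patellar tendon
cool, and the amount of warming is linked to how much load each leg
carries. Quantifying this requires (i) extracting per-zone temperature
profiles from a thermal video while the knee moves, (ii) converting the
corner loads of a balance board into per-leg weight shares and a
centre-of-pressure trajectory, and (iii) testing whether two different
temperature-extraction routes agree. `thermoknee` implements all three
stages plus a synthetic-cohort generator with known ground truth, so
every stage is testable end to end.

## What it computes

**Temperature extraction** (`thermoknee.thermal`). Two routes over a
timestamped stack of temperature frames (°C):

* *semi-automatic* — an operator-style rectangular ROI, repositioned
  frame by frame, sampled once every 30 s (20 frames over a 10-min
  exercise), reporting the ROI maximum (ligament region) and minimum
  (patella region);
* *automatic* — temperatures sampled at tracked keypoint coordinates
  (12 knee zones: {R,L} × {SL, SM, P, LJLA, MJLA, PT}) at 1 Hz,
  discarding detections with likelihood < 0.5.

Profiles can be smoothed with a **robust lowess** filter (2 % span,
tricube distance weights × bisquare robustness weights) that removes
outlier spikes while leaving a linear trend untouched.

**Balance board** (`thermoknee.wbb`). From corner loads TL, TR, BL, BR
(kg, 20 Hz): total weight; sit/stand/transition segmentation and cycle
count; per-leg share `left = (TL+BL)/total`; fore/rearfoot shares;
asymmetry flag (one leg > 52 % of load); and the centre of pressure

```
x = (span_x / 2) · ((TR+BR) − (TL+BL)) / total
y = (span_y / 2) · ((TL+TR) − (BL+BR)) / total
```

**Method agreement** (`thermoknee.compare`). The automatic series is
interpolated onto the 20 semi-automatic timestamps, then per region
(left/right ligament, left/right patella): OLS regression with R²,
RMSE about each profile's own linear trend, Bland–Altman bias and
limits of agreement (bias ± 1.96·sd), and AG / NAG / PAG labels —
whether both, neither, or exactly one method finds that the most
thermally responsive leg is the more heavily loaded one. Cohort results
stratify by gender, BMI and weight asymmetry.

**Synthetic cohort** (`thermoknee.synth`). Generates the three data
streams with known ground truth: Gaussian-blob thermal fields riding a
raised-cosine sit-to-stand excursion (0.04 °C sensor noise, 382×288 px,
20 Hz), tracker output with 9.3 px RMS keypoint error and mean
likelihood 0.99, and corner loads with configurable left-leg share,
rearfoot share, and load–warming coupling.

## Worked example

```python
from thermoknee import ParticipantSpec, RunConfig, SyntheticConfig, run_pipeline

synth = SyntheticConfig(duration_s=600.0, left_share=0.53, seed=42)
cfg = RunConfig(
    out_dir="example_run",
    participants=[ParticipantSpec(participant_id="s01", gender="M",
                                  height_cm=178, mass_kg=74.0,
                                  left_share=0.53)],
    synth=synth, seed=42)
result = run_pipeline(cfg)
p = result.report["participants"]["s01"]
```

which prints, for this seed:

```
cycles completed:        170
mean left-leg share:     0.530
rearfoot share:          0.650
asymmetric (>52%):       True (left)
right_ligament  R2=0.873  bias=-0.177 degC  LoA=[-0.351, -0.003]
left_ligament   R2=0.964  bias=-0.171 degC  LoA=[-0.300, -0.043]
right_patella   R2=0.923  bias=+0.145 degC  LoA=[+0.062, +0.227]
left_patella    R2=0.920  bias=+0.141 degC  LoA=[+0.056, +0.226]
agreement (heating):     AG
```

Reading: the participant completed 170 sit-to-stand cycles; the board
recovers the configured 53 % left-leg loading and 65 % rearfoot share
and flags the asymmetry. The two extraction methods correlate strongly
(R² 0.87–0.96) with a small systematic offset (the ROI maximum reads
the blob peak while keypoint sampling is slightly attenuated by tracker
error, and conversely for the minimum), and both identify the heavier
left leg as the one warming fastest (label AG). `example_run/` contains
`report.json`, per-comparison CSV tables and a log;
`thermoknee.make_figures(result)` renders the standard plots.

The same pipeline runs from the command line:

```bash
thermoknee synth --out data/s01 --duration 600 --seed 42 --left-share 0.53
thermoknee run --config run.yaml --figures
```

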