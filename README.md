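# usvloc

Hybrid acoustic localization and emitter assignment of rodent ultrasonic
vocalizations (USVs).

Mice communicate with 30–110 kHz calls, and attributing each call to its
emitter during close social interaction is the bottleneck of vocal-behavior
analysis: snouts are ~10 mm apart, so the localizer must reach millimetre
accuracy. `usvloc` implements a hybrid system that fuses two localizers
with complementary failure modes —

- **Beamforming** on a 64-channel overhead MEMS array: steered-response
  power `P(x,y) = Σ_f |Σ_m S_m(f) e^{i2πf τ_m(x,y)}|²` on a plane 10 mm
  above the platform, scanned coarse (10 mm) then fine (1 mm, 30 × 30 mm
  window), origin = power-weighted centroid, per-call SNR = max/std of the
  coarse field. Precise, but blind above ~95 kHz where the MEMS noise
  floor rises.
- **Four-microphone TDOA (SLIM-style)**: GCC-PHAT time differences per
  microphone pair, each constraining the source to a hyperbola; curves are
  accumulated on a 1 mm grid and the density peak is the origin,
  uncertainty = spread of the >90 %-of-max region. Frequency-agnostic, but
  vulnerable to a single noisy channel.

Per call, each candidate mouse k gets a **Mouse Probability Index**
`MPI_k = P_k / Σ_m P_m` with `P_k = N(origin − mouth_k; σ²)`, σ calibrated
so mean uncertainty matches the far-condition (>100 mm separation)
residual, and `P_k = 0` beyond 50 mm. A method's estimate is *reliable*
when its top MPI exceeds 0.95; one reliable method wins outright, two
reliable methods are split by residual distance. The package also ships a
ground-truthed synthetic-scene generator (moving mice, frequency sweeps
from snout positions, technology-specific sensor noise, independent
recorder clocks with click synchronization), a camera
distortion/pixel-to-world model, and the downstream spatial statistics
(relative polar occurrence maps, bootstrap bin significance, sex
fractions, dominance classification).

It is intended for researchers building or validating multi-microphone
USV-tracking rigs, and for method work that needs a fully controlled,
ground-truthed acoustic scene.

## Worked example

The CLI drives the pipeline over a bundle directory (multichannel WAVs,
pose-track CSV, ground-truth JSON):

```sh
usvloc simulate --out demo --seed 1 --n-usvs 25
usvloc detect   --bundle demo
usvloc localize --bundle demo
usvloc assign   --bundle demo
usvloc analyze  --bundle demo
```

prints

```
bundle written to demo (25 calls, 5.1 s)
25 calls detected
cam64: 25/25 calls localized
slim: 25/25 calls localized
assigned 25/25 calls (100.0%), MAE = 0.30 mm
{
 "per_mouse_counts": {
  "0": 9,
  "1": 16
 },
 "female_fraction": 0.36,
 "n_relative_points": 25
}
```

Reading: all 25 simulated calls were detected on the peripheral
microphones, localized by both methods, and assigned to a mouse with top
MPI > 0.95; the median distance between assigned origins and the true
(snout) sources is 0.30 mm — far below the ~10 mm snout scale, as expected
for an anechoic simulation with exactly known geometry. Mouse 1 (male)
emitted 16 of the calls; 36 % were attributed to the female, which here
simply reflects the simulator's uniform emitter schedule. The same
operations are available as library functions (`usvloc.pipeline.simulate`,
`.run`, `.evaluate`) when you want the intermediate objects.

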