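# chemosearch

Simulation and trajectory analysis of chemically mediated search in small
marine invertebrates — parasitic gnathiid isopods hunting fish hosts and
coral larvae seeking settlement cues — modelled as Braitenberg-style
chemosensing vehicles. The package is aimed at movement ecologists and
modellers who want to (a) simulate deterministic and stochastic
gradient-search agents in configurable signal landscapes and (b) run the
same bout/turning statistics on recorded tracks (5 Hz positional CSV
exports) and on simulations alike.

## Models

An agent has position $(x, y)$ in mm and heading $\theta \in [0, 2\pi)$
against the positive $x$-axis, moving in a signal landscape $S(x,y) \ge 0$.

**Classic (type 3a) vehicle.** Speed is a decreasing response to the local
signal, and the heading relaxes toward the uphill direction:

$$\dot x = F(S)\cos\theta,\qquad \dot y = F(S)\sin\theta,\qquad
\dot\theta = -d\left(-\tfrac{\partial F}{\partial x}\sin\theta
+ \tfrac{\partial F}{\partial y}\cos\theta\right),$$

with $F(S) = a_1\arctan\!\big((b-S)/c_1\big)$, so the agent halts exactly on
the level set $S = b$.

**Gradient-search vehicle.** Speed instead rises with the squared gradient
magnitude, $v = v_0 + G(\|\nabla S\|^2)$ with
$G(s) = a_2\arctan(s/c_2)$, keeping the same steering; the agent seeks
critical points of $S$ and coasts at the background speed $v_0$ where the
landscape is flat.

**Energy-gated rest–run searcher.** A reservoir $E$ drains during motion,
$\dot E = -m\,v^2$. When $E < E_{\min}$ the agent rests for a
$\Gamma(k,\theta)$-distributed time $T_R$, recharges to $E = T_R$, and
resumes in a heading drawn from a Normal (s.d. 1 rad) around the previous
one. Defaults are the values estimated from isopod recordings: rests
$\Gamma(0.127, 16.257)$ (mean 2.06 s), running speed $v_0 = 3.04$ mm/s, and
$m$ calibrated so the mean flat-field run bout is 3.81 s.

**Vigilance searcher (SDE).** A continuously moving agent integrated with
Euler–Maruyama, with Wiener noise on position and heading and a vigilance
variable $r \in [0,1]$ scaling the gradient coupling:

$$d\theta = -r(t)\,d\,(\nabla F(S)\cdot u)\,dt + \sigma_3\,dB_t,\qquad
dr = -\alpha r\,dt,\qquad r(t_k^+) = 1,$$

with renewals $t_k$ from a rate-$\beta$ Poisson process. An optional second,
narrow signal $R$ adds a steering term that is immune to vigilance loss.

**Moving-source pursuit.** Any of the above agents released against a
landscape translating at constant speed $v_1$; the chase succeeds when the
agent enters a 3 mm capture circle around the source. Pursuit succeeds on
most seeds when $v_1 \le v_0$ and fails when $v_1 > v_0$ with the agent
starting behind.

The analysis side mirrors the processing applied to digitised video tracks:
rest/run segmentation at a 0.05 mm/s speed threshold, maximum-likelihood
Gamma fits to resting times, osculating-circle (Menger curvature) turning
radii, and source-approach metrics.

## Worked example

```python
import chemosearch as cs

# simulate an energy-gated searcher in a flat arena for 10 minutes
result = cs.simulate_rest_run(
    cs.linear_field(rate=0.0),            # no chemical signal
    cs.ResponseParams(),                  # a1=b=1, c1=2, a2=1, c2=2
    cs.SteeringParams(d=5.0, v0=3.04),    # running speed 3.04 mm/s
    cs.EnergyParams(),                    # m calibrated from the bout means
    cs.RestModel(),                       # Gamma(k=0.127, theta=16.257) rests
    t_max=600.0, dt=0.01, rng=42)

track = result.trajectory
print(f"simulated {track.duration:.0f} s, {len(track)} samples at 5 Hz")
print(f"mean rest {result.rest_durations.mean():.2f} s, "
      f"mean run {result.run_durations.mean():.2f} s")

cs.write_track(track, "flat_search.csv")
bouts = cs.segment_bouts(cs.read_track("flat_search.csv"), speed_threshold=0.05)
fit = cs.fit_gamma_rests(bouts.rest_durations)
print(f"segmented {len(bouts.rest_durations)} rests / "
      f"{len(bouts.run_durations)} runs from the 5 Hz track")
print(f"Gamma MLE: shape {fit.shape_hat:.3f}, scale {fit.scale_hat:.2f}")
```

prints

```
simulated 600 s, 3001 samples at 5 Hz
mean rest 2.21 s, mean run 4.14 s
segmented 34 rests / 35 runs from the 5 Hz track
Gamma MLE: shape 0.777, scale 7.18
```

The simulator's internal bout log (94 completed cycles, means near the
2.06 s / 3.81 s calibration targets) is exact, while the 5 Hz track analysis
recovers only 34 rests with a much larger fitted shape: with a shape
parameter as small as 0.127 most resting bouts are shorter than one 0.2 s
sampling interval and are invisible at video frame rates. This resolution
effect is intrinsic to threshold segmentation of heavy-tailed bout
distributions (see `docs/methods.md`), and is why parameter-recovery checks
use bout scales the sampling rate can resolve.

A command-line interface exposes the same functionality:

```
chemosearch simulate --preset restrun --seed 7 --out track.csv
chemosearch analyze track.csv --threshold 0.05 --source 0 20
chemosearch pursue --preset pursuit --v1 2.736 --n-seeds 100 --out pursuit.json
chemosearch make-fixture --kind rest_run --seed 1 --duration 600 --out fix.csv
```

Every command writes a `*.manifest.json` recording the configuration, seed
and package version needed to reproduce the run.

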