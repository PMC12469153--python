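# Methods

This note documents the models implemented in `chemosearch`, the parameter
choices that matter, the numerical schemes, and the design decisions taken
where more than one defensible choice existed.

## Vehicle models

All agents live on the unbounded plane (an optional rectangular arena with
reflecting walls is available via the `arena` argument), with lengths in mm,
times in s and angles in radians. The state is position $(x, y)$, heading
$\theta$ (wrapped into $[0, 2\pi)$ after every step), and, depending on the
model, an energy reservoir $E \ge 0$ and a vigilance $r \in [0, 1]$.

### Response functions

* $F(S) = a_1 \arctan((b - S)/c_1)$ — speed of the classic type-3a vehicle.
  $a_1$ sets the speed far below the target level $b$; $c_1$ the width of
  the velocity transition. $F$ is strictly decreasing and crosses zero
  exactly at $S = b$, so the level set $S = b$ is invariant.
* $G(s) = a_2 \arctan(s/c_2)$ applied to $s = \|\nabla S\|^2$ — the
  gradient-driven speed of the search vehicle, with a background speed
  $v_0$ added so the agent never stalls in flat regions.

An important practical consequence of the arctan form: the steering gain is
proportional to $F'(S) = -a_1 / (c_1 (1 + ((b-S)/c_1)^2))$, which collapses
when $S \gg b$. Landscapes whose amplitude is far above the target level
render the agent nearly blind close to the source. The scenario presets
therefore keep landscape amplitudes within an order of magnitude of $b$.

### Steering convention

The heading equation couples $\nabla F(S) = F'(S)\,\nabla S$ (chain rule,
analytic) to the heading through the perpendicular projection
$-\partial_x F \sin\theta + \partial_y F \cos\theta = \nabla F \cdot
(-\sin\theta, \cos\theta)$, with the ipsilateral sign making the uphill
direction the stable heading equilibrium for a decreasing $F$. This is the
default for *all* models. A heading-parallel variant
(`SteeringParams(coupling="parallel")`, coupling $\nabla F \cdot
(\cos\theta, \sin\theta)$) is retained for model comparison; analysis and
simulation show it steers the agent along level sets (its stable heading is
tangential, tilted slightly downhill), producing drift *perpendicular* to
the gradient in a linear landscape and escape-to-infinity on radial hills —
behaviour inconsistent with gradient search, which is why it is not the
default. Gradients with norm below $10^{-12}$ are treated as exactly zero so
numerical noise at the resolution limit cannot be amplified into turning.

In the level-set demonstration (Gaussian landscape $1.2\,e^{-(x^2+y^2)/2}$,
$a_1 = b = 1$, $c_1 = 2$, $d = 5$), the six standard initial conditions are
$x_0 \in \{1.3, 1.7, 2.1\}$, $y_0 = 0$, with headings tilted by $\pi/4$ and
$\pi/8$ *against* the positive $x$-axis, i.e. $\theta_0 \in \{3\pi/4,
7\pi/8\}$. With these headings all six trajectories terminate on the
$S = 1$ circle (radius $\sqrt{2\ln 1.2} \approx 0.604$ mm) by $t = 200$ s;
with outward headings $\{\pi/4, \pi/8\}$ three of the six escape the
gradient's reach before turning, for any integrator (verified against
`scipy.solve_ivp` at tolerance $10^{-10}$).

### Energy-gated rest–run layer

During runs the agent follows the gradient-search dynamics while
$\dot E = -m v^2$. When $E$ drops below $E_{\min}$ (default 0) it rests for
$T_R \sim \Gamma(k, \theta)$, recharges to $E = T_R$ (recharge rate 1),
keeps its position, and restarts with heading
$\mathcal N(\theta_{\text{prev}}, 1)$ wrapped. Defaults $k = 0.127$,
$\theta = 16.257$ s (mean rest 2.06 s) and $v_0 = 3.04$ mm/s are the values
estimated from the isopod recordings.

The depletion constant $m$ is not directly observable. It is calibrated so
that, in a flat landscape, the expected run duration
$\mathbb E[T_R]/(m v_0^2)$ matches the observed 3.81 s mean run:
$m = 2.06/(3.81 \cdot 3.04^2) \approx 0.0585$. The initial reservoir is
drawn as one Gamma resting time, making the first run statistically
identical to later ones. With these defaults the run-time distribution is
an emergent, scaled copy of the rest-time distribution — strongly
right-skewed, with most bouts far shorter than the mean.

### Vigilance SDE

The continuous searcher follows, in Euler–Maruyama form with step $dt$,

* $dx = (v_0 + G)\cos\theta\,dt + \sigma_1 dB^1$, similarly for $y$ with
  $\sigma_2$;
* $d\theta = -r\,d\,(\nabla F(S)\cdot u)\,dt + \sigma_3 dB^3$ with $u$ the
  steering direction above;
* $dr = -\alpha r\,dt$ between renewals; at the epochs of a rate-$\beta$
  Poisson process $r$ is reset to 1 (a renewal falling inside a step is
  applied at the end of that step, an $O(dt)$ approximation).

Each Wiener increment is $\mathcal N(0, dt)$. With all $\sigma = 0$ a step
is bit-for-bit one explicit-Euler step of the deterministic system.
Defaults $\alpha = 0.5$ s$^{-1}$ and $\beta = 1$ s$^{-1}$ give a mean
vigilance of $\beta/(\alpha+\beta) = 2/3$.

With a second signal $R$ the heading drift becomes
$-d\,((r \nabla F(S) + \nabla F(R)) \cdot u)$: the response to the
close-range cue is *not* scaled by vigilance, which is what retains the
agent near the source after interest in the broad signal has decayed.

### Pursuit scenario

A static base landscape is translated so its centre moves from
$(x_0, 20\,\text{mm})$ rightward at $v_1$ (centre at $x_0 + v_1 t$; the
alternative sign convention placing it at $v_1 t - x_0$ is available via
`literal=True`). The agent starts at the origin with a random heading;
capture means coming within 3 mm of the source centre. During rest phases
the agent is stationary and the source moves, so the first crossing of the
capture circle is found in closed form from the quadratic
distance-versus-time function rather than by stepping.

The default pursuing agent is the *continuous* vigilance searcher. The
rest–run searcher spends only $3.81/(2.06+3.81) \approx 65\%$ of its time
moving, so its sustained speed is $\approx 0.65 v_0$ and it cannot hold a
chase at $v_1 = 0.9 v_0$; a parameter sweep confirmed at most ~20 % success
for any tested landscape and turn gain. The continuous agent's signal-free
speed is exactly $v_0$, matching the intended reading of "success when
$v_1 \le v_0$"; with the preset below it succeeds on ~87 % of seeds at
$v_1 = 0.9 v_0$ and on 0 % when starting behind a source at
$v_1 = 1.1 v_0$. The rest–run agent remains selectable
(`PursuitConfig(agent="rest_run")`).

## Scenario presets

Landscape amplitudes and scales for the multi-peak, larva, dual-signal and
pursuit scenarios are not pinned by any recording; the presets fix one
documented choice each (all validated to realise the intended qualitative
regime, then frozen):

| preset | landscape | key parameters |
|---|---|---|
| `levelset` | Gaussian, amplitude 1.2, scale 1 | $a_1=b=1$, $c_1=2$, $d=5$, $v_0=0$ |
| `restrun` | flat | $v_0=3.04$, rests $\Gamma(0.127, 16.257)$ |
| `multipeak` | 4 Gaussian peaks, amplitudes 0.8–1.2, scales 4–6 mm | as `restrun`, $d=0.5$ |
| `larva` | Gaussian, amplitude 8, scale 20 mm | $a_1=a_2=100$, $b=1$, $c_1=c_2=2$, $d=2$, $\sigma_1=\sigma_2=5$, $\sigma_3=1$, $v_0=0.15$ |
| `dual_signal` | broad Gaussian (8, 50 mm) + narrow (16, 15 mm) | as `larva`; $R \ge S$ within $\approx 18.5$ mm of the source |
| `pursuit` | Gaussian, amplitude 3, scale 20 mm | $a_1=b=1$, $c_1=2$, $d=20$, $v_0=3.04$, $\sigma_{1,2,3}=0.2$, capture 3 mm, $t_{\max}=300$ s |

The larva/dual amplitudes (8–16) keep the signal within the sensitive range
of the arctan response where its derivative — and hence the steering gain,
which for those presets is amplified by $a_1 = 100$ — remains large along
the whole approach.

## Trajectory statistics

* **Speeds** are central finite differences at interior samples, one-sided
  at the ends (exact for uniform straight motion).
* **Segmentation**: a sample rests iff its speed is strictly below the
  threshold (default 0.05 mm/s; equality counts as running). A bout of $n$
  samples is assigned duration $n$ sampling intervals, so a single-sample
  bout lasts one interval; any consistent convention shifts durations by at
  most one interval. The leading and trailing bouts are censored by the
  recording window and can be dropped (`drop_partial`).
* **Resolution caveat**: central differencing blurs each rest/run boundary
  by about one sample, and bouts shorter than the sampling interval are
  invisible. At 5 Hz this is immaterial for bouts of several seconds but
  severely truncates a $\Gamma(0.127, \cdot)$ bout distribution, whose
  median is far below 0.2 s — which is why recovered shape parameters from
  frame-rate tracks are biased upward, and why the parameter-recovery tests
  use bout scales (shape 2, scale 5 s) the sampling rate can resolve. At
  those scales the full chain (generate → write → read → segment → fit)
  recovers shape, scale and running speed within 10 % at $10^4$ bouts.
* **Gamma fits** are maximum likelihood with the location fixed at zero
  (`scipy.stats.gamma.fit(floc=0)`); a closed-form method-of-moments
  estimator is provided as an independent cross-check. Expected histogram
  counts are $n\,(\mathrm{CDF}(r) - \mathrm{CDF}(l))$ per bin.
* **Turning radii**: per-sample curvature is the Menger (circumscribed
  circle) curvature of three consecutive positions, $\kappa = 4A/(abc)$;
  collinear triples have $\kappa = 0$ (infinite radius) and are never
  candidates. Turning points are local curvature maxima (plateaus included)
  at or above a percentile threshold (default 90) of the positive
  curvatures; radii are $1/\kappa$. On noiseless circles the construction
  is exact. On noisy tracks the curvature estimate is reliable only when
  the sagitta of each three-point arc is well above the noise s.d.; the
  fixture used in validation (radius 5 mm, 0.8 rad per sample, noise
  0.01 mm) recovers the radius within 2 %.
* **Approach metrics**: initial/final/minimum distance to a fixed source,
  time spent within a capture radius (sample count × interval), and a
  final-closer-than-initial flag.

## Synthetic fixtures

`make_rest_run_track` is deliberately *kinematic*: positions are written
directly from drawn bout sequences (straight runs at $v_0$, stationary
rests, Normal heading kicks), bypassing the ODE/SDE machinery, so analysis
tests cannot be fooled by a bug shared with the simulators. Run durations
mirror the energy mechanism by scaling the preceding rest with
`run_ratio` (default 3.81/2.06). The generator returns exact bout
boundaries for oracle comparisons and is bit-reproducible from its seed.
Geometric fixtures (lines, circles, arcs, plus optional isotropic Gaussian
position noise) provide closed-form oracles for the speed and curvature
estimators. What these fixtures do not emulate: measurement noise of real
video tracking, arena walls and occlusion, gradual speed changes within
runs, and any coupling between heading and signal — so passing analysis
tests demonstrates correctness of the estimators, not fidelity of the
behavioural model to real animals.

## Numerics and reproducibility

* Deterministic phases (classic/gradient vehicles, rest-run run phases) use
  fixed-step RK4 at $dt = 0.01$ s (configurable); the energy reservoir is
  updated with explicit Euler at the same step, so rests trigger within one
  step of the threshold crossing and a run bout's duration is its step
  count times $dt$.
* The SDE uses Euler–Maruyama at $dt = 0.01$ s; vigilance decay is exact to
  $O(dt)$ (relative error $\approx \alpha\,dt/2$ against $e^{-\alpha t}$).
* Every simulation takes one integer seed (or `numpy` generator) and spawns
  deterministic substreams per stochastic component (rest times,
  reorientations, Wiener increments, renewal epochs), so switching one
  component off does not perturb the draws of the others. Identical seed
  and configuration give bit-identical trajectories.
* Track files are written with 9 significant digits; read∘write is the
  identity on retained channels to that precision.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at desk scale: level-set
integrations to $t = 200$ s at $dt = 0.01$; 10,000–30,000 rest–run cycles
for bout-mean estimates (Monte-Carlo s.e. of the mean run $\approx$
0.06–0.11 s, dominated by the heavy-tailed rest distribution); 100 seeds
per pursuit regime; 100 paired seeds for the biased/unbiased walk; 30
paired seeds for dual-signal containment; $10^4$ bouts for parameter
recovery; $10^5$–$10^6$ draws for distribution checks.

## Known limitations

* Two-dimensional motion only; no vertical component.
* No inference of model parameters from data beyond the Gamma bout fit —
  the simulators are forward-only.
* The chemical landscapes are idealised Gaussians/ramps; no
  advection–diffusion plume structure, and no attempt to reconstruct the
  flow field of a real olfactometer.
* Boundary behaviour is an idealisation (unbounded plane or perfectly
  reflecting rectangle).
* The heading-parallel steering variant is provided for comparison but has
  no validated behavioural regime.
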