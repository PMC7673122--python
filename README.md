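# obcode

Odor coding in the mouse olfactory bulb: how a small population of young
adult-born granule cells (abGCs) sharpens mitral-cell (MC) odor tuning and
improves population odor discrimination.

The package is aimed at systems neuroscientists analyzing paired
before/after two-photon calcium-imaging experiments (e.g. chemogenetic
silencing of an interneuron population) and at modellers studying
inhibition-mediated tuning in recurrent circuits. It provides:

- **Trace analysis** (`obcode.traces`) — dF/F against a 5–2 s pre-stimulus
  baseline, span-5 moving-average smoothing, response detection by an
  effect-size statistic

  ```
  ES = (mean(S_resp) − mean(S_base)) / mean(sd(S_resp), sd(S_base))
  ```

  computed on 7-point windows around the response-window extremum and a
  matching pre-stimulus extremum, with |ES| > 5 marking a significant
  excited or suppressed response; 0–5 s response-magnitude integrals;
  exact 252-partition permutation tests on 5+5 per-trial means; per-cell
  tuning curves and a population sharpening ratio with confidence borders
  (Avg ± SEM)_before / (Avg ∓ SEM)_after; and a background-relative
  baseline-activity shift estimate.
- **Population discrimination** (`obcode.discrimination`) — pairwise
  population d′ in the n_cells-dimensional response space,

  ```
  d′ = ‖mean(p) − mean(q)‖ / mean(inner_p, inner_q)
  ```

  (inner distances = mean trial distance from the odor centroid), the
  discrimination change index DCI = (d′_after − d′_before)/(d′_after +
  d′_before), cell-count-weighted cross-animal aggregation, and a
  one-sample test of the DCI entries against zero.
- **Circuit model** (`obcode.network`) — a linear firing-rate MC/GC/abGC
  network on a ring with Gaussian distance-dependent connectivity
  J_ij = J exp(−d(θ_i, θ_j)²/2σ²), abGCs distinguished by broader input
  connectivity (b) and higher gain (g), solved as a single linear system;
  its closed-form reduction to (J_eff, g_eff = b·g, f) with tuning and
  sharpening formulas, silencing experiments, and inversion of the
  sharpening relation for g_eff.
- **Coding efficiency** (`obcode.chernoff`) — the closed-form Chernoff
  distance between Poisson spike-count distributions, the expected per-MC
  discriminability (I₁²/4I₀)(1 + J_eff(1 + (g_eff − 1)f)), and the
  iso-discrimination curve trading MC count against abGC fraction, with
  half-benefit fraction f_half = 1/(2 + ρ), ρ = J_eff(g_eff − 1)/(1 + J_eff).
- **Synthetic data** (`obcode.synth`) — paired before/after imaging
  sessions (7 Hz, 2-s stimuli, 11 odors × 5 trials) with known ground
  truth: double-exponential transients of either sign, per-frame noise, a
  condition-dependent quenching factor, and an optional baseline shift.
- **I/O and CLI** (`obcode.io`, `obcode.cli`) — a plain-text session format
  (`session.json` + `traces.csv`), YAML/JSON run configuration, and an
  `obcode` command with `synth`, `analyze`, `dprime`, `model`, `iso`, and
  `run` subcommands.

## Worked example

```python
from obcode import (NetworkParams, effective_params, iso_discrimination,
                    asymptotic_geff)
from obcode.synth import SynthConfig, generate_session_pair
from obcode.traces import session_tuning, estimate_sharpening

params = NetworkParams()          # 500 MCs, 19,500 GCs + 500 abGCs (f = 0.025)
eff = effective_params(params)
print(f"J_eff = {eff.j_eff:.3f}   g_eff = {eff.g_eff:.0f}   f = {eff.f}")
print(f"Sharpening_abGCs = {eff.sharpening_abgcs:.4f}")
print(f"asymptotic g_eff = {asymptotic_geff(eff.sharpening_abgcs, eff.f):.2f}")
curve = iso_discrimination(params)
print(f"f_half = {100 * curve.f_half:.2f}%   rho = {curve.rho:.2f}")

cfg = SynthConfig(n_cells=40, quench_factor=0.5, noise_sd=0.02, seed=1)
before, after, _ = generate_session_pair(cfg)
est = estimate_sharpening(session_tuning(before), session_tuning(after))
print(f"recovered sharpening = {est.sharpening:.3f}  "
      f"ci = ({est.ci_low:.3f}, {est.ci_high:.3f})")
```

prints

```
J_eff = 3.979   g_eff = 15   f = 0.025
Sharpening_abGCs = 1.3058
asymptotic g_eff = 11.93
f_half = 7.58%   rho = 11.19
recovered sharpening = 1.996  ci = (1.880, 2.119)
```

Reading the numbers: with peak connectivity 10 and width 0.5 rad the mean
MC↔GC loop strength is J_eff ≈ 3.98; abGCs with threefold-broader input and
fivefold gain have efficacy g_eff = 15. At 2.5% of the granule population
they sharpen MC tuning by a factor 1.306, and holding that sharpening fixed
while letting lateral inhibition grow without bound still requires
g_eff ≈ 12 — young granule cells must be substantially more effective than
mature ones no matter the inhibition strength. The iso-discrimination curve
reaches half of the achievable MC-count saving when abGCs are ≈7.6% of the
granule population, close to physiological turnover. The last two lines run
the full imaging pipeline on a synthetic experiment whose response
amplitudes were halved ("quenched") in the second condition: the estimated
sharpening ratio recovers the true factor 2 inside its confidence interval.

The same stages are available from the shell, e.g.:

```sh
obcode iso --out runs/iso            # writes iso_discrimination.csv + summary
obcode run --seed 1 --out runs/demo  # synthetic session -> full pipeline
```

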