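# nocidepth

Inference of the **depth** and **threshold temperature** of heat-sensitive
C-fiber nociceptor endings in skin, from the first-spike latencies they fire
under ramped heat stimulation.

## The problem

The temperature that actually activates a nociceptor's membrane cannot be
measured: the ending sits somewhere below the skin surface, and skin is an
imperfect heat conductor, so the membrane sees an attenuated, delayed version
of the surface stimulus.  Given a few stimuli with different ramp rates and
the latency of the first action potential to each (conduction-corrected),
both the receptor depth and its firing threshold can in principle be read off
a heat-conduction model of skin.  `nocidepth` implements three estimators of
increasing robustness:

1. **Classical intersection method.**  Treating skin as a semi-infinite
   homogeneous solid at baseline temperature T₀, the temperature at
   normalized depth γ = x/(2√α) (α = k/(ρc) the thermal diffusivity) under
   surface temperature T_s is the first-order (Henriques) solution

   T(γ, t) = T₀ + (T_s − T₀)·erfc(γ/√t).

   Each stimulus's latency τᵢ defines a curve of consistent (γ, T_threshold)
   pairs; the curves' common intersection is the estimate.  The outcome is
   classified as `single`, `triangle`, `partial`, or `none`.

2. **Delay-model maximum likelihood.**  Real first spikes lag the threshold
   crossing: τᵢ = t*ᵢ(T, γ) + Δᵢ with Δᵢ ≥ 0 exponentially distributed
   (rate λ, default 1).  The log likelihood Σᵢ[log λ − λΔᵢ] is maximized
   jointly over (T, γ) inside the feasible region (all Δᵢ ≥ 0); in the
   zero-delay limit this reproduces the classical solution.

3. **Evidence-based outlier rejection.**  A first spike may be a spontaneous
   discharge rather than a response.  The full model M₁ is compared against
   exclusion models M₂,ᵢ (stimulus i's spike is a Poisson-process event with
   rate λ_s) by marginal likelihood, integrating the likelihood against a
   Normal(38, 2) °C threshold prior and a Gaussian-mixture approximation of
   the γ prior induced by a Beta(4.75, 2.25) depth prior and uniform thermal
   parameters.  Evidences are normalized to weights summing to 1; the
   maximum wins, and the normalized full-model weight flags outliers.

A ground-truth simulator of the whole experiment (3 ramps 32→48 °C over
16/4/2 s with a 10 s hold, exponential delays, spontaneous outlier spikes)
makes every estimator testable by parameter recovery.

## Worked example

A receptor 0.3 mm deep with a 38.8 °C threshold, probed with four constant
supra-threshold surface temperatures:

```python
import numpy as np
import nocidepth as nd

skin = nd.MIDPOINT_SKIN                      # k=0.095, rho=1158, c=825
alpha = skin.alpha_eff()                     # 9.944e-08 m^2/s
gamma = nd.gamma_from_depth(0.3, alpha)      # 0.4757 s^1/2

traces = [nd.StimulusTrace.step(32.0, Ts, 30.0) for Ts in (43, 45, 47, 49)]
latencies = [nd.threshold_time(38.8, 32.0, gamma, tr) for tr in traces]
# [1.8216, 1.1096, 0.8048, 0.6389] seconds

rec = nd.Recording(traces=tuple(traces), latencies=np.array(latencies),
                   T0=32.0, neuron_id="example")
est = nd.classify_and_estimate(rec, alpha_eff=alpha)
print(est.status, round(est.T_threshold, 2), round(est.D, 4))
# single 38.8 0.3

mle = nd.mle_fit(rec)
print(round(mle.T_threshold, 2), np.round(mle.delays.delays, 6))
# 38.8 [0. 0. 0. 0.]
```

All four consistency curves intersect in one point at the generating
parameters (`status == "single"`), and the delay-model MLE reproduces the
classical estimate with vanishing delays, as it must in the noise-free limit.

## Command line

```
nocidepth simulate --n-neurons 4 --outlier-fraction 0.25 -o sims/
nocidepth fit-classical sims/neuron_000 -o classical.json
nocidepth fit-mle       sims/neuron_000 --lambda 1.0 -o mle.json
nocidepth select-model  sims/neuron_000 -o evidence.json
nocidepth run-all       sims/neuron_000 -o report.json
```

Recording bundles are a `manifest.json` plus one `time_s,temp_C` CSV per
stimulus; all results are JSON and embed the effective configuration hash.

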