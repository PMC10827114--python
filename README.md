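# lpa — Laminar Population Analysis

Joint decomposition of multi-unit activity (MUA) and local field potential /
current source density (LFP/CSD) recorded on a laminar probe into
per-population spatial profiles, firing-rate temporal profiles, synaptic
kernels, and per-population CSD contributions.

Extracellular recordings across cortical depth mix the signals of many
neural populations: the high-frequency band (MUA) reflects nearby spiking,
while the low-frequency band (LFP) and the current source density (CSD)
derived from it reflect synaptic input whose origin — feedforward,
recurrent, feedback — is not visible in the raw signal. Statistical
decompositions (PCA, ICA) separate these sources only when their
orthogonality or independence assumptions hold. LPA instead uses a
physiological assumption: the CSD is generated by the firing of presynaptic
populations, so the MUA-derived population firing rates, convolved with
causal synaptic kernels, form the temporal basis for decomposing the CSD.
The package targets electrophysiologists working with laminar probe
(e.g. Neuropixels) recordings in layered structures such as visual cortex.

## The model

Stage 1 decomposes the trial-averaged MUA bilinearly,

    φ_M(z_i, t_j) ≈ Σ_n M_n(z_i) r_n(t_j),

with the spatial profiles M_n constrained to non-overlapping height-1
trapezoids (position z, plateau width a, ramp width b) — each trapezoid
marks one laminar population and delineates its layer. Given profiles, the
rates are the least-squares solution r = pinv(Mᵀ)φ_M; the trapezoid
parameters are fitted by differential evolution on the relative MSE.

Stages 2–4 convolve presynaptic rates (internal populations, plus external
structures appended as extra rows) with causal exponential kernels
h_n(t) = (1/τ_n)e^{−(t−Δ_n)/τ_n}Θ(t−Δ_n), estimate spatial CSD profiles by
least squares, L = C·pinv(h⊛r), and optimize the kernel parameters {τ_n, Δ_n}
under the penalized cost

    e_C = relMSE(C, C_est) + λ·(1/B)Σ_j |Σ_i C_est(z_i, t_j)|,

whose second term discourages a net monopole moment in the reconstruction
(the delta iCSD method, unlike the traditional second-derivative CSD, does
not force the channel sum to zero). The reconstruction factors exactly into
per-population CSD contributions L_n·R_n.

Also included: delta iCSD (forward and inverse), Butterworth band splitting
and MUA envelope extraction, spike-train rate estimation, layer
classification scoring (confusion matrix, precision/recall/F1), PCA/ICA
baselines, a synthetic forward generator with full ground truth, and a CLI.

## Worked example

```python
import numpy as np
from lpa import MUAModel, CSDModel
from lpa.synthetic import SyntheticConfig, generate

# a flash-evoked laminar recording with known ground truth
ds = generate(SyntheticConfig(), seed=42)

# stage 1: decompose the MUA into 5 laminar populations
mua_fit = MUAModel(ds.mua, n_populations=5).fit(seed=0)
print(mua_fit.summary().round(1))
print(f"MUA relative MSE: {mua_fit.e_m:.4f}")

# stages 2-4: decompose the CSD using the presynaptic rates
csd_fit = CSDModel(ds.csd, ds.rates).fit(seed=0)
print(csd_fit.summary().round(2))
print(f"CSD relative MSE: {csd_fit.relative_mse:.4f}, "
      f"correlation: {csd_fit.correlation:.3f}")
```

prints

```
      center_um  top_um  slope_um  support_lo_um  support_hi_um  peak_rate
pop0       60.9    56.8      24.2            8.3          113.5       30.1
pop1      208.1   157.5       0.1          129.2          286.9       20.5
pop2      389.2   119.4      29.3          300.2          478.1       34.4
pop3      586.7   180.9      18.1          478.2          695.2       20.7
pop4      855.1   202.5      44.9          708.9         1001.3       26.0
MUA relative MSE: 0.0090
      tau_ms  delta_ms  contribution_rms
pop0   21.75      4.26              2.91
pop1   21.92      7.53              3.28
pop2   12.89      3.80              3.50
pop3   20.97      6.67              3.51
pop4    7.04      4.37              2.92
CSD relative MSE: 0.0098, correlation: 0.995
```

The five trapezoids tile the probe depth — their supports delineate the
five layers (the generator's true layer boundaries lie at 115, 300, 475 and
705 µm, each within a few micrometres of a fitted support edge). The MUA
relative MSE of 0.009 means the two-factor model explains 99% of the MUA
energy at noise SNR 10. In the CSD stage the fitted kernel time constants
and delays (per population, in milliseconds) reproduce the generating
kernels, and the summed per-population contributions reconstruct the CSD at
correlation 0.995. `mua_fit.assign_layers(...)`, `csd_fit.contributions`
and `lpa.lambda_sweep(...)` expose layer labels, per-population CSD, and
the penalty-weight sweep.

The same pipeline is available from the shell:

```sh
lpa simulate --seed 0 sim.h5
lpa icsd --radius-um 400 --sigma 0.3 sim.h5 csd.h5
lpa fit-mua --npop 5 --seed 0 sim.h5 mua_fit.h5
lpa fit-csd --lam 4 --seed 0 sim.h5 sim.h5 csd_fit.h5
lpa sweep-lambda --grid 0:8:1 sim.h5 sim.h5 sweep.csv
lpa baseline --method pca -k 4 sim.h5 pca.h5
```

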