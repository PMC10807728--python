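# siftersim

Signal theory, simulation and background correction for **SIFTER**
(single-frequency technique for refocusing dipolar couplings), a four-pulse
pulsed dipolar EPR experiment that measures nanometre distance distributions
between S = 1/2 spin labels.

## The problem

A SIFTER trace V(t), recorded on the time axis t = τ1 − τ2 at fixed total
evolution time 2τ0, mixes the wanted intramolecular dipolar modulation
("form factor" F(t) = ⟨cos ω_dd t⟩, with ω_dd ∝ (1 − 3cos²θ)/r³) with
intermolecular background from the randomly distributed surrounding spins
and with relaxation filtering by the nuclear bath.  Unlike in DEER, the
background is not a single multiplicative factor.  For a biradical sample
with modulation depth λ the signal composes as

    V = (1−λ)·V_nm + λ·[ F(t)·(BS + Bt·Bt)/2 + F(τ1)F(τ2)·Dτ1τ2·Bt·Bt ]
    V_nm = BS + Dτ1τ2·Bt·Bt + λ/(2(1−λ))·K·(BS − Bt·Bt)

where Bt(τ) is the two-pulse (Hahn) echo decay, BS(τ1, τ2) the
fixed-total-time refocused-echo (SIDRE) surface, Dτ1τ2 the intermolecular
coherence-transfer factor (D = ⟨Σω_n²⟩) and K = ⟨cos ω_dd τ0⟩ a constant of
the trace.  Correct form-factor extraction therefore requires **fitting and
subtracting** the unmodulated part V_nm, then **dividing** by
(BS + Bt·Bt)/2 — not the heuristic division of V by the SIDRE trace, which
distorts the modulation by (1 + Bt·Bt/BS)/2 whenever dynamical decoupling
makes BS decay slower than Bt·Bt.

`siftersim` implements, with tests against exact density-matrix propagation
and closed-form integrals:

* `quantum_core` — exact propagation of ≤ 10-spin networks through ideal
  SIFTER/SIDRE/Hahn sequences (the package's oracle);
* `dipolar_model` — ω_dd, powder form factor, sine-product kernel, fixed-sum
  constant;
* `ensemble_mc` — Monte-Carlo mono-/biradical ensembles: B2p background,
  summed second moment D, factorization-assumption check;
* `relaxation_models` — SSE Hahn decays Bt and the SIDRE surface BS with a
  decoupling exponent ξ; decay fitting;
* `signal_composition` — assembly of complete mono-/biradical signals;
* `background_pipeline` — the fit–subtract–divide correction, the heuristic
  SIDRE division for comparison, Gaussian distance recovery;
* `synthetic_data_io` — seeded synthetic studies, ASCII trace I/O, CLI.

## Worked example

```python
import numpy as np
from siftersim.synthetic_data_io import SampleSpec, StudyConfig, generate_study
from siftersim.background_pipeline import correct_proposed, recover_gaussian_distribution

# one biradical sample: r = 3.0 +- 0.2 nm, modulation depth 0.3, SNR 50
cfg = StudyConfig(samples=(SampleSpec(name="demo", kind="bi"),),
                  tau0_list_us=(2.5,), snr=50.0, master_seed=7)
entry = generate_study(cfg).entries[0]          # SIFTER + SIDRE + Hahn traces

result = correct_proposed(entry.sifter, entry.sidre, hahn=entry.hahn)
r_mean, r_sigma, _ = recover_gaussian_distribution(result)
print(f"lambda = {result.params.lam:.3f}")
print(f"r_mean = {r_mean:.3f} nm, r_sigma = {r_sigma:.3f} nm")
```

Output:

```
lambda = 0.299
r_mean = 3.003 nm, r_sigma = 0.173 nm
```

The pipeline fitted the unmodulated part of the noisy trace, subtracted it,
divided by the main-term background and fitted a Gaussian distance
distribution through the powder kernel: the ground truth (λ = 0.3,
r̄ = 3.0 nm, σ = 0.2 nm) is recovered within the noise.

The same pipeline is available from the shell:

```bash
siftersim simulate --out study/ --seed 7
siftersim correct --sifter study/nitroxide_bi_tau0_2.5_sifter.dat \
                  --sidre  study/nitroxide_bi_tau0_2.5_sidre.dat \
                  --hahn   study/nitroxide_bi_tau0_2.5_hahn.dat \
                  --out formfactor.dat
siftersim validate --seed 7
siftersim oracle-check
```

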