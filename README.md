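# dmsapk — pediatric ⁹⁹ᵐTc-DMSA renal pharmacokinetics

⁹⁹ᵐTc-dimercaptosuccinic acid (DMSA) is among the most common pediatric
nuclear-medicine agents, yet the biokinetic model behind its dose estimates
is adult data from the 1970s. `dmsapk` is a tested re-implementation of a
pediatric kidney pharmacokinetics analysis built on modern quantitative
imaging: it simulates SPECT/planar acquisitions of a digital two-kidney
phantom, quantifies fractional kidney uptake with OS-EM reconstruction
(attenuation, scatter and collimator-response compensation), fits the ICRP
sum-of-exponentials model to time–activity data, computes decay-weighted
time-integrated activity coefficients (TIAC), and runs the median-regression
covariate analysis of uptake versus age, weight and sex. It is intended for
internal-dosimetry and quantitative-imaging researchers who need a fully
synthetic, end-to-end testable version of this pipeline.

## The model

Kidney activity as a fraction of the administered activity A₀ follows

    A_s(t) / A₀ = F_S · Σᵢ aᵢ · exp(−ln2 · t / Tᵢ)

with F_S the fractional distribution to the kidneys, each (aᵢ, Tᵢ) a kinetic
component with biological half-time Tᵢ (a negative aᵢ is the uptake phase;
Tᵢ → ∞ is trapped tracer). For pediatric DMSA the identifiable form fixes
a₁ = −1 and T₂ = ∞, leaving F_S, T₁, a₂ free. Weighting by physical decay
(half-life T_p = 6.0 h) and integrating gives the TIAC in closed form:

    TIAC = F_S · Σᵢ aᵢ / (λᵢ + λ_p),   λ = ln2 / T   [hours]

The adult reference parameters (F_S = 0.5, −1 @ 1.0 h, +1 @ ∞) give
3.71 h; the pediatric parameters (F_S = 0.3, −1 @ 1.1 h, +1.2 @ ∞) give
2.71 h — a 27% reduction with direct consequences for pediatric
absorbed-dose estimates.

## Worked example

```
$ python examples/03_fit_biokinetics_and_tiac.py
fit over 23 bins: F_S = 0.304 +/- 0.070, T1 = 0.80 +/- 0.40 h, a2 = 1.20 +/- 0.31
TIAC of the fitted model: 2.86 +/- 0.28 h
        model  F_S  T1_h  T2_h   a1  a2   tiac_h  pct_diff_vs_ref
       icrp53  0.5   1.0   inf -1.0 1.0 3.709787                0
        evans  0.4   1.0   7.0 -1.0 1.0 1.369768              -63
current_study  0.3   1.1   inf -1.0 1.2 2.713892              -27
```

The fit runs on the packaged 10-minute-binned cohort uptake table (23 bins,
97 measurements from 77 patients) and recovers the published pediatric
parameters within their standard errors. The comparison table evaluates each
published parameter set's TIAC in closed form; the percent column is the
difference against the adult reference — the pediatric row is the 27%
reduction. (The `evans` row reports the closed form of that study's printed
parameters as-is; its printed TIAC is not reproducible from them, a known
discrepancy the table surfaces rather than hides.)

The other examples cover phantom simulation (`01`), full SPECT
quantification with true and scatter-window-derived attenuation maps (`02`),
cohort median regression (`04`), and hybrid planar–SPECT calibration of a
second time point (`05`). A thin CLI wraps the same functions:
`dmsapk simulate | reconstruct | quantify | fit-pk | tiac | compare-models |
regress | report | reproduce-paper`.

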