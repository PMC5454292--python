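# snorhythm

Bayesian detection of circadian rhythms in replicated expression time
courses, with the population analyses needed to study small nucleolar
RNAs (snoRNA): host-gene abundance ratios, expressed/identifiable calls,
and enrichment of anticorrelation between rRNA-modifying snoRNA and their
target rRNA.

The package is aimed at analyses of short circadian designs — typically
six Zeitgeber time points (ZT0..ZT20, 4 h spacing) with two biological
replicates — where replicate disagreement is large and informative, and
where nascent transcription produces peaked rather than sinusoidal
waveforms.

## Model

Each gene competes under three mean models on the 0–10 scaled axis
(per-time replicate medians rescaled to span [0, 10]):

- 24 h peaked cosine: `f(t) = a * ((1 + cos(2πt/T − p))/2)^q`, `T = 24`,
  amplitude `a ∈ [0, 10]`, phase `p` (peak at ZT `pT/2π`), exponent
  `q ∈ [1, 8]` (q = 1 is the standard cosinor shape);
- the same form with `T = 12` (fast oscillation / noise alternative);
- a linear drift `b0 + b1 t`.

The likelihood is a per-time Laplace density of the replicate median with
an adaptive scale `ε_t = mean_r |x_rt − μ_t|`, so
`log L = Σ_t [−log 2ε_t − |x̃_t − μ_t|/ε_t]`: maximising it minimises
absolute residuals while down-weighting times where replicates disagree.
Evidence `Z = ∫ L(θ)π(θ)dθ` per model comes from nested sampling; a gene
passing a permutation-calibrated Fourier screen (F24, relative 24 h
spectral power of the replicate-concatenated ZT0..ZT44 series, BH-adjusted
p ≤ 0.2) is called circadian when the 24 h evidence exceeds the better
alternative by a Bayes factor ≥ 10 and it survives a radial
quality filter combining phase uncertainty and L1 fit error (worst 5%
excluded).  The snoRNA–rRNA analysis removes rRNA, renormalises TPM to
10⁶ per sample, regresses each expressed gene on the target rRNA series,
and scans hypergeometric enrichment of the target's modifiers among
negatively (and positively) correlated genes over R² thresholds 0 to 1.

A synthetic-data module generates the full study structure (gene classes
with known parameters, snoRNA–host pairs, an antiphase rRNA module) so the
whole pipeline runs — and is validated — without any downloads.

## Worked example

```python
import numpy as np
from snorhythm import (GeneratorConfig, RRNAModuleSpec, generate_dataset,
                       rhythm_analysis, correlate_analysis)

cfg = GeneratorConfig(
    n_per_class={"cyclic24": 10, "cyclic12": 5, "linear": 5, "flat": 20},
    rrna_module=RRNAModuleSpec(n_modifiers=5),
    seed=42)
matrix, truths, annotations = generate_dataset(cfg)
print(f"{len(matrix)} genes x {len(matrix.sample_labels)} samples")

result = rhythm_analysis(matrix, master_seed=42)
print(result.calls["status"].value_counts().to_dict())

called = result.calls[result.calls["circadian"]]
for g, row in called.iterrows():
    print(f"{g}: phase ZT{row['phase_hours']:.1f} +- {row['phase_sd_hours']:.1f} h "
          f"(truth ZT{truths[g].params.phase_hours:.1f}), "
          f"evidence ratio {row['evidence_ratio']:.0f}")

scan = correlate_analysis(matrix, annotations, {"28S": "rRNA_28S"},
                          grid_step=0.05)
sub = scan[(scan["set"] == "modifier") & (scan.direction == "negative")
           & np.isclose(scan.r2_threshold, 0.3)]
print("negative-correlation enrichment at R^2>=0.3:",
      f"k={int(sub['k'].iloc[0])}/{int(sub['n'].iloc[0])} modifiers,",
      f"p={float(sub['p'].iloc[0]):.2e}")
```

Output:

```
51 genes x 12 samples
{'failed_f24': 26, 'not_circadian': 17, 'circadian': 8}
cyclic24_0002: phase ZT3.2 +- 1.6 h (truth ZT3.9), evidence ratio 15
mod28S_0000: phase ZT3.9 +- 0.9 h (truth ZT4.0), evidence ratio 34
modhost28S_0000: phase ZT16.1 +- 0.9 h (truth ZT16.0), evidence ratio 20
mod28S_0001: phase ZT3.9 +- 0.4 h (truth ZT4.0), evidence ratio 148
mod28S_0002: phase ZT3.9 +- 0.3 h (truth ZT4.0), evidence ratio 180
mod28S_0003: phase ZT3.7 +- 0.9 h (truth ZT4.0), evidence ratio 13
modhost28S_0003: phase ZT15.9 +- 0.8 h (truth ZT16.0), evidence ratio 12
mod28S_0004: phase ZT4.0 +- 0.6 h (truth ZT4.0), evidence ratio 53
negative-correlation enrichment at R^2>=0.3: k=5/5 modifiers, p=1.32e-04
```

Every called gene recovers its true phase within the reported
uncertainty; the antiphase modifiers are strongly enriched among genes
negatively correlated with the rRNA target, while in-phase host genes are
not.  Flat and 12 h genes end as `failed_f24` or `not_circadian` — the
factor-10 evidence rule is deliberately conservative on a 6-point design
(see `docs/methods.md`).

The same stages are available from the shell:

```sh
snorhythm simulate  --config cfg.yaml --seed 42 --out sim/
snorhythm rhythm    --config cfg.yaml --seed 42 --out run/    # calls.tsv
snorhythm correlate --config cfg.yaml --seed 42 --out scan/   # scan.tsv
snorhythm filters   --config cfg.yaml --seed 42 --out filt/   # filters.tsv
```

All randomness flows from the single `--seed`; re-running any stage with
the same inputs and seed reproduces its output byte for byte.

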