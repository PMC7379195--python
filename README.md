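# mmnlab

Tools for frequency mismatch-negativity (MMN) experiments that compare
**cascade** and **no-repetition** control conditions, packaged as a tested,
reusable pipeline: stimulus-sequence generation, synthetic epoched EEG with a
neural-adaptation model of the N1, ERP averaging and windowing, and Bayesian
hypothesis testing with informed priors.

## The scientific problem

The oddball MMN — the deviant-minus-standard difference wave — is confounded:
the deviant differs from the standard both physically and in presentation
probability, so part of the difference wave reflects stimulus-specific neural
adaptation of the N1 rather than pattern violation. The classic remedy is a
*corrected* MMN: subtract the response to a physically identical, equiprobable
control tone recorded in a separate control condition. Two orderings of that
control condition are in use:

* **no-repetition** — pseudorandom order, consecutive tones never identical;
* **cascade** — the tones rise and fall in a fixed ladder
  (500, 550, 605, 666, 732, 666, 605, 550 Hz), a regularity that is never
  violated.

If the cascade's regularity were easier for the auditory system to extract,
the cascade-corrected MMN (deviant − cascade control) should exceed the
no-repetition-corrected MMN (deviant − no-repetition control). The critical
effect is therefore the difference score

θ = (deviant − norep) − (deviant − cascade) = cascade − norep,

tested with a Bayes factor whose likelihood is a t distribution (df = n−1,
location = observed mean difference, scale = SE recovered from the 95% CI)
and whose alternative is a uniform prior from 0 to an empirically motivated
maximum (the observed oddball MMN magnitude):

BF10 = ∫ L(θ) dπ(θ) / L(0),  BF01 = 1/BF10.

The package reproduces every published Bayes factor of the reference study
from its printed summary statistics, and validates the full pipeline by
parameter recovery on synthetic data generated with a tonotopic-recency
adaptation model of the N1.

## Worked example

Recompute the published informed-prior Bayes factors from published inputs
(`python examples/03_bayes_reproduction.py`):

```
         analysis  mean_uv                prior  bf01  reported_bf01                              label
mmn_preregistered   -0.020     uniform[0, 2.67] 6.448          6.250         moderate evidence for null
 n1_preregistered    0.140     uniform[0, 0.17] 0.882          0.880 anecdotal evidence for alternative
          n1_wide    0.140     uniform[0, 1.38] 2.643          2.630        anecdotal evidence for null
    n1_two_tailed    0.140 uniform[-1.38, 1.38] 3.782          3.700         moderate evidence for null
       mmn_narrow   -0.020      uniform[0, 1.5] 3.623          3.570         moderate evidence for null
   mmn_two_tailed   -0.020 uniform[-2.67, 2.67] 6.151          6.250         moderate evidence for null

all recomputed BF01 within 5% of published values: True
```

Each row recovers the SE from the printed 95% CI (n = 26, df = 25),
integrates the t likelihood against the stated uniform prior and reports
BF01. The preregistered corrected-MMN analysis (first row) gives roughly six
times more evidence for "cascade and no-repetition controls yield the same
corrected MMN" than for a difference — the study's headline result. Residual
deviations from the published values are within the rounding of the printed
two-decimal inputs.

A noise-free synthetic subject run through the pipeline
(`python examples/02_synthetic_subject.py`) lands on the published condition
means:

```
detected windows: {'N1': '92.8 +- 15 ms', 'MMN': '138.7 +- 25 ms'}
standard   N1-window  +0.73 uV   MMN-window  +1.80 uV
deviant    N1-window  -0.56 uV   MMN-window  -0.77 uV
cascade    N1-window  -0.64 uV   MMN-window  +0.83 uV
norep      N1-window  -0.76 uV   MMN-window  +0.74 uV
```

The N1 ordering deviant > cascade > norep (least to most negative) is the
adaptation signature: a tone preceded by tonotopically close, recent tones
evokes a smaller N1. The randomization simulation
(`python examples/04_repetition_simulation.py`) shows why full randomization
is an inadequate control: 8 tones × 180 presentations in random order repeat
on 12.44% of adjacent pairs (closed form m·r·(r−1)/(N·(N−1))), low enough
that chance repetitions would themselves evoke an MMN.

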