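# voiceinv

**Voice production inversion with uncertainty quantification.**

`voiceinv` predicts how a speaker is using their voice at the
physiological level — the subglottal pressure driving phonation, the
glottal angle (how strongly the vocal folds are adducted), and vocal fold
geometry and stiffness — from features of the glottal source alone, and
attaches a 95% confidence interval to every prediction. It is aimed at
researchers in voice science and biomedical signal processing who want to
study the voice *inverse problem*: monitoring vocal behavior (talking too
loud, squeezing the larynx) without endoscopy, from signals obtainable
outside the clinic.

## What's inside

The inverse map is learned from simulation: a forward model generates
glottal flow waveforms from nine physiological parameters, fourteen
standard voice-source features are extracted from each waveform

> F0, SPL, CPP, HNR, SHR, H1-H2, H1-H4, H1-H2k, H1-H5k,
> Qmean, Qamp, CQ, MFDR, MFAR

and neural networks are trained to invert features → parameters. Two
uncertainty back-ends are provided:

- **Deep ensemble** — N independently initialized networks (14 → 4×200
  tanh → 9), each trained on its own random 70/15/15 split minimizing
  MSE + L2; the spread of member predictions yields the CI.
- **Mean-field variational network (BNN)** — a Gaussian posterior over
  every weight, fitted by maximizing the evidence lower bound
  (reparameterized sampling + Adam, learned per-output observation
  noise); prediction samples the posterior predictive 100 times.

Both report the 2.5/97.5 percentiles of their prediction samples as the
95% CI. Around the core sit: a kinematic surrogate forward model (string-law
F0, Bernoulli aerodynamics, Rosenberg-type pulses — see
`docs/methods.md`), the native feature extractors, evaluation metrics
(MAE, MAPE, prediction-interval coverage, CI width, regression slope/R²),
and the /pa/-utterance protocol that turns peak intraoral pressure during
plosive occlusions into ground-truth subglottal pressure for the
intervening vowels.

## Worked example

```python
import voiceinv as vi

params = vi.PhysioParams(
    vf_length=16.0, vf_thickness=3.5, body_depth=6.0, cover_depth=2.0,
    body_stiffness=15.0, cover_stiffness=23.5, transverse_stiffness=10.0,
    glottal_angle=3.0, subglottal_pressure=800.0,
)
signal = vi.synthesize_glottal_flow(params, noise_seed=0)
print(vi.extract_features(signal))
```

prints (among the fourteen features)

```
F0     =   167.849 Hz      # string law predicts 167.8 Hz for L=16mm, 30 kPa
SPL    =    74.967 dB      # monopole radiation at 0.3 m
Qmean  =     0.209 L/s     # DC leak through the 3-degree posterior gap
Qamp   =     0.420 L/s     # pulse amplitude driven by the 800 Pa pressure
MFDR   =   948.046 L/s^2   # steepest flow fall, tracks vocal intensity
```

Train and predict with uncertainty (`examples/02_train_ensemble.py`):

```python
corpus = vi.make_corpus(3300, seed=0)               # simulate + extract
model = vi.train_ensemble(corpus.iloc[:3000], n_members=5, seed=1)
pred  = vi.predict_ensemble(model, corpus.iloc[3000:][list(vi.FEATURE_NAMES)].to_numpy())
# pred.mean / pred.lower / pred.upper are (n, 9) arrays in physical units
```

The /pa/ protocol (`examples/04_pa_protocol.py`) synthesizes five /pa/
repetitions with the commanded pressure ramping 800 → 1200 Pa and recovers
it from the intraoral pressure channel alone:

```
detected 5 plosive peaks:
  t =  0.06 s   peak intraoral pressure =    814 Pa
  ...
  t =  1.57 s   peak intraoral pressure =   1134 Pa
4 vowels are bracketed by peaks and evaluable:
  vowel 0.18-0.31 s: truth Ps =    854 Pa, extracted F0 = 167.4 Hz, SPL =  73.4 dB
```

Each `examples/*.py` script is a short narrative of one capability; the
same stages are available as shell subcommands:

```bash
voiceinv simulate --n 5000 --seed 0 --out corpus.csv
voiceinv train --dataset corpus.csv --backend ensemble --out model.npz
voiceinv predict --model model.npz --features feats.csv --out pred.csv
voiceinv demo --outdir demo_out      # end-to-end with figures
```

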