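"""Train a small deep ensemble and predict physiology with a 95% CI.

Generates a 3000-row surrogate corpus, trains 5 independently
initialized networks (each on its own random 70/15/15 split), and
prints the predicted subglottal pressure with its confidence interval
for a few held-out voices.
"""
import numpy as np

import voiceinv as vi
from voiceinv.features import FEATURE_NAMES
from voiceinv.params import PARAM_NAMES

corpus = vi.make_corpus(3300, seed=0)
train_df, test_df = corpus.iloc[:3000], corpus.iloc[3000:]

model = vi.train_ensemble(
    train_df,
    vi.NetworkSpec(),                       # 14 -> 4 x 200 (tanh) -> 9
    vi.TrainConfig(max_epochs=60, patience=10),
    n_members=5,
    seed=1,
)

X = test_df[list(FEATURE_NAMES)].to_numpy()
y = test_df[list(PARAM_NAMES)].to_numpy()
pred = vi.predict_ensemble(model, X)

ps = list(PARAM_NAMES).index("subglottal_pressure")
print("held-out subglottal pressure, first 5 voices (Pa):")
print("   true    predicted   95% CI")
for i in range(5):
    print(
        f"  {y[i, ps]:6.0f}    {pred.mean[i, ps]:6.0f}   "
        f"[{pred.lower[i, ps]:6.0f}, {pred.upper[i, ps]:6.0f}]"
    )
slope, r2 = vi.regression_fit(pred.mean[:, ps], y[:, ps])
print(f"regression of prediction on truth: slope={slope:.3f}, R^2={r2:.3f}")
print(f"MAPE: {vi.mape(pred.mean[:, ps], y[:, ps]):.1f}%")
print("The CI here reflects member disagreement (epistemic uncertainty).")
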