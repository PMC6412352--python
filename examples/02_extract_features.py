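"""Window a drive and extract the 36-feature matrix.

Each 3-second window of steering angle and velocity yields 18 descriptors
per channel; features are min-max normalized with bounds learned from the
data itself (in a real fit, from the training split only).
"""

import numpy as np

from steerwake import (
    FEATURE_NAMES,
    ScenarioConfig,
    WindowSpec,
    apply_normalizer,
    extract_features,
    fit_normalizer,
    generate_trace,
    slide_windows,
)

trace = generate_trace(ScenarioConfig(duration_s=180.0, seed=2))
segments = slide_windows(trace, WindowSpec())
fm, labels = extract_features(segments, trace.fs)
print(f"{fm.n_windows} labelled windows x {fm.n_features} features "
      f"({int((labels == 1).sum())} drowsy)")

norm = fit_normalizer(fm.X)
Xn = apply_normalizer(fm.X, norm)
print(f"normalized range: [{Xn.min():.3f}, {Xn.max():.3f}]")

# features whose class means differ most after normalization
gap = np.abs(Xn[labels == 1].mean(axis=0) - Xn[labels == 0].mean(axis=0))
top = np.argsort(gap)[::-1][:5]
print("largest awake/drowsy mean gaps:")
for j in top:
    print(f"  {FEATURE_NAMES[j]}: {gap[j]:.3f}")
print("(I-numbers 1-18 index the descriptor, the suffix the channel:")
print(" a = steering angle, v = steering velocity)")
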