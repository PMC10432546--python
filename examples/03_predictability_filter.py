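"""Score OCR predictability with NMEA and choose the tau threshold.

NMEA_p(i) = mean_n |pred - truth| / mean_n |truth| per (cell type, OCR);
OCRs with NMEA below M + tau * sigma are kept, and tau is chosen to
maximise the mean per-cell-type Spearman on validation pairs.
"""

import numpy as np

from atacsep import compute_nmea, optimize_tau

rng = np.random.default_rng(0)
N, S, P = 40, 2, 300
truth = np.abs(rng.lognormal(0.0, 0.8, size=(N, S, P)))
pred = truth + rng.normal(0, 0.1, size=truth.shape)  # mostly accurate
pred[:, :, :60] = rng.random((N, S, 60))  # first 60 OCRs unpredictable

scores = compute_nmea(pred, truth)
print(f"NMEA range: {scores.nmea.min():.3f} .. {scores.nmea.max():.3f}")

tau, mask, curve = optimize_tau(pred, truth, scores=scores)
kept = mask.mask.sum(axis=1)
bad_kept = mask.mask[:, :60].sum(axis=1)
print(f"optimal tau = {tau:+.1f}; OCRs kept per cell type: {kept.tolist()}")
print(f"unpredictable OCRs kept: {bad_kept.tolist()} of 60")
for row in curve[::5]:
    print(f"  tau {row['tau']:+.1f}: objective {row['objective']:.3f}, "
          f"retained {row['n_retained']}")
# The filter discards the corrupted block almost entirely: high NMEA marks
# OCRs whose predictions cannot be trusted downstream.
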