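"""Call-density series and their Pearson/Spearman agreement.

Even an imperfect detector is ecologically useful if it preserves the
temporal pattern of vocal activity. This example builds a density
series from annotations, degrades it into a plausible set of detections
(missed calls plus spurious events), and correlates the two.
"""

import numpy as np

from sirenet import evaluation as ev

rng = np.random.default_rng(0)

# True calls over 10 minutes with pronounced activity peaks.
per_minute = [3, 9, 0, 5, 14, 2, 11, 1, 6, 16]
true_starts = [
    60.0 * k + float(t)
    for k, c in enumerate(per_minute)
    for t in np.sort(rng.uniform(0, 58, size=c))
]

# A detector that misses 30 % of calls and adds a few false events.
detected = [t for t in true_starts if rng.random() > 0.3]
detected += list(rng.uniform(0, 600.0, size=4))

truth = ev.call_density(true_starts, "minute", (0.0, 600.0))
pred = ev.call_density(sorted(detected), "minute", (0.0, 600.0))
print("true  counts/min:", truth.counts.tolist())
print("pred  counts/min:", pred.counts.tolist())

corr = ev.density_correlation(pred, truth)
print(f"Pearson r = {corr.pearson_r:.3f} (p = {corr.pearson_p:.2e})")
print(f"Spearman rho = {corr.spearman_rho:.3f} (p = {corr.spearman_p:.2e})")
# High correlations despite the misses: the activity peaks survive, which
# is what a researcher scanning months of recordings needs.
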