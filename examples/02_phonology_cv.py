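"""Phonological variability: per-syllable CV and score-batch aggregation.

Samples 25 renditions of one syllable under two conditions (the singing
condition 1.5x noisier), summarizes each acoustic feature's coefficient
of variation, and aggregates a synthetic all-vs-all similarity batch.
"""

import numpy as np
import pandas as pd

from songvar import ScoreMatrix, aggregate_cv, aggregate_scores, feature_summary, identity_score
from songvar.synthetic import DEFAULT_FEATURE_MEANS, sample_feature_renditions

tables = [
    sample_feature_renditions(
        DEFAULT_FEATURE_MEANS, cv=0.074 * (1.5 if cond == "UD-UD" else 1.0),
        n=25, seed=i, bird_id="demo", syllable="a", condition=cond,
    )
    for i, cond in enumerate(("NS-UD", "UD-UD"))
]
summary = feature_summary(pd.concat(tables, ignore_index=True))
pitch = summary[summary["feature"] == "pitch"].set_index("condition")
print("pitch CV by condition (SD/mean over 25 renditions):")
print(pitch[["mean", "sd", "cv"]].round(4).to_string())
print()
print(aggregate_cv(summary, level="per_syllable").round(4).to_string(index=False))
print()
# Higher CV after two hours of singing = noisier syllable phonology.

# a 20-motif all-vs-all similarity batch: (20*20) - 20 self-tests = 380 scores
rng = np.random.default_rng(0)
sim = np.clip(rng.normal(82, 5, (20, 20)), 0, 100)
acc = np.clip(rng.normal(88, 4, (20, 20)), 0, 100)
np.fill_diagonal(sim, 100.0)
np.fill_diagonal(acc, 100.0)
batch = aggregate_scores(ScoreMatrix(similarity=sim, accuracy=acc, unit="motif"))
print(f"n_scores   : {batch.n_scores}")
print(f"similarity : {batch.similarity_mean:.2f} +/- {batch.similarity_se:.2f} (SE)")
print(f"accuracy   : {batch.accuracy_mean:.2f} +/- {batch.accuracy_se:.2f} (SE)")
print(f"identity of the means: "
      f"{identity_score(batch.similarity_mean, batch.accuracy_mean):.2f}")
# identity = similarity x accuracy / 100 combines both scores on one scale.
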