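"""End-to-end recovery: generate a paired dataset, run the full pipeline.

Simulates 11 birds whose singing-condition syllable chains are more
entropic (epsilon 0.4 vs 0.2), writes the motif/string/feature files, and
runs the complete analysis to recover the conditional difference.
"""

import tempfile
from pathlib import Path

from songvar import EffectSpec, RunConfig, make_paired_dataset, run_pipeline

effect = EffectSpec(n_birds=11, eps_ns=0.2, eps_ud=0.4, eps_sd=0.05)

with tempfile.TemporaryDirectory() as tmp:
    data = Path(tmp) / "data"
    ds = make_paired_dataset(effect, seed=7, outdir=data)
    truth_gap = sum(
        b.true_entropy["UD-UD"] - b.true_entropy["NS-UD"] for b in ds.birds
    ) / len(ds.birds)
    print(f"ground-truth mean entropy gap: {truth_gap:.3f}")

    result = run_pipeline(RunConfig(seed=7, n_bootstrap=10_000), data)

print("\nconditional tests (one sign-flip bootstrap per mode x measure):")
print(result.tests[["mode", "measure", "M", "p_value", "significant"]]
      .round(4).to_string(index=False))
# M > 0 for motif_entropy = the singing condition is more variable; the
# string-based test should detect the built-in epsilon gap at p < 0.05.
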