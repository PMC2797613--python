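"""End-to-end analysis pipeline over a directory of song inputs.

Input layout (as written by :func:`songvar.synthetic.make_paired_dataset`):

    <indir>/<bird>_NSUD.motifs.txt    one motif per line
    <indir>/<bird>_UDUD.motifs.txt
    <indir>/<bird>_NSUD.string.txt    300-syllable string (optional)
    <indir>/<bird>_UDUD.string.txt
    <indir>/features.csv              per-rendition acoustic features (optional)

For every bird with both conditions the pipeline computes motif-based and
string-based entropy/stereotypy, per-bird percent changes, acoustic CV
summaries, and a paired sign-flip bootstrap across birds for each
sequence measure; everything is written as CSV plus a JSON run log with
the seed, config hash, and per-stage record counts.  Outputs are a pure
function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .io import RunConfig, read_feature_table, read_motif_file, read_syllable_string
from .phonology import feature_summary
from .sequence import analyze_sequences, percent_change
from .stats import PairedSample, paired_signflip_bootstrap

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger("songvar")

_CONDITION_TAGS = {"NSUD": "NS-UD", "UDUD": "UD-UD"}
_FILE_RE = re.compile(r"^(?P<bird>.+)_(?P<tag>NSUD|UDUD)\.(?P<kind>motifs|string)\.txt$")


@dataclass
class PipelineResult:
    sequence_scores: pd.DataFrame      # per bird x condition x mode
    percent_changes: pd.DataFrame      # per bird x mode x measure
    tests: pd.DataFrame                # one sign-flip bootstrap per measure
    feature_summaries: Optional[pd.DataFrame]
    log: dict = field(default_factory=dict)


def _discover(indir: Path) -> dict:
    """Map bird -> condition -> {kind: path} from the directory layout."""
    found: dict = {}
    for path in sorted(indir.iterdir()):
        m = _FILE_RE.match(path.name)
        if not m:
            continue
        cond = _CONDITION_TAGS[m.group("tag")]
        found.setdefault(m.group("bird"), {}).setdefault(cond, {})[
            m.group("kind")
        ] = path
    return found


def run_pipeline(
    config: RunConfig,
    indir: Union[str, Path],
    outdir: Optional[Union[str, Path]] = None,
) -> PipelineResult:
    """Run the full song-variability analysis on a directory of inputs.

    Raises with input-file context when a file fails to parse.  With
    ``outdir`` set, writes ``sequence_scores.csv``, ``percent_changes.csv``,
    ``tests.csv``, ``feature_summary.csv`` (when features are present) and
    ``run_log.json``.
    """
    indir = Path(indir)
    birds = _discover(indir)
    if not birds:
        raise ValueError(f"no recognizable input files in {indir}")

    seq_rows, pct_rows = [], []
    for bird, conds in birds.items():
        for cond, files in conds.items():
            for kind, path in files.items():
                try:
                    if kind == "motifs":
                        data = read_motif_file(path, bird_id=bird, condition=cond)
                        res = analyze_sequences(
                            data,
                            include_end=config.include_end_transitions,
                            weighting=config.weighting,
                        )
                    else:
                        data = read_syllable_string(path, bird_id=bird, condition=cond)
                        res = analyze_sequences(data, weighting=config.weighting)
                except Exception as exc:
                    raise RuntimeError(f"while processing {path}: {exc}") from exc
                seq_rows.append(
                    {
                        "bird": bird,
                        "condition": cond,
                        "mode": res.mode,
                        "weighting": res.weighting,
                        "motif_entropy": res.motif_entropy,
                        "stereotypy": res.motif_stereotypy,
                        "stereotypy_scaled": res.stereotypy_scaled,
                        "n_unique": res.n_unique,
                    }
                )
    seq_df = pd.DataFrame(seq_rows)

    # per-bird percent change NS-UD -> UD-UD per mode and measure
    for (bird, mode), grp in seq_df.groupby(["bird", "mode"]):
        by_cond = grp.set_index("condition")
        if not {"NS-UD", "UD-UD"}.issubset(by_cond.index):
            continue
        for measure in ("motif_entropy", "stereotypy"):
            ns = by_cond.loc["NS-UD", measure]
            ud = by_cond.loc["UD-UD", measure]
            row = {"bird": bird, "mode": mode, "measure": measure,
                   "ns_value": ns, "ud_value": ud}
            row["percent_change"] = (
                percent_change(ns, ud) if ns != 0 else float("nan")
            )
            pct_rows.append(row)
    pct_df = pd.DataFrame(pct_rows)

    # paired sign-flip bootstrap across birds, per mode x measure
    test_rows = []
    if not pct_df.empty:
        for (mode, measure), grp in pct_df.groupby(["mode", "measure"]):
            if len(grp) < 2:  # cross-bird inference needs >= 2 birds
                continue
            sample = PairedSample.from_conditions(
                grp["ns_value"].to_numpy(),
                grp["ud_value"].to_numpy(),
                unit_ids=list(grp["bird"]),
                measure=f"{mode}:{measure}",
            )
            res = paired_signflip_bootstrap(
                sample,
                n_iter=config.n_bootstrap,
                seed=config.seed,
                alpha=config.alpha,
                keep_null=False,
            )
            test_rows.append(
                {
                    "mode": mode,
                    "measure": measure,
                    "n_birds": sample.n,
                    "M": res.m_observed,
                    "p_value": res.p_value,
                    "n_iter": res.n_iter,
                    "seed": config.seed,
                    "significant": res.significant,
                }
            )
    tests_df = pd.DataFrame(test_rows)

    feat_df = None
    features_path = indir / "features.csv"
    if features_path.exists():
        try:
            feat_df = feature_summary(read_feature_table(features_path))
        except Exception as exc:
            raise RuntimeError(f"while processing {features_path}: {exc}") from exc

    log = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "n_birds": len(birds),
        "n_sequence_scores": len(seq_df),
        "n_percent_changes": len(pct_df),
        "n_tests": len(tests_df),
        "n_feature_summaries": 0 if feat_df is None else len(feat_df),
    }
    logger.info("pipeline run: %s", log)

    result = PipelineResult(
        sequence_scores=seq_df,
        percent_changes=pct_df,
        tests=tests_df,
        feature_summaries=feat_df,
        log=log,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = "%.12g"
        seq_df.to_csv(outdir / "sequence_scores.csv", index=False, float_format=fmt)
        pct_df.to_csv(outdir / "percent_changes.csv", index=False, float_format=fmt)
        tests_df.to_csv(outdir / "tests.csv", index=False, float_format=fmt)
        if feat_df is not None:
            feat_df.to_csv(outdir / "feature_summary.csv", index=False, float_format=fmt)
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return result
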