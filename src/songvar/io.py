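"""Text and tabular input/output for song-variability analysis.

Formats follow the transcription workflow of motif-based song studies:

* **motif files** — plain text, one motif per line.  A line is either a
  contiguous run of letters (``AAB``; mapped ``A=1, B=2, ...``) or
  whitespace-separated integers (``1 1 2``; allows repertoires beyond 26
  syllables).  Blank lines are ignored.
* **syllable-string files** — a single whitespace/newline-separated
  sequence of labels, conventionally 300 syllables long.
* **feature tables** — CSV with one row per syllable rendition and one
  column per acoustic feature (duration, amplitude, pitch, FM, Wiener
  entropy, mean frequency, pitch goodness).
* **score matrices** — long-format CSV of all-vs-all similarity/accuracy
  comparisons (``item_i, item_j, similarity[, accuracy]``).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MotifSet",
    "SyllableString",
    "RunConfig",
    "FEATURE_COLUMNS",
    "REQUIRED_FEATURE_COLUMNS",
    "read_motif_file",
    "write_motif_file",
    "read_syllable_string",
    "write_syllable_string",
    "read_feature_table",
    "write_feature_table",
    "read_score_matrix",
    "write_score_matrix",
    "load_config",
]

CONDITIONS = ("NS-UD", "UD-UD")

#: Acoustic-feature columns of a rendition table.
FEATURE_COLUMNS = [
    "duration",
    "amplitude",
    "pitch",
    "FM",
    "wiener_entropy",
    "mean_frequency",
    "pitch_goodness",
]

REQUIRED_FEATURE_COLUMNS = ["bird", "syllable", "condition", "rendition"] + FEATURE_COLUMNS


@dataclass
class MotifSet:
    """An ordered collection of transcribed motifs for one bird/condition.

    Each motif is an ordered list of syllable labels (positive integers
    after letter mapping).  The motif is the basic analytical unit of
    zebra-finch song: a short, repeated syllable sequence.
    """

    motifs: list
    bird_id: str = ""
    condition: str = ""
    age_days: Union[int, str, None] = None

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("no motifs")
        for m in self.motifs:
            if len(m) == 0:
                raise ValueError("empty motif")
        if self.condition and self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    @property
    def alphabet(self) -> frozenset:
        return frozenset(s for m in self.motifs for s in m)


@dataclass
class SyllableString:
    """One long un-segmented syllable sequence (string-based analysis).

    Carries no motif-boundary information; the conventional length is 300
    syllables (roughly one minute of continuous song).
    """

    symbols: list
    bird_id: str = ""
    condition: str = ""
    age_days: Union[int, str, None] = None
    nominal_length: int = 300

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValueError("syllable string must contain at least 2 symbols")
        if self.condition and self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


@dataclass
class RunConfig:
    """Pipeline configuration.

    Attributes
    ----------
    include_end_transitions
        Count end-of-motif transitions in motif mode.
    entropy_log_base
        Base of the entropy logarithm (2 = bits; normalized scores are
        base-invariant).
    n_bootstrap
        Resampling iterations for the sign-flip test.
    alpha
        Significance level.
    seed
        Root seed for all stochastic stages.
    weighting
        "standard" or "weighted" motif entropy.
    """

    include_end_transitions: bool = True
    entropy_log_base: float = 2.0
    n_bootstrap: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    weighting: str = "standard"

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.weighting not in ("standard", "weighted"):
            raise ValueError("weighting must be 'standard' or 'weighted'")

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return RunConfig(**data)


def _parse_motif_line(line: str) -> tuple[list, str]:
    """Parse one motif line; returns (labels, alphabet_kind)."""
    tokens = line.split()
    if len(tokens) > 1 or (len(tokens) == 1 and tokens[0].isdigit()):
        try:
            return [int(t) for t in tokens], "integer"
        except ValueError as exc:
            raise ValueError(f"bad integer motif line {line!r}") from exc
    word = tokens[0]
    if word.isalpha():
        return [ord(c.upper()) - ord("A") + 1 for c in word], "letter"
    raise ValueError(
        f"motif line {line!r} is neither contiguous letters nor "
        "whitespace-separated integers"
    )


def read_motif_file(
    path: Union[str, Path],
    bird_id: str = "",
    condition: str = "",
    age_days: Union[int, str, None] = None,
) -> MotifSet:
    """Read a plain-text motif file (one motif per line).

    Letter lines are mapped to integers via ``A=1, B=2, ...``; integer
    lines are used as-is.  Mixing the two alphabets within one file is an
    error, as is an empty file.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise ValueError(f"no motifs in {path}")
    motifs = []
    kinds = set()
    for ln in lines:
        labels, kind = _parse_motif_line(ln)
        kinds.add(kind)
        motifs.append(labels)
    if len(kinds) > 1:
        raise ValueError(f"mixed letter/integer alphabets in {path}")
    return MotifSet(motifs=motifs, bird_id=bird_id, condition=condition, age_days=age_days)


def write_motif_file(motifs: MotifSet, path: Union[str, Path]) -> None:
    """Write a MotifSet as one whitespace-separated integer motif per line."""
    Path(path).write_text(
        "\n".join(" ".join(str(s) for s in m) for m in motifs.motifs) + "\n"
    )


def read_syllable_string(
    path: Union[str, Path],
    bird_id: str = "",
    condition: str = "",
    age_days: Union[int, str, None] = None,
    nominal_length: int = 300,
) -> SyllableString:
    """Read a syllable-string file (whitespace/newline-separated labels).

    Warns, but does not fail, when the string length differs from the
    nominal 300-syllable convention.
    """
    tokens = Path(path).read_text().split()
    if len(tokens) < 2:
        raise ValueError(f"syllable string in {path} has fewer than 2 symbols")
    symbols = [int(t) if t.lstrip("-").isdigit() else t for t in tokens]
    if len(symbols) != nominal_length:
        warnings.warn(
            f"{path}: {len(symbols)} syllables (nominal {nominal_length})",
            stacklevel=2,
        )
    return SyllableString(
        symbols=symbols,
        bird_id=bird_id,
        condition=condition,
        age_days=age_days,
        nominal_length=nominal_length,
    )


def write_syllable_string(string: SyllableString, path: Union[str, Path]) -> None:
    Path(path).write_text(" ".join(str(s) for s in string.symbols) + "\n")


def read_feature_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a per-rendition acoustic-feature CSV.

    Requires the columns ``bird, syllable, condition, rendition`` plus the
    seven acoustic features; unknown columns are preserved.  Raises a
    ``ValueError`` naming the first missing column.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"feature table {path} is empty")
    for col in REQUIRED_FEATURE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"feature table {path} is missing column {col!r}")
    if (df["duration"] <= 0).any():
        raise ValueError(f"feature table {path} has non-positive durations")
    dupes = df.duplicated(subset=["bird", "syllable", "condition", "rendition"])
    if dupes.any():
        raise ValueError(
            f"feature table {path} has duplicate rendition indices within "
            "(bird, syllable, condition)"
        )
    return df


def write_feature_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, index=False)


def read_score_matrix(path: Union[str, Path]):
    """Read a long-format all-vs-all score CSV into a ScoreMatrix."""
    from .phonology import ScoreMatrix  # local import to avoid a cycle

    df = pd.read_csv(path)
    for col in ("item_i", "item_j", "similarity"):
        if col not in df.columns:
            raise ValueError(f"score file {path} is missing column {col!r}")
    items = sorted(set(df["item_i"]) | set(df["item_j"]))
    idx = {it: k for k, it in enumerate(items)}
    m = len(items)
    sim = np.full((m, m), np.nan)
    acc = np.full((m, m), np.nan) if "accuracy" in df.columns else None
    for _, row in df.iterrows():
        i, j = idx[row["item_i"]], idx[row["item_j"]]
        sim[i, j] = row["similarity"]
        if acc is not None:
            acc[i, j] = row["accuracy"]
    np.fill_diagonal(sim, 100.0)
    if acc is not None:
        np.fill_diagonal(acc, 100.0)
    return ScoreMatrix(similarity=sim, accuracy=acc, items=items)


def write_score_matrix(matrix, path: Union[str, Path]) -> None:
    """Write a ScoreMatrix as long-format CSV (off-diagonal pairs only)."""
    rows = []
    m = matrix.m
    items = matrix.items or list(range(m))
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            row = {
                "item_i": items[i],
                "item_j": items[j],
                "similarity": matrix.similarity[i, j],
            }
            if matrix.accuracy is not None:
                row["accuracy"] = matrix.accuracy[i, j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
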