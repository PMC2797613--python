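"""Syllable-sequence variability statistics for birdsong.

A bird's song is modelled as a first-order Markov chain over its syllable
repertoire.  For each leading syllable the outgoing transition distribution
is estimated from observed counts; the Shannon entropy of that distribution,
normalized to the maximum entropy attainable given the repertoire size, is
the syllable's sequence-variability score.  Averaging the normalized
syllable entropies (optionally frequency-weighted, to damp the influence of
rarely-sung syllables) gives the *motif entropy*; *stereotypy* is its
complement, ``1 - motif_entropy``, so a stereotypy of 1 means a perfectly
fixed syllable order.

Two estimation modes exist, mirroring how song data are transcribed:

* **motif mode** — input is a set of segmented motifs; the transition from
  the last syllable of each motif to the end-of-motif marker is (by default)
  counted as a real transition, so motif termination contributes to
  variability.
* **string mode** — input is one long un-segmented syllable string; there is
  no motif boundary, so the final symbol simply contributes no transition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .io import MotifSet, SyllableString

__all__ = [
    "END",
    "TransitionCounts",
    "TransitionModel",
    "SequenceVariabilityResult",
    "count_transitions",
    "transition_probabilities",
    "syllable_entropy",
    "max_entropy",
    "normalized_entropy",
    "motif_entropy",
    "percent_change",
    "analyze_sequences",
]

Label = Hashable


class _EndMarker:
    """Singleton sentinel for the end-of-motif outcome."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "END"

    def __str__(self) -> str:
        return "END"


#: End-of-motif outcome symbol.  Never a leading syllable.
END = _EndMarker()


@dataclass
class TransitionCounts:
    """Raw outgoing-transition tallies per leading syllable.

    Attributes
    ----------
    alphabet
        All syllable labels observed anywhere in the input (END excluded).
    end_included
        Whether end-of-motif transitions were tallied.
    counts
        ``counts[a][b]`` = number of times leading syllable ``a`` was
        immediately followed by outcome ``b`` (a syllable, or :data:`END`).
    f_total
        Total outgoing-transition count per leading syllable (the
        denominator of each transition probability).
    frequency
        Number of occurrences of each syllable *as a leading syllable*,
        i.e. occurrences that have an outgoing transition.  This is the
        frequency used for the weighted motif entropy, so weights and
        transition distributions share the same support.
    """

    alphabet: frozenset
    end_included: bool
    counts: dict
    f_total: dict
    frequency: dict

    def __post_init__(self) -> None:
        for sym, row in self.counts.items():
            if sym is END:
                raise ValueError("END cannot be a leading syllable")
            if sum(row.values()) != self.f_total[sym]:
                raise ValueError(f"count/F_total mismatch for syllable {sym!r}")


@dataclass
class TransitionModel:
    """Estimated first-order transition probabilities.

    ``p[a][b]`` is the probability that leading syllable ``a`` is followed
    by outcome ``b``; each outgoing row sums to 1.
    """

    alphabet: frozenset
    end_included: bool
    p: dict

    def __post_init__(self) -> None:
        for sym, row in self.p.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"outgoing distribution for {sym!r} sums to {total}, not 1"
                )
            if any(v < 0 or v > 1 for v in row.values()):
                raise ValueError(f"probability out of [0, 1] for {sym!r}")

    @property
    def symbols(self) -> list:
        return list(self.p)


@dataclass
class SequenceVariabilityResult:
    """Per-syllable and motif-level entropy/stereotypy scores."""

    mode: str                      # "motif_based" | "string_based"
    weighting: str                 # "standard" | "weighted"
    raw_entropy: dict              # symbol -> H in bits
    h_max: float                   # bits; shared normalization ceiling
    normalized: dict               # symbol -> H / H_max in [0, 1]
    weights: dict                  # symbol -> F_s / F_mostfrequent in (0, 1]
    n_unique: int
    motif_entropy: float
    motif_stereotypy: float = field(init=False)
    stereotypy_scaled: float = field(init=False)

    def __post_init__(self) -> None:
        self.motif_stereotypy = 1.0 - self.motif_entropy
        self.stereotypy_scaled = 100.0 * self.motif_stereotypy

    def per_syllable_frame(self) -> pd.DataFrame:
        """Per-syllable table (symbol, F_s, w_s, H, H_max, H_norm)."""
        rows = [
            {
                "symbol": str(s),
                "w_s": self.weights[s],
                "H": self.raw_entropy[s],
                "H_max": self.h_max,
                "H_norm": self.normalized[s],
            }
            for s in self.raw_entropy
        ]
        return pd.DataFrame(rows)


def _as_sequences(
    sequences: Union[MotifSet, SyllableString, Iterable[Sequence[Label]]],
    include_end: bool,
) -> tuple[list, str]:
    """Normalize input to (list of symbol sequences, mode)."""
    if isinstance(sequences, MotifSet):
        return [list(m) for m in sequences.motifs], "motif_based"
    if isinstance(sequences, SyllableString):
        if include_end:
            raise ValueError(
                "end-of-motif transitions are undefined for string input: "
                "a syllable string carries no motif boundaries"
            )
        return [list(sequences.symbols)], "string_based"
    seqs = [list(s) for s in sequences]
    return seqs, "motif_based"


def count_transitions(
    sequences: Union[MotifSet, SyllableString, Iterable[Sequence[Label]]],
    include_end: bool = True,
) -> TransitionCounts:
    """Tally first-order syllable transitions.

    Parameters
    ----------
    sequences
        A :class:`~songvar.io.MotifSet` (motif mode), a
        :class:`~songvar.io.SyllableString` (string mode), or a bare
        iterable of label sequences (treated as motifs).
    include_end
        In motif mode, whether the last syllable of each motif contributes
        one transition to :data:`END`.  Must be ``False`` for string input.

    Returns
    -------
    TransitionCounts

    Notes
    -----
    ``frequency`` counts every syllable position that has an outgoing
    transition.  With ``include_end`` every occurrence does; otherwise each
    sequence's final position is excluded.
    """
    seqs, mode = _as_sequences(sequences, include_end)
    if not seqs or all(len(s) == 0 for s in seqs):
        raise ValueError("no sequences to count")
    min_len = 1 if (mode == "motif_based" and include_end) else 2
    if all(len(s) < min_len for s in seqs):
        raise ValueError(
            f"need at least one sequence of length >= {min_len} in this mode"
        )

    counts: dict = {}
    frequency: dict = {}
    alphabet: set = set()
    for seq in seqs:
        alphabet.update(seq)
        outcomes = list(seq[1:])
        if mode == "motif_based" and include_end:
            outcomes.append(END)
        for lead, nxt in zip(seq, outcomes):
            row = counts.setdefault(lead, {})
            row[nxt] = row.get(nxt, 0) + 1
            frequency[lead] = frequency.get(lead, 0) + 1
    f_total = {s: sum(row.values()) for s, row in counts.items()}
    return TransitionCounts(
        alphabet=frozenset(alphabet),
        end_included=(mode == "motif_based" and include_end),
        counts=counts,
        f_total=f_total,
        frequency=frequency,
    )


def transition_probabilities(counts: TransitionCounts) -> TransitionModel:
    """Convert transition counts to probabilities.

    ``p(A -> B) = F_(A->B) / F_total(A)``.  Syllables that occur in the
    data but never with an outgoing transition (only possible as a
    string's final symbol) have an undefined distribution; they are
    excluded from the model with a warning.
    """
    orphans = counts.alphabet - set(counts.counts)
    if orphans:
        warnings.warn(
            f"syllables with no outgoing transitions excluded from model: "
            f"{sorted(map(str, orphans))}",
            stacklevel=2,
        )
    p = {
        sym: {out: c / counts.f_total[sym] for out, c in row.items()}
        for sym, row in counts.counts.items()
    }
    return TransitionModel(
        alphabet=counts.alphabet, end_included=counts.end_included, p=p
    )


def syllable_entropy(model: TransitionModel, symbol: Label) -> float:
    """Shannon entropy (bits) of one syllable's outgoing distribution.

    ``H = -sum_i p_i log2 p_i`` with the convention ``0 log 0 = 0``.
    """
    if symbol not in model.p:
        raise KeyError(f"symbol {symbol!r} not in model")
    probs = np.array(list(model.p[symbol].values()), dtype=float)
    probs = probs[probs > 0]
    return float(-(probs * np.log2(probs)).sum() + 0.0)  # +0.0 avoids -0.0


def max_entropy(n_outcomes: int) -> float:
    """Maximum entropy (bits) over ``n_outcomes`` equally-likely outcomes.

    This is ``log2(n_outcomes)``; 0 for a single outcome.
    """
    if n_outcomes < 1:
        raise ValueError("n_outcomes must be >= 1")
    return math.log2(n_outcomes)


def normalized_entropy(h: float, h_max: float) -> float:
    """Entropy scaled to the repertoire maximum, in [0, 1].

    Defined as ``H / H_max``; 0 when ``H_max`` is 0 (single-outcome
    repertoire).  Inputs with ``H > H_max`` beyond float round-off are
    rejected as inconsistent.
    """
    if h < 0 or h_max < 0:
        raise ValueError("entropies must be nonnegative")
    if h > h_max + 1e-9:
        raise ValueError(f"H={h} exceeds H_max={h_max}: inconsistent inputs")
    if h_max == 0:
        return 0.0
    ratio = h / h_max
    # clamp only float overshoot (<= 1e-12 past the bounds)
    return min(max(ratio, 0.0), 1.0)


def motif_entropy(
    model: TransitionModel,
    counts: TransitionCounts,
    weighting: str = "standard",
    legacy_hmax: bool = False,
    mode: str | None = None,
) -> SequenceVariabilityResult:
    """Average normalized syllable entropy across the repertoire.

    Parameters
    ----------
    model, counts
        Paired output of :func:`transition_probabilities` /
        :func:`count_transitions`.
    weighting
        ``"standard"``: unweighted mean of per-syllable normalized
        entropies.  ``"weighted"``: each syllable's normalized entropy is
        first multiplied by ``w_s = F_s / F_mostfrequent`` (its frequency
        as a leading syllable relative to the most frequent one), damping
        rare syllables; the weighted values are then averaged.
    legacy_hmax
        When end-of-motif transitions are included, the normalization
        ceiling defaults to ``log2(n_unique + 1)`` — END counts as one
        additional possible outcome, keeping every normalized entropy
        <= 1.  Set ``legacy_hmax=True`` to use ``log2(n_unique)`` instead,
        for sensitivity analysis.
    mode
        Override the recorded mode label; inferred from ``counts`` by
        default.

    Returns
    -------
    SequenceVariabilityResult
        With ``motif_stereotypy = 1 - motif_entropy`` and
        ``stereotypy_scaled = 100 * motif_stereotypy``.
    """
    if weighting not in ("standard", "weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    symbols = model.symbols
    if not symbols:
        raise ValueError("empty transition model")
    n_unique = len(counts.alphabet)
    n_out = n_unique + 1 if (counts.end_included and not legacy_hmax) else n_unique
    h_max = max_entropy(n_out)

    raw = {s: syllable_entropy(model, s) for s in symbols}
    norm = {s: normalized_entropy(raw[s], h_max) for s in symbols}
    f_max = max(counts.frequency[s] for s in symbols)
    weights = {s: counts.frequency[s] / f_max for s in symbols}

    if weighting == "standard":
        me = float(np.mean([norm[s] for s in symbols]))
    else:
        me = float(np.mean([weights[s] * norm[s] for s in symbols]))

    return SequenceVariabilityResult(
        mode=mode or ("motif_based" if counts.end_included else "string_based"),
        weighting=weighting,
        raw_entropy=raw,
        h_max=h_max,
        normalized=norm,
        weights=weights,
        n_unique=n_unique,
        motif_entropy=me,
    )


def percent_change(ns_value: float, ud_value: float) -> float:
    """Percent change from the non-singing to the singing condition.

    ``100 * (ud - ns) / ns``; negative when the singing-condition value is
    lower (e.g. reduced stereotypy after two hours of practice).
    """
    if ns_value == 0:
        raise ValueError("percent change undefined for ns_value = 0")
    return 100.0 * (ud_value - ns_value) / ns_value


def analyze_sequences(
    sequences: Union[MotifSet, SyllableString, Iterable[Sequence[Label]]],
    include_end: bool = True,
    weighting: str = "standard",
    legacy_hmax: bool = False,
) -> SequenceVariabilityResult:
    """One-call convenience: count, estimate, and score a sequence set."""
    if isinstance(sequences, SyllableString):
        include_end = False
    counts = count_transitions(sequences, include_end=include_end)
    model = transition_probabilities(counts)
    return motif_entropy(model, counts, weighting=weighting, legacy_hmax=legacy_hmax)
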