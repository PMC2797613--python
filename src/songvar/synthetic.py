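"""Synthetic song data with known ground truth.

Generates the inputs the analysis pipeline consumes — motif files,
300-syllable strings, and per-rendition acoustic-feature tables — from a
one-parameter family of Markov syllable chains.  Syllable ``i``'s
outgoing row mixes a deterministic cycle (``i`` always followed by
``i+1``) with a uniform distribution:

    p(i -> successor) = (1 - eps) + eps / n,    p(i -> other) = eps / n

so ``eps = 0`` gives a perfectly stereotyped cyclic motif (normalized
entropy 0) and ``eps = 1`` a uniform chain (normalized entropy 1), with a
closed-form normalized row entropy in between — ideal as an oracle for
the entropy estimator.

Paired two-condition datasets emulate the within-bird study design: each
bird receives one epsilon per condition (the singing condition more
entropic than the non-singing one), drawn around the condition means from
a truncated Gaussian to model between-bird heterogeneity, plus
condition-dependent CV multipliers for the acoustic features.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import (
    MotifSet,
    SyllableString,
    write_feature_table,
    write_motif_file,
    write_syllable_string,
)
from .sequence import TransitionModel

__all__ = [
    "ChainSpec",
    "EffectSpec",
    "BirdData",
    "PairedDataset",
    "DEFAULT_FEATURE_MEANS",
    "chain_row_entropy",
    "make_transition_matrix",
    "sample_motifs",
    "sample_syllable_string",
    "sample_feature_renditions",
    "make_paired_dataset",
]

#: Realistic per-feature rendition means for a harmonic zebra-finch
#: syllable: duration (s), amplitude (dB), pitch (Hz), FM, Wiener entropy
#: (log scale, <= 0), mean frequency (Hz), pitch goodness.
DEFAULT_FEATURE_MEANS = {
    "duration": 0.085,
    "amplitude": 70.0,
    "pitch": 700.0,
    "FM": 25.0,
    "wiener_entropy": -2.0,
    "mean_frequency": 3000.0,
    "pitch_goodness": 300.0,
}

#: Features that are physically positive and get truncated at zero.
POSITIVE_FEATURES = ("duration", "pitch", "mean_frequency")


@dataclass
class ChainSpec:
    """Parameters of one cycle/uniform mixture syllable chain.

    ``epsilon`` is the mixing weight: 0 = deterministic cycle, 1 =
    uniform.  Motifs are ``motif_length`` syllables long unless
    ``end_prob`` is set, in which case each step after the first
    terminates the motif with that probability.
    """

    n_syllables: int = 5
    epsilon: float = 0.2
    motif_length: int = 5
    end_prob: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_syllables < 2:
            raise ValueError("need at least 2 syllables")
        if not 0 <= self.epsilon <= 1:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.motif_length < 1:
            raise ValueError("motif_length must be >= 1")
        if self.end_prob is not None and not 0 < self.end_prob < 1:
            raise ValueError("end_prob must lie in (0, 1)")


def chain_row_entropy(epsilon: float, n: int) -> float:
    """Closed-form normalized row entropy h(eps, n) of the mixture chain.

    Every row has one probability ``(1 - eps) + eps/n`` (the cycle
    successor) and ``n - 1`` probabilities ``eps/n``; h is the Shannon
    entropy of that row divided by log2(n).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 <= epsilon <= 1:
        raise ValueError("epsilon must lie in [0, 1]")
    p_succ = (1.0 - epsilon) + epsilon / n
    p_other = epsilon / n
    h = 0.0
    for p, mult in ((p_succ, 1), (p_other, n - 1)):
        if p > 0:
            h -= mult * p * math.log2(p)
    return h / math.log2(n)


def make_transition_matrix(spec: ChainSpec) -> tuple[TransitionModel, float]:
    """Build the mixture chain's transition model and its analytic entropy.

    Returns ``(model, h_norm)`` where the model is over integer labels
    ``1..n`` (no end-of-motif outcome; END transitions arise at motif
    sampling time) and ``h_norm`` is the closed-form normalized row
    entropy shared by every row.
    """
    n, eps = spec.n_syllables, spec.epsilon
    labels = list(range(1, n + 1))
    p = {}
    for i, lab in enumerate(labels):
        succ = labels[(i + 1) % n]
        row = {out: eps / n for out in labels}
        row[succ] += 1.0 - eps
        # drop exact zeros so support matches the sampled data at eps=0
        p[lab] = {out: v for out, v in row.items() if v > 0}
    model = TransitionModel(alphabet=frozenset(labels), end_included=False, p=p)
    return model, chain_row_entropy(eps, n)


def _row_tables(model: TransitionModel) -> dict:
    """Per-symbol (outcomes, cumulative probabilities) for fast sampling."""
    tables = {}
    for sym, row in model.p.items():
        outs = list(row)
        cum = np.cumsum([row[o] for o in outs])
        cum[-1] = 1.0
        tables[sym] = (outs, cum)
    return tables


def _walk(model: TransitionModel, start, length: int, rng: np.random.Generator) -> list:
    tables = _row_tables(model)
    symbols = [start]
    cur = start
    draws = rng.random(length - 1)
    for u in draws:
        outs, cum = tables[cur]
        cur = outs[int(np.searchsorted(cum, u, side="right"))]
        symbols.append(cur)
    return symbols


def sample_motifs(
    model: TransitionModel,
    spec: ChainSpec,
    n_motifs: int = 20,
    seed: Optional[int] = None,
    bird_id: str = "",
    condition: str = "",
) -> MotifSet:
    """Sample a motif set by walking the chain.

    Every motif starts at syllable 1 (the canonical motif onset) and runs
    for ``spec.motif_length`` steps, or until the per-step ``end_prob``
    termination fires.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    rng = np.random.default_rng(seed)
    start = min(model.alphabet)
    motifs = []
    for _ in range(n_motifs):
        if spec.end_prob is None:
            motifs.append(_walk(model, start, spec.motif_length, rng))
        else:
            m = [start]
            cur = start
            while rng.random() >= spec.end_prob:
                row = model.p[cur]
                outs = list(row)
                probs = np.array([row[o] for o in outs])
                cur = outs[rng.choice(len(outs), p=probs)]
                m.append(cur)
            motifs.append(m)
    return MotifSet(motifs=motifs, bird_id=bird_id, condition=condition)


def sample_syllable_string(
    model: TransitionModel,
    length: int = 300,
    seed: Optional[int] = None,
    bird_id: str = "",
    condition: str = "",
) -> SyllableString:
    """Sample one continuous chain walk of the requested length (no END)."""
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(seed)
    start = min(model.alphabet)
    return SyllableString(
        symbols=_walk(model, start, length, rng),
        bird_id=bird_id,
        condition=condition,
        nominal_length=length,
    )


def sample_feature_renditions(
    means: dict,
    cv: Union[float, dict],
    n: int = 25,
    seed: Optional[int] = None,
    bird_id: str = "bird1",
    syllable: str = "a",
    condition: str = "NS-UD",
) -> pd.DataFrame:
    """Sample n renditions of one syllable's acoustic features.

    Each feature is an independent Gaussian draw with SD = cv x |mean|;
    physically positive features (duration, pitch, mean frequency) are
    truncated just above zero.  ``cv`` may be a scalar or a per-feature
    mapping.
    """
    if n < 2:
        raise ValueError("need n >= 2 renditions")
    cvs = {f: cv for f in means} if np.isscalar(cv) else dict(cv)
    if any(v < 0 for v in cvs.values()):
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    data = {
        "bird": bird_id,
        "syllable": syllable,
        "condition": condition,
        "rendition": np.arange(1, n + 1),
    }
    for feat, mu in means.items():
        sd = cvs.get(feat, 0.0) * abs(mu)
        vals = rng.normal(mu, sd, size=n) if sd > 0 else np.full(n, float(mu))
        if feat in POSITIVE_FEATURES:
            vals = np.maximum(vals, 1e-9)
        data[feat] = vals
    return pd.DataFrame(data)


@dataclass
class EffectSpec:
    """Design of a paired two-condition synthetic study.

    Defaults mirror the strong-effect regime: 11 birds, non-singing
    condition epsilon 0.2, singing condition epsilon 0.4 (gap 0.2),
    between-bird epsilon SD 0.05, 5 syllables, 20 motifs of 5 syllables
    and one 300-syllable string per condition, 25 feature renditions per
    syllable with CV 0.074 in the non-singing condition and 1.5x that
    after singing.  Inflating ``eps_sd`` emulates the noisier
    younger-bird regime where within-condition variability swamps the
    conditional effect.
    """

    n_birds: int = 11
    eps_ns: float = 0.2
    eps_ud: float = 0.4
    eps_sd: float = 0.05
    n_syllables: int = 5
    motif_length: int = 5
    n_motifs: int = 20
    string_length: int = 300
    feature_means: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_MEANS))
    cv_ns: float = 0.074
    cv_ud_multiplier: float = 1.5
    n_renditions: int = 25

    def __post_init__(self) -> None:
        if self.n_birds < 2:
            raise ValueError("need at least 2 birds")
        for e in (self.eps_ns, self.eps_ud):
            if not 0 <= e <= 1:
                raise ValueError("epsilons must lie in [0, 1]")
        if self.eps_sd < 0:
            raise ValueError("eps_sd must be >= 0")


@dataclass
class BirdData:
    """One bird's generated inputs and ground truth, per condition."""

    bird_id: str
    epsilon: dict            # condition -> epsilon actually drawn
    true_entropy: dict       # condition -> closed-form h(eps, n)
    motifs: dict             # condition -> MotifSet
    string: dict             # condition -> SyllableString
    features: dict           # condition -> per-rendition DataFrame


@dataclass
class PairedDataset:
    effect: EffectSpec
    seed: int
    birds: list

    def feature_table(self) -> pd.DataFrame:
        """All birds' feature renditions, both conditions, one frame."""
        frames = [
            b.features[c] for b in self.birds for c in ("NS-UD", "UD-UD")
        ]
        return pd.concat(frames, ignore_index=True)

    def ground_truth(self) -> dict:
        return {
            b.bird_id: {
                "epsilon": b.epsilon,
                "true_entropy": b.true_entropy,
            }
            for b in self.birds
        }


def _draw_epsilon(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Truncated-Gaussian epsilon draw on [0, 1]."""
    if sd == 0:
        return mean
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return float(
        sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
    )


def make_paired_dataset(
    effect: EffectSpec,
    seed: int = 0,
    outdir: Optional[Union[str, Path]] = None,
) -> PairedDataset:
    """Generate a full paired two-condition dataset for ``n_birds`` birds.

    For each bird, one epsilon is drawn per condition (truncated Gaussian
    around the condition mean), a chain is built per condition, and the
    condition's motif file, syllable string, and feature renditions are
    sampled.  Ground-truth per-bird epsilons and closed-form entropies are
    returned for recovery tests.  With ``outdir`` set, all inputs are also
    written in the pipeline's text/CSV formats plus a ground-truth JSON;
    identical seeds give byte-identical files.
    """
    rng = np.random.default_rng(seed)
    cond_eps = {"NS-UD": effect.eps_ns, "UD-UD": effect.eps_ud}
    birds = []
    for i in range(effect.n_birds):
        bird_id = f"bird{i + 1:02d}"
        epsilon, true_h, motifs, strings, feats = {}, {}, {}, {}, {}
        for cond, mean_eps in cond_eps.items():
            eps = _draw_epsilon(mean_eps, effect.eps_sd, rng)
            spec = ChainSpec(
                n_syllables=effect.n_syllables,
                epsilon=eps,
                motif_length=effect.motif_length,
            )
            model, h = make_transition_matrix(spec)
            epsilon[cond] = eps
            true_h[cond] = h
            motifs[cond] = sample_motifs(
                model,
                spec,
                n_motifs=effect.n_motifs,
                seed=int(rng.integers(2**31)),
                bird_id=bird_id,
                condition=cond,
            )
            strings[cond] = sample_syllable_string(
                model,
                length=effect.string_length,
                seed=int(rng.integers(2**31)),
                bird_id=bird_id,
                condition=cond,
            )
            cv = effect.cv_ns * (
                effect.cv_ud_multiplier if cond == "UD-UD" else 1.0
            )
            feats[cond] = sample_feature_renditions(
                effect.feature_means,
                cv,
                n=effect.n_renditions,
                seed=int(rng.integers(2**31)),
                bird_id=bird_id,
                syllable="a",
                condition=cond,
            )
        birds.append(
            BirdData(
                bird_id=bird_id,
                epsilon=epsilon,
                true_entropy=true_h,
                motifs=motifs,
                string=strings,
                features=feats,
            )
        )
    ds = PairedDataset(effect=effect, seed=seed, birds=birds)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for b in ds.birds:
            for cond in ("NS-UD", "UD-UD"):
                tag = cond.replace("-", "")
                write_motif_file(b.motifs[cond], outdir / f"{b.bird_id}_{tag}.motifs.txt")
                write_syllable_string(
                    b.string[cond], outdir / f"{b.bird_id}_{tag}.string.txt"
                )
        write_feature_table(ds.feature_table(), outdir / "features.csv")
        (outdir / "ground_truth.json").write_text(
            json.dumps(
                {"effect": asdict(effect), "seed": seed, "birds": ds.ground_truth()},
                indent=2,
            )
        )
    return ds
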