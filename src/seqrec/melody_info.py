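"""Information content and entropy of melodic sequences.

An n-gram model over MIDI pitches supplies, for every tone, the conditional
probability p(e_i | preceding context).  Two quantities are derived from it:

* information content, ``IC_i = log2(1 / p_i)`` — the minimum number of bits
  needed to encode tone ``e_i`` given its context (high IC = surprising tone);
* entropy, ``H(context) = sum_e p(e) * log2(1 / p(e))`` over the alphabet —
  the uncertainty about the upcoming tone (0 when one continuation is
  certain, ``log2 |A|`` when all continuations are equally likely).

The model is a deliberately small stand-in for full multiple-viewpoint
predictive models of music: a single pitch viewpoint, additive smoothing, and
suffix back-off for short contexts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synth import MelodicSequence

Context = tuple[int, ...]


@dataclass
class NGramModel:
    """Additively smoothed n-gram model over a pitch alphabet.

    ``counts[k]`` maps (context of length k, event) -> occurrence count, for
    every k from 0 (unigram) up to ``order``.  Contexts shorter than the model
    order (sequence starts) and unseen contexts fall back to the longest
    suffix with observed counts, then to the unigram distribution.
    """

    order: int
    alphabet: tuple[int, ...]
    counts: dict[int, dict[tuple[Context, int], int]]
    smoothing: float = 0.5

    def _context_total(self, k: int, context: Context) -> int:
        if not hasattr(self, "_totals"):
            totals: dict[int, dict[Context, int]] = {}
            for kk, table in self.counts.items():
                t: dict[Context, int] = {}
                for (ctx, _), c in table.items():
                    t[ctx] = t.get(ctx, 0) + c
                totals[kk] = t
            object.__setattr__(self, "_totals", totals)
        return self._totals[k].get(context, 0)

    def probability(self, event: int, context: Sequence[int]) -> float:
        """p(event | context) with suffix back-off and additive smoothing."""
        context = tuple(context)[-self.order:] if self.order > 0 else ()
        a = len(self.alphabet)
        for k in range(len(context), -1, -1):
            ctx = context[len(context) - k:]
            total = self._context_total(k, ctx)
            if total > 0 or k == 0:
                c = self.counts[k].get((ctx, event), 0)
                denom = total + self.smoothing * a
                if denom == 0:  # empty corpus cannot happen post-fit
                    return 0.0
                return (c + self.smoothing) / denom
        raise AssertionError("unreachable: unigram level always answers")

    def distribution(self, context: Sequence[int]) -> np.ndarray:
        """Conditional distribution over the alphabet, normalized."""
        p = np.array([self.probability(e, context) for e in self.alphabet])
        total = p.sum()
        return p / total if total > 0 else p


def fit_ngram(
    corpus: Iterable[MelodicSequence | Sequence[int]],
    order: int = 2,
    smoothing: float = 0.5,
) -> NGramModel:
    """Tally (context, event) occurrences over a corpus of pitch sequences.

    All context lengths 0..order are tallied so back-off has counts at every
    level.  ``smoothing`` is the additive constant per event (default 0.5,
    which keeps unseen continuations finite-cost without washing out the
    empirical distribution).
    """
    if order < 1:
        raise ValueError("model order must be >= 1")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    sequences = [
        tuple(s.pitches) if isinstance(s, MelodicSequence) else tuple(s)
        for s in corpus
    ]
    if not sequences:
        raise ValueError("corpus is empty")
    alphabet = tuple(sorted({p for seq in sequences for p in seq}))
    counts: dict[int, dict[tuple[Context, int], int]] = {
        k: {} for k in range(order + 1)
    }
    for seq in sequences:
        for i, event in enumerate(seq):
            for k in range(order + 1):
                if i - k < 0:
                    continue
                key = (seq[i - k:i], event)
                counts[k][key] = counts[k].get(key, 0) + 1
    return NGramModel(order, alphabet, counts, smoothing)


def information_content(
    model: NGramModel, sequence: MelodicSequence | Sequence[int]
) -> np.ndarray:
    """Per-tone IC in bits: ``-log2 p(e_i | context)``.

    A zero-probability tone under an unsmoothed model yields ``inf`` (the tone
    is unencodable under the model); callers should check ``np.isinf``.
    """
    pitches = (sequence.pitches if isinstance(sequence, MelodicSequence)
               else tuple(sequence))
    ic = np.empty(len(pitches))
    for i, e in enumerate(pitches):
        p = model.probability(e, pitches[max(0, i - model.order):i])
        ic[i] = np.inf if p == 0 else -np.log2(p)
    return ic


def entropy(model: NGramModel, context: Sequence[int]) -> float:
    """Shannon entropy (bits) of the continuation distribution for a context,
    with the convention ``0 * log2(1/0) = 0``."""
    p = model.distribution(context)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum() + 0.0)  # +0.0 avoids -0.0


@dataclass
class InfoProfile:
    """Per-tone IC and context entropy for one sequence, with summaries."""

    sequence_id: str
    ic: np.ndarray  # bits, one per tone
    h: np.ndarray   # bits, entropy of the context preceding each tone

    @property
    def mean_ic(self) -> float:
        return float(np.mean(self.ic))

    @property
    def mean_h(self) -> float:
        return float(np.mean(self.h))


def profile(model: NGramModel,
            sequence: MelodicSequence | Sequence[int]) -> InfoProfile:
    """IC of every tone plus the entropy of each tone's predictive context."""
    pitches = (sequence.pitches if isinstance(sequence, MelodicSequence)
               else tuple(sequence))
    sid = sequence.id if isinstance(sequence, MelodicSequence) else ""
    ic = information_content(model, pitches)
    h = np.array([
        entropy(model, pitches[max(0, i - model.order):i])
        for i in range(len(pitches))
    ])
    return InfoProfile(sid, ic, h)


def matching_report(
    memorized: Sequence[MelodicSequence],
    novel: Sequence[MelodicSequence],
    model: NGramModel,
) -> pd.DataFrame:
    """Category-level mean +/- sd of per-tone IC and H, and their difference.

    This is the stimulus-matching check: well-matched categories have small
    IC/H differences.  Rows: memorized, novel, difference (memorized - novel).
    """
    if not memorized or not novel:
        raise ValueError("both categories must be non-empty")

    def stats(seqs: Sequence[MelodicSequence]) -> tuple[float, float, float, float]:
        ics = np.concatenate([information_content(model, s) for s in seqs])
        hs = np.concatenate([profile(model, s).h for s in seqs])
        return (float(ics.mean()), float(ics.std(ddof=1)),
                float(hs.mean()), float(hs.std(ddof=1)))

    m = stats(memorized)
    n = stats(novel)
    return pd.DataFrame(
        {
            "mean_ic": [m[0], n[0], m[0] - n[0]],
            "sd_ic": [m[1], n[1], np.nan],
            "mean_h": [m[2], n[2], m[2] - n[2]],
            "sd_h": [m[3], n[3], np.nan],
        },
        index=["memorized", "novel", "difference"],
    )


def per_tone_table(model: NGramModel,
                   melodies: Sequence[MelodicSequence]) -> pd.DataFrame:
    """Long-format per-tone table (sequence id, position, pitch, IC, H)."""
    rows = []
    for mel in melodies:
        prof = profile(model, mel)
        for i, (pitch, _) in enumerate(mel.tones):
            rows.append({
                "sequence_id": mel.id, "category": mel.category,
                "position": i, "pitch": pitch,
                "ic_bits": prof.ic[i], "h_bits": prof.h[i],
            })
    return pd.DataFrame(rows)
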