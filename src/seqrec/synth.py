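"""Synthetic inputs for the melody-recognition pipeline.

Every downstream stage (decoding, cluster statistics, envelope connectivity,
melodic information content) is exercised on data produced here, with the
injected structure recorded in a :class:`GroundTruth` so that recovery can be
asserted.  The generators emulate the study conditions of an old/new auditory
recognition experiment: 80 trials (40 "memorized" + 40 "novel" five-tone
excerpts of 1,250 ms), 3,500 ms epochs with 100 ms of prestimulus at 150 Hz on
a 306-channel Elekta-like layout, and 90-parcel source time courses for the
connectivity analyses.

Signal model for sensor epochs
------------------------------
Both conditions receive an N100-like transient ~100 ms after each of the five
tone onsets (0, 250, 500, 750, 1,000 ms) over two temporal sensor patches.
The "memorized" condition additionally receives a sustained, spatially
localized difference waveform (a raised-cosine bump over ``effect_window`` on
``effect_sites``), which is the effect all recovery tests chase.  Sensor noise
is Gaussian, optionally mixed with a 1/f-shaped component; with
``effect_amplitude = 0`` the two conditions are exchangeable by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .layout import ChannelInfo, N_SITES, auditory_sites, make_channels

Category = Literal["memorized", "novel"]

#: MIDI pitch alphabet loosely spanning a C-minor octave, shared by the two
#: stimulus categories.
DEFAULT_PITCH_ALPHABET: tuple[int, ...] = (60, 62, 63, 65, 67, 68, 70, 72)

_AAL_STEMS = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup", "Temporal_Pole_Sup",
    "Temporal_Mid", "Temporal_Pole_Mid", "Temporal_Inf",
]

#: 90 non-cerebellar parcel labels (left/right pairs), AAL-style.
AAL90_LABELS: tuple[str, ...] = tuple(
    f"{stem}_{side}" for stem in _AAL_STEMS for side in ("L", "R")
)
N_PARCELS = 90
assert len(AAL90_LABELS) == N_PARCELS


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MelodicSequence:
    """A five-tone excerpt: (MIDI pitch, duration ms) events plus category."""

    tones: tuple[tuple[int, float], ...]
    category: Category
    id: str

    def __post_init__(self) -> None:
        if len(self.tones) != 5:
            raise ValueError("an excerpt carries exactly 5 tones")
        durations = {d for _, d in self.tones}
        if len(durations) > 1:
            raise ValueError("all tone durations must be equal")

    @property
    def pitches(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.tones)

    @property
    def duration_ms(self) -> float:
        return sum(d for _, d in self.tones)

    @property
    def tone_rate_hz(self) -> float:
        """Tone presentation rate in Hz (4 Hz for 250 ms tones)."""
        return 1000.0 / self.tones[0][1]


@dataclass(frozen=True)
class GroundTruth:
    """Record of every injected structure, stored alongside generated data."""

    effect_sites: frozenset[int] = frozenset()
    effect_window: tuple[float, float] = (0.55, 1.18)
    effect_amplitude: float = 0.0
    hub_parcels: frozenset[int] = frozenset()
    hub_band: tuple[float, float] = (2.0, 8.0)
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "effect_sites": sorted(self.effect_sites),
            "effect_window": list(self.effect_window),
            "effect_amplitude": self.effect_amplitude,
            "hub_parcels": sorted(self.hub_parcels),
            "hub_band": list(self.hub_band),
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            effect_sites=frozenset(d["effect_sites"]),
            effect_window=tuple(d["effect_window"]),
            effect_amplitude=d["effect_amplitude"],
            hub_parcels=frozenset(d["hub_parcels"]),
            hub_band=tuple(d["hub_band"]),
            rng_seed=d["rng_seed"],
        )


@dataclass
class EpochSet:
    """Trials x channels x samples sensor data with channel/trial metadata.

    ``data`` is in fT (magnetometers) or fT/cm (planar gradiometers); ``t0``
    is the epoch start relative to stimulus onset (negative = prestimulus).
    ``trials`` has one row per trial: condition, correct, rt_ms.
    """

    data: np.ndarray
    channels: list[ChannelInfo]
    sfreq: float
    t0: float
    trials: pd.DataFrame
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel metadata does not match data")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("trial metadata does not match data")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[2]) / self.sfreq

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def pick(self, kind: str) -> "EpochSet":
        """Sub-EpochSet with only channels of ``kind``."""
        idx = [i for i, ch in enumerate(self.channels) if ch.kind == kind]
        return EpochSet(
            self.data[:, idx, :], [self.channels[i] for i in idx],
            self.sfreq, self.t0, self.trials, self.ground_truth,
        )


@dataclass
class ParcelSet:
    """Trials x 90 parcels x samples source-space time courses."""

    data: np.ndarray
    sfreq: float
    role: Literal["task", "baseline"]
    parcel_names: tuple[str, ...] = AAL90_LABELS
    trials: pd.DataFrame | None = None
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, parcels, samples)")
        if self.data.shape[1] != len(self.parcel_names):
            raise ValueError("parcel names do not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# melodies
# ---------------------------------------------------------------------------

def _walk(rng: np.random.Generator, alphabet: np.ndarray, start: int,
          step_signs: Sequence[int]) -> list[int]:
    """Random contour walk over alphabet indices with prescribed step signs."""
    idx = [start]
    top = len(alphabet) - 1
    for s in step_signs:
        step = int(rng.integers(1, 3)) * s  # steps of 1 or 2 alphabet degrees
        nxt = idx[-1] + step
        if nxt < 0 or nxt > top:
            nxt = idx[-1] - step  # reflect at the alphabet edge
        idx.append(int(np.clip(nxt, 0, top)))
    return [int(alphabet[i]) for i in idx]


def generate_melodies(
    n_per_category: int = 40,
    tone_duration_ms: float = 250.0,
    pitch_alphabet: Sequence[int] = DEFAULT_PITCH_ALPHABET,
    seed: int = 0,
) -> list[MelodicSequence]:
    """Two matched categories of five-tone excerpts over a shared alphabet.

    "Memorized" excerpts follow an arch contour (rise then fall), "novel"
    ones a falling zigzag, so the categories are statistically separable in
    contour while drawing on the same pitches.  Returns
    ``2 * n_per_category`` sequences, each lasting ``5 * tone_duration_ms``.
    """
    if n_per_category < 1:
        raise ValueError("n_per_category must be >= 1")
    alphabet = np.unique(np.asarray(sorted(pitch_alphabet), dtype=int))
    if alphabet.size < 2:
        raise ValueError(
            "pitch alphabet needs at least 2 pitches to build two "
            "distinguishable contours"
        )
    rng = np.random.default_rng(seed)
    out: list[MelodicSequence] = []
    lo_starts = np.arange(0, max(1, alphabet.size // 3))
    hi_starts = np.arange(alphabet.size - max(1, alphabet.size // 3),
                          alphabet.size)
    for k in range(n_per_category):
        start = int(rng.choice(lo_starts))
        pitches = _walk(rng, alphabet, start, (+1, +1, -1, -1))
        out.append(MelodicSequence(
            tuple((p, tone_duration_ms) for p in pitches),
            "memorized", f"mem{k:03d}",
        ))
    for k in range(n_per_category):
        start = int(rng.choice(hi_starts))
        pitches = _walk(rng, alphabet, start, (-1, +1, -1, +1))
        out.append(MelodicSequence(
            tuple((p, tone_duration_ms) for p in pitches),
            "novel", f"nov{k:03d}",
        ))
    return out


# ---------------------------------------------------------------------------
# sensor epochs
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                slope: float = 1.0) -> np.ndarray:
    """1/f^slope-shaped Gaussian noise along the last axis, unit variance."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-slope / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _effect_window_shape(times: np.ndarray, start: float, stop: float,
                         taper: float = 0.25) -> np.ndarray:
    """Sustained effect waveform: a Tukey (tapered-cosine) window over
    [start, stop] — flat at 1 across the central part, cosine tapers at the
    edges — and 0 outside."""
    bump = np.zeros_like(times)
    inside = (times >= start) & (times <= stop)
    x = (times[inside] - start) / (stop - start)  # in [0, 1]
    w = np.ones_like(x)
    half = taper / 2.0
    left = x < half
    right = x > 1 - half
    w[left] = 0.5 * (1 + np.cos(np.pi * (x[left] / half - 1)))
    w[right] = 0.5 * (1 + np.cos(np.pi * ((x[right] - 1 + half) / half)))
    bump[inside] = w
    return bump


TONE_ONSETS_S: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)


def generate_epochs(
    n_trials_per_condition: int = 40,
    channels: list[ChannelInfo] | None = None,
    sfreq: float = 150.0,
    ground_truth: GroundTruth | None = None,
    noise_sd: float = 30.0,
    seed: int = 0,
    epoch_tmin: float = -0.1,
    epoch_tmax: float = 3.4,
    tone_amplitude: float = 40.0,
    pink_fraction: float = 0.3,
    pink_slope: float = 1.0,
    p_correct: float = 0.8,
    rt_median_ms: float = 1870.0,
    rt_sigma: float = 0.15,
) -> EpochSet:
    """Simulate one participant's evoked sensor epochs.

    Parameters mirror the study conditions: 40 + 40 trials of 3.5 s (0.1 s of
    prestimulus) at 150 Hz over the full 306-channel layout.  Reaction times
    are lognormal with median ``rt_median_ms`` and correctness is Bernoulli
    ``p_correct``, so the downstream correct-trial and fastest-trial selection
    rules are exercised.
    """
    if sfreq <= 0:
        raise ValueError("sfreq must be positive")
    if channels is None:
        channels = make_channels()
    gt = ground_truth if ground_truth is not None else GroundTruth(rng_seed=seed)
    if not all(0 <= s < N_SITES for s in gt.effect_sites):
        raise ValueError("effect sites outside the sensor layout")
    n_samples = int(round((epoch_tmax - epoch_tmin) * sfreq))
    times = epoch_tmin + np.arange(n_samples) / sfreq
    w0, w1 = gt.effect_window
    if gt.effect_amplitude != 0 and not (times[0] <= w0 < w1 <= times[-1] + 1e-9):
        raise ValueError("effect window outside the epoch")

    rng = np.random.default_rng(seed)
    n_channels = len(channels)
    n_trials = 2 * n_trials_per_condition

    # --- shared evoked response: N100-like transient after each tone onset
    transient = np.zeros(n_samples)
    for onset in TONE_ONSETS_S:
        transient += np.exp(-0.5 * ((times - onset - 0.1) / 0.035) ** 2)
    aud = set(auditory_sites().tolist())
    grid_cols = max(ch.pos2d[1] for ch in channels) + 1
    gains = np.zeros(n_channels)
    for i, ch in enumerate(channels):
        if ch.site not in aud:
            continue
        g = 0.6 + 0.4 * rng.random()
        if ch.kind == "magnetometer":
            # crude dipolar flip between the two sides of the helmet
            g *= 1.0 if ch.pos2d[1] < grid_cols / 2 else -1.0
        gains[i] = g
    evoked = tone_amplitude * gains[:, None] * transient[None, :]

    # --- condition difference on the effect sites, "memorized" only
    effect = np.zeros((n_channels, n_samples))
    if gt.effect_amplitude != 0 and gt.effect_sites:
        bump = _effect_window_shape(times, w0, w1)
        for i, ch in enumerate(channels):
            if ch.site not in gt.effect_sites:
                continue
            g = 0.5 + 0.5 * rng.random()
            if ch.kind == "magnetometer":
                g *= 1.0 if ch.site % 2 == 0 else -1.0
            effect[i] = gt.effect_amplitude * g * bump

    conditions = np.array(
        ["memorized"] * n_trials_per_condition + ["novel"] * n_trials_per_condition
    )
    order = rng.permutation(n_trials)
    conditions = conditions[order]

    data = np.empty((n_trials, n_channels, n_samples))
    white = rng.standard_normal(data.shape)
    if pink_fraction > 0:
        pink = _pink_noise(rng, data.shape, pink_slope)
        noise = np.sqrt(1 - pink_fraction) * white + np.sqrt(pink_fraction) * pink
    else:
        noise = white
    data[:] = evoked[None] + noise_sd * noise
    data[conditions == "memorized"] += effect[None]

    rt = rt_median_ms * np.exp(rng.normal(0.0, rt_sigma, size=n_trials))
    correct = rng.random(n_trials) < p_correct
    trials = pd.DataFrame(
        {"condition": conditions, "correct": correct, "rt_ms": rt}
    )
    return EpochSet(data, channels, sfreq, epoch_tmin, trials, gt)


# ---------------------------------------------------------------------------
# parcel time series
# ---------------------------------------------------------------------------

def _bandpass_noise(rng: np.random.Generator, n: int, sfreq: float,
                    band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to ``band`` via FFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    x = np.fft.irfft(spec * mask, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_parcels(
    n_trials: int = 80,
    sfreq: float = 150.0,
    ground_truth: GroundTruth | None = None,
    shared_envelope_r: float = 0.8,
    seed: int = 0,
    trial_len_s: float = 3.5,
    noise_sd: float = 1.0,
    hub_amplitude: float = 1.5,
    resting_len_s: float = 120.0,
    p_correct: float = 0.8,
    rt_median_ms: float = 1870.0,
    rt_sigma: float = 0.15,
) -> tuple[ParcelSet, ParcelSet]:
    """Simulate (task, baseline) 90-parcel source time courses.

    Hub parcels carry a phase-locked (evoked) band-limited carrier whose
    amplitude envelope is partially shared across hubs: each hub's envelope is
    modulated by ``(1 - r) + r * m(t)`` with a common slow modulator ``m`` and
    mixing weight ``r = shared_envelope_r``, so ``r = 0`` yields independent
    hubs and large ``r`` strongly correlated envelopes.  The baseline is
    pseudo-trials cut from a continuous resting record of pure noise (no hub
    structure).
    """
    if not 0.0 <= shared_envelope_r <= 1.0:
        raise ValueError("shared_envelope_r must lie in [0, 1]")
    gt = ground_truth if ground_truth is not None else GroundTruth(rng_seed=seed)
    lo, hi = gt.hub_band
    if not (0.0 < lo < hi < sfreq / 2.0):
        raise ValueError("hub band must lie inside (0, Nyquist)")
    if not all(0 <= p < N_PARCELS for p in gt.hub_parcels):
        raise ValueError("hub parcels outside the 90-parcel atlas")

    rng = np.random.default_rng(seed)
    n = int(round(trial_len_s * sfreq))

    # common slow modulator, positive, mean ~1
    slow = _bandpass_noise(rng, n, sfreq, (0.1, max(0.5, (hi - lo) / 8.0)))
    m = 1.0 + 0.8 * slow / max(np.abs(slow).max(), 1e-12)

    evoked = np.zeros((N_PARCELS, n))
    r = shared_envelope_r
    from scipy.signal import hilbert
    for p in sorted(gt.hub_parcels):
        carrier = _bandpass_noise(rng, n, sfreq, (lo, hi))
        # constant-envelope oscillation: the hub's analysis-band envelope is
        # then set by the (partially shared) modulator, not by the carrier's
        # own amplitude fluctuations
        phase = np.cos(np.angle(hilbert(carrier)))
        evoked[p] = hub_amplitude * phase * ((1.0 - r) + r * m)

    task_data = (
        evoked[None]
        + noise_sd * rng.standard_normal((n_trials, N_PARCELS, n))
    )
    half = n_trials // 2
    conditions = np.array(
        ["memorized"] * half + ["novel"] * (n_trials - half)
    )[rng.permutation(n_trials)]
    trials = pd.DataFrame({
        "condition": conditions,
        "correct": rng.random(n_trials) < p_correct,
        "rt_ms": rt_median_ms * np.exp(rng.normal(0.0, rt_sigma, n_trials)),
    })
    task = ParcelSet(task_data, sfreq, "task", AAL90_LABELS, trials, gt)

    resting = noise_sd * rng.standard_normal(
        (N_PARCELS, int(round(resting_len_s * sfreq)))
    )
    baseline = make_pseudo_trials(
        resting, n_trials=n_trials, trial_len=n,
        seed=int(rng.integers(0, 2**31)), sfreq=sfreq, ground_truth=gt,
    )
    return task, baseline


def make_pseudo_trials(
    resting: np.ndarray,
    n_trials: int = 80,
    trial_len: int | None = None,
    seed: int = 0,
    sfreq: float = 150.0,
    ground_truth: GroundTruth | None = None,
) -> ParcelSet:
    """Cut ``n_trials`` windows from a continuous resting record at random
    start points (overlap allowed), the connectivity baseline construction."""
    resting = np.asarray(resting)
    if resting.ndim != 2:
        raise ValueError("resting must be (parcels, samples)")
    n_total = resting.shape[1]
    if trial_len is None:
        trial_len = n_total
    if trial_len > n_total:
        raise ValueError("trial_len exceeds the resting record length")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, n_total - trial_len + 1, size=n_trials)
    data = np.stack([resting[:, s:s + trial_len] for s in starts])
    names = (AAL90_LABELS if resting.shape[0] == N_PARCELS
             else tuple(f"parcel{i}" for i in range(resting.shape[0])))
    return ParcelSet(data, sfreq, "baseline", names, None, ground_truth)


# ---------------------------------------------------------------------------
# behavior and cohorts
# ---------------------------------------------------------------------------

GROUPS = ("pianist", "non-pianist musician", "non-musician")


def generate_behavior(
    n_participants: int = 20,
    seed: int = 0,
    neural_gain: np.ndarray | None = None,
    coupling: float = 0.0,
) -> pd.DataFrame:
    """Per-participant behavioral scores.

    wm: WAIS-IV working-memory style index (mean 100, sd 15); liking: Likert
    -3..+3; familiarity: ordinal 1..6; msi: musical-engagement index (mean 70,
    sd 15).  With ``coupling > 0`` the continuous scores are correlated with
    the per-participant neural effect gain, so behavior-neural scans have a
    recoverable target.
    """
    rng = np.random.default_rng(seed)
    if neural_gain is None or coupling == 0.0:
        latent = rng.standard_normal(n_participants)
    else:
        g = (neural_gain - neural_gain.mean()) / max(neural_gain.std(), 1e-12)
        latent = coupling * g + np.sqrt(1 - coupling**2) * rng.standard_normal(
            n_participants
        )
    wm = 100 + 15 * (0.7 * latent + 0.7 * rng.standard_normal(n_participants))
    msi = 70 + 15 * (0.7 * latent + 0.7 * rng.standard_normal(n_participants))
    liking = np.clip(np.round(rng.normal(1.0, 1.5, n_participants)), -3, 3)
    familiarity = np.clip(
        np.round(rng.normal(2.5, 1.2, n_participants)), 1, 6
    )
    groups = [GROUPS[i % 3] for i in range(n_participants)]
    return pd.DataFrame({
        "participant": np.arange(n_participants),
        "group": groups,
        "wm": wm,
        "liking": liking.astype(int),
        "familiarity": familiarity.astype(int),
        "msi": msi,
        "accuracy": np.clip(rng.normal(0.8, 0.1, n_participants), 0.5, 1.0),
        "mean_rt": rng.normal(1890, 150, n_participants),
    })


@dataclass
class Cohort:
    """A group of synthetic participants sharing one ground truth.

    Epochs are generated lazily per participant (`epochs(i)`) so group-level
    pipelines can stream participants without holding the whole cohort in
    memory.
    """

    n_participants: int
    ground_truth: GroundTruth
    behavior: pd.DataFrame
    participant_seeds: tuple[int, ...]
    effect_gains: np.ndarray
    epoch_kwargs: dict = field(default_factory=dict)

    def epochs(self, i: int) -> EpochSet:
        gt = replace(
            self.ground_truth,
            effect_amplitude=self.ground_truth.effect_amplitude
            * float(self.effect_gains[i]),
        )
        return generate_epochs(
            ground_truth=gt, seed=self.participant_seeds[i],
            **self.epoch_kwargs,
        )


def generate_cohort(
    n_participants: int = 20,
    ground_truth: GroundTruth | None = None,
    seed: int = 0,
    gain_sd: float = 0.2,
    behavior_coupling: float = 0.0,
    **epoch_kwargs,
) -> Cohort:
    """Build a cohort (default 20 participants) with per-participant effect
    gains (lognormal, sd ``gain_sd`` on the log scale) and behavior scores."""
    gt = ground_truth if ground_truth is not None else GroundTruth(rng_seed=seed)
    ss = np.random.SeedSequence(seed)
    part_seeds = tuple(
        int(s) for s in ss.generate_state(n_participants + 1)[:-1] % (2**31)
    )
    rng = np.random.default_rng(ss.generate_state(n_participants + 1)[-1])
    gains = np.exp(rng.normal(0.0, gain_sd, n_participants))
    behavior = generate_behavior(
        n_participants, seed=int(rng.integers(0, 2**31)),
        neural_gain=gains, coupling=behavior_coupling,
    )
    return Cohort(n_participants, gt, behavior, part_seeds, gains, epoch_kwargs)


def melodies_to_json(melodies: Sequence[MelodicSequence]) -> str:
    return json.dumps([
        {"id": m.id, "category": m.category,
         "tones": [[p, d] for p, d in m.tones]}
        for m in melodies
    ], indent=1)


def melodies_from_json(text: str) -> list[MelodicSequence]:
    return [
        MelodicSequence(
            tuple((int(p), float(d)) for p, d in rec["tones"]),
            rec["category"], rec["id"],
        )
        for rec in json.loads(text)
    ]
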