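"""Synthetic personality-clustered EEG dataset generator.

Every downstream stage (preprocessing, clustering, the network, both
evaluation protocols) is exercised on this generator, since the real
personality+EEG dataset it emulates is access-restricted.

Generative model
----------------
* Personalities: isotropic unit Gaussians around cluster centres placed
  on a simplex (scaled unit basis vectors) so that every pair of
  centres is exactly ``cluster_sep`` apart in OCEAN space.
* EEG: per-channel 1/f (pink) background noise, unit scale.  On each
  cluster's configured informative channels, a band-limited sinusoid is
  added whose amplitude depends on the trial's latent binary state —
  valence drives a low-alpha (9.5 Hz) tone, arousal a theta (6 Hz)
  tone.  Odd-numbered clusters invert the state->amplitude mapping, so
  a model pooled across clusters sees contradictory evidence while a
  per-cluster model sees a clean contrast.
* Ratings: the latent state is mapped to the outer halves of the rating
  scales (valence -3..3, arousal 0..6) with uniform jitter that never
  crosses the scale midpoint, so a median split over balanced trials
  recovers the latent states exactly.
* Optional per-trial distractor tones, label-independent, on random
  non-informative channels (makes channel selection matter).

Deterministic given ``seed``.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocessing import Recording

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_dataset",
    "write_dataset",
    "load_dataset",
]

VALENCE_TONE_HZ = 9.5   # centre of the low-alpha band
AROUSAL_TONE_HZ = 6.0   # centre of the theta band
WEAK_STATE_GAIN = 0.25  # amplitude ratio of the weak latent state


@dataclass(frozen=True)
class GeneratorConfig:
    n_clusters: int = 3
    subjects_per_cluster: int = 5
    n_trials: int = 36
    n_channels: int = 8
    fs: float = 32.0
    trial_length_s: float = 60.0
    cluster_sep: float = 8.0
    signal_snr: float = 1.0
    informative_channels: dict[int, tuple[int, ...]] | None = None
    distractor_amp: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_clusters", "subjects_per_cluster", "n_trials", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cluster_sep < 0:
            raise ValueError("cluster_sep must be >= 0")
        if self.signal_snr < 0:
            raise ValueError("signal_snr must be >= 0")
        if self.fs <= 0 or self.trial_length_s <= 0:
            raise ValueError("fs and trial_length_s must be positive")
        if self.trial_length_s * self.fs < self.fs:  # one analysis window = 1 s
            raise ValueError("trial shorter than one analysis window")
        ic = self.informative_channels
        if ic is None:
            # default: cluster c marks channel (2c) mod M as informative
            ic = {c: ((2 * c) % self.n_channels,) for c in range(self.n_clusters)}
        else:
            ic = {int(k): tuple(int(j) for j in v) for k, v in ic.items()}
        if set(ic) != set(range(self.n_clusters)):
            raise ValueError("informative_channels keys must cover 0..n_clusters-1")
        for c, chans in ic.items():
            if any(not 0 <= j < self.n_channels for j in chans):
                raise ValueError(f"cluster {c}: channel index out of range")
        object.__setattr__(self, "informative_channels", ic)

    @property
    def n_subjects(self) -> int:
        return self.n_clusters * self.subjects_per_cluster

    @property
    def trial_samples(self) -> int:
        return int(round(self.trial_length_s * self.fs))


@dataclass
class SyntheticDataset:
    recordings: list[Recording]
    personalities: dict[str, tuple]                 # subject -> 5-vector
    ratings: dict[tuple[str, int], tuple[float, float]]   # (subject, trial) -> (v, a)
    true_cluster: dict[str, int]
    true_states: dict[tuple[str, int], tuple[int, int]]   # latent (valence, arousal) bits
    true_informative_channels: dict[int, tuple[int, ...]]
    config: GeneratorConfig

    def __post_init__(self):
        keys = {(r.subject_id, r.trial_id) for r in self.recordings}
        if len(keys) != len(self.recordings):
            raise ValueError("duplicate (subject, trial) recordings")
        if keys != set(self.ratings):
            raise ValueError("recordings and ratings must cover identical (subject, trial) pairs")
        for p in self.personalities.values():
            if len(p) != 5:
                raise ValueError("personality vectors must have 5 components")

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.personalities)


def _cluster_centres(n_clusters: int, sep: float) -> np.ndarray:
    """Centres in OCEAN space with pairwise distance exactly ``sep``."""
    dims = 5
    centres = np.zeros((n_clusters, dims))
    for c in range(n_clusters):
        centres[c, c % dims] += (sep / np.sqrt(2.0)) * (1 + c // dims)
    return centres


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    """1/f-amplitude-shaped Gaussian noise, unit variance per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.ones_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    shaping[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    return x / np.where(std > 0, std, 1.0)


def _balanced_states(rng: np.random.Generator, n: int) -> np.ndarray:
    """Binary vector with floor(n/2) ones (plus a coin for odd n), shuffled."""
    ones = n // 2 + (rng.integers(2) if n % 2 else 0)
    states = np.array([1] * ones + [0] * (n - ones))
    rng.shuffle(states)
    return states


def _rating(rng: np.random.Generator, state: int, lo: float, hi: float) -> float:
    """Map a latent bit to the outer half of [lo, hi]; jitter stays off-centre."""
    span = (hi - lo) / 4.0
    if state:
        return float(rng.uniform(hi - span, hi))
    return float(rng.uniform(lo, lo + span))


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a full dataset: subjects, personalities, ratings and EEG."""
    rng = np.random.default_rng(config.seed)
    centres = _cluster_centres(config.n_clusters, config.cluster_sep)
    L = config.trial_samples
    t = np.arange(L) / config.fs

    recordings: list[Recording] = []
    personalities: dict[str, tuple] = {}
    ratings: dict[tuple[str, int], tuple[float, float]] = {}
    true_cluster: dict[str, int] = {}
    true_states: dict[tuple[str, int], tuple[int, int]] = {}

    n_subjects = config.n_subjects
    width = max(2, len(str(n_subjects - 1)))
    sid_fmt = f"S{{:0{width}d}}"

    for c in range(config.n_clusters):
        flip = c % 2 == 1  # odd clusters invert the state->amplitude mapping
        info = config.informative_channels[c]
        for s in range(config.subjects_per_cluster):
            sid = sid_fmt.format(c * config.subjects_per_cluster + s)
            personalities[sid] = tuple(centres[c] + rng.standard_normal(5))
            true_cluster[sid] = c
            v_states = _balanced_states(rng, config.n_trials)
            a_states = _balanced_states(rng, config.n_trials)
            for k in range(config.n_trials):
                vs, as_ = int(v_states[k]), int(a_states[k])
                x = _pink_noise(rng, config.n_channels, L)
                for state, tone_hz in ((vs, VALENCE_TONE_HZ), (as_, AROUSAL_TONE_HZ)):
                    eff = state != flip  # XOR: which latent value carries the strong tone
                    amp = config.signal_snr * (1.0 if eff else WEAK_STATE_GAIN)
                    phase = rng.uniform(0, 2 * np.pi)
                    tone = amp * np.sin(2 * np.pi * tone_hz * t + phase)
                    for j in info:
                        x[j] += tone
                if config.distractor_amp > 0:
                    others = [j for j in range(config.n_channels) if j not in info]
                    if others:
                        j = others[rng.integers(len(others))]
                        hz = rng.uniform(4.0, 14.0)
                        amp = config.distractor_amp * rng.uniform(0.5, 1.5)
                        x[j] += amp * np.sin(2 * np.pi * hz * t + rng.uniform(0, 2 * np.pi))
                recordings.append(Recording(sid, k, x, config.fs))
                ratings[(sid, k)] = (_rating(rng, vs, -3.0, 3.0),
                                     _rating(rng, as_, 0.0, 6.0))
                true_states[(sid, k)] = (vs, as_)

    return SyntheticDataset(
        recordings=recordings,
        personalities=personalities,
        ratings=ratings,
        true_cluster=true_cluster,
        true_states=true_states,
        true_informative_channels=dict(config.informative_channels),
        config=config,
    )


# ----------------------------------------------------------------------- I/O

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_dataset(dataset: SyntheticDataset, directory) -> dict:
    """Write the dataset as delimited text; returns the manifest dict.

    Layout: ``signals/<subject>_trial<k>.csv`` (one row per channel),
    ``personalities.csv`` (subject_id,O,C,E,A,N), ``ratings.csv``
    (subject_id,trial_id,valence,arousal) and ``manifest.json`` with
    per-file SHA-256 checksums.
    """
    if not dataset.recordings:
        raise ValueError("refusing to write an empty dataset")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sigdir = directory / "signals"
    sigdir.mkdir(exist_ok=True)

    entries = {}
    for rec in dataset.recordings:
        fname = f"{rec.subject_id}_trial{rec.trial_id:03d}.csv"
        path = sigdir / fname
        np.savetxt(path, rec.signal, delimiter=",", fmt="%.10g",
                   header=f"fs={rec.fs}", comments="# ")
        entries[f"signals/{fname}"] = _sha256(path)

    ppath = directory / "personalities.csv"
    with open(ppath, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "O", "C", "E", "A", "N"])
        for sid in dataset.subject_ids:
            w.writerow([sid] + [f"{v:.10g}" for v in dataset.personalities[sid]])
    entries["personalities.csv"] = _sha256(ppath)

    rpath = directory / "ratings.csv"
    with open(rpath, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "trial_id", "valence", "arousal"])
        for (sid, k) in sorted(dataset.ratings):
            v, a = dataset.ratings[(sid, k)]
            w.writerow([sid, k, f"{v:.10g}", f"{a:.10g}"])
    entries["ratings.csv"] = _sha256(rpath)

    manifest = {
        "n_subjects": len(dataset.personalities),
        "n_recordings": len(dataset.recordings),
        "fs": dataset.config.fs,
        "files": entries,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_dataset(directory):
    """Load signals, personalities and ratings written by :func:`write_dataset`.

    Returns ``(recordings, personalities, ratings)`` — ground-truth
    fields are not persisted and not reloaded.
    """
    directory = Path(directory)
    personalities: dict[str, tuple] = {}
    with open(directory / "personalities.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            personalities[row["subject_id"]] = tuple(
                float(row[k]) for k in ("O", "C", "E", "A", "N"))
    ratings: dict[tuple[str, int], tuple[float, float]] = {}
    with open(directory / "ratings.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            ratings[(row["subject_id"], int(row["trial_id"]))] = (
                float(row["valence"]), float(row["arousal"]))
    recordings = []
    for (sid, k) in sorted(ratings):
        path = directory / "signals" / f"{sid}_trial{k:03d}.csv"
        with open(path) as fh:
            header = fh.readline()
        fs = float(header.strip().lstrip("#").strip().split("=")[1])
        sig = np.loadtxt(path, delimiter=",", skiprows=1)
        recordings.append(Recording(sid, k, np.atleast_2d(sig), fs))
    return recordings, personalities, ratings
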