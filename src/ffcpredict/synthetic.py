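"""Synthetic per-frame feature tables with the study's session structure.

The laboratory videos behind the original study are not public, so this
module emulates the *output* of the upstream feature extractor: per-frame
head-pose rotations and AU intensity/presence channels for 4-participant
groups, organised into sessions (24 sessions, 127 groups in the original
design; subjects may recur across groups only within a session).

Channels are stationary first-order autoregressive (AR(1)) processes — the
simplest model with tunable smoothness.  AU intensities are AR(1) latents
clipped to [0, 5]; AU presence is the indicator that the latent exceeds a
per-channel threshold fixed at the 70th percentile of the stationary latent
distribution, which yields the sparse on/off activations typical of presence
streams.  A binary group label can shift the mean of selected channels inside
a chosen time window for all four members, giving the pipeline a controllable,
time-localisable effect to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .descriptors import SegmentSpec, segment_bounds
from .errors import ConfigurationError
from .io import (
    REGISTRY,
    Dataset,
    FrameFeatureTable,
    GroupRecord,
)

# Stationary process parameters per channel kind: (mean, sd, lag-1 autocorr).
POSE_PARAMS = (0.0, 0.15, 0.99)  # radians; slow head motion
AU_PARAMS = (0.5, 0.5, 0.97)  # latent intensity; sparse activity after clipping
PRESENCE_QUANTILE = 0.70


def _presence_threshold(mu: float, sd: float) -> float:
    """Per-channel presence threshold: the 70th percentile of the stationary
    latent distribution."""
    from scipy.stats import norm

    return float(norm.ppf(PRESENCE_QUANTILE, loc=mu, scale=sd))


@dataclass(frozen=True)
class SynthConfig:
    """Shape and process parameters of a synthetic dataset."""

    n_sessions: int = 24
    groups_per_session: int | tuple[int, ...] = 5
    fps: float = 25.0
    duration_s: float = 180.0
    pose_params: tuple[float, float, float] = POSE_PARAMS
    au_params: tuple[float, float, float] = AU_PARAMS
    participant_reuse: float = 0.3  # fraction of the per-session id pool saved by reuse
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ConfigurationError("n_sessions must be >= 1")
        if self.duration_s * self.fps < 15:
            raise ConfigurationError("duration_s * fps must be >= 15 frames")
        for mu, sd, phi in (self.pose_params, self.au_params):
            if sd <= 0:
                raise ConfigurationError("process variances must be positive")
            if not (0 <= phi < 1):
                raise ConfigurationError("autocorrelation must lie in [0, 1)")
        if not (0 <= self.participant_reuse < 1):
            raise ConfigurationError("participant_reuse must lie in [0, 1)")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def session_sizes(self) -> list[int]:
        if isinstance(self.groups_per_session, int):
            return [self.groups_per_session] * self.n_sessions
        sizes = list(self.groups_per_session)
        if len(sizes) != self.n_sessions:
            raise ConfigurationError("groups_per_session list must match n_sessions")
        return sizes


@dataclass(frozen=True)
class EffectSpec:
    """A time-localised, group-level mean shift distinguishing the labels.

    Label-1 groups get ``effect_size`` standard deviations added to each
    affected channel's latent mean inside ``window``, for all four members.
    Presence channels follow their AU's latent, so shifting an intensity also
    raises its presence rate.
    """

    effect_size: float = 0.0
    affected_channels: tuple[str, ...] = ("pose_Ry", "AU07_r", "AU17_r", "AU45_r")
    window: SegmentSpec = field(default_factory=lambda: SegmentSpec(3, (3,)))
    label_balance: float = 0.5

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if not (0 < self.label_balance < 1):
            raise ConfigurationError("label_balance must lie in (0, 1)")
        for ch in self.affected_channels:
            if ch not in REGISTRY.names:
                raise ConfigurationError(f"unknown affected channel {ch!r}")
            if REGISTRY.kind(ch) == "au_presence":
                raise ConfigurationError(
                    f"{ch!r}: presence channels follow their intensity latent; "
                    "shift the AU's intensity channel instead"
                )


NULL_EFFECT = EffectSpec()


# --------------------------------------------------------------------------
# Process generation
# --------------------------------------------------------------------------


def _ar1(n: int, cols: int, mu: float, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) columns: x_t = mu + phi (x_{t-1} - mu) + e_t."""
    eps = rng.standard_normal((n, cols)) * (sd * np.sqrt(1 - phi * phi))
    eps[0] = rng.standard_normal(cols) * sd  # stationary start
    x = _signal.lfilter([1.0], [1.0, -phi], eps, axis=0)
    return mu + x


def _effect_mask(n_frames: int, window: SegmentSpec) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    bounds = segment_bounds(n_frames, window.divisions)
    for p in window.parts:
        lo, hi = bounds[p - 1]
        mask[lo:hi] = True
    return mask


def generate_group(
    config: SynthConfig,
    effect: EffectSpec,
    label: int,
    rng: np.random.Generator,
    session_id: str = "S01",
    group_id: str = "S01G01",
    participant_ids: tuple[str, ...] | None = None,
) -> GroupRecord:
    """One 4-participant group's per-frame tables plus its label."""
    n = config.n_frames
    mu_p, sd_p, phi_p = config.pose_params
    mu_a, sd_a, phi_a = config.au_params
    thr = _presence_threshold(mu_a, sd_a)
    mask = _effect_mask(n, effect.window) if (label == 1 and effect.effect_size > 0) else None
    pids = participant_ids or tuple(f"{group_id}P{i + 1}" for i in range(4))
    n_int = len([c for c in REGISTRY.channels if c.kind == "au_intensity"])

    participants = []
    for pid in pids:
        pose = _ar1(n, 3, mu_p, sd_p, phi_p, rng)
        # one latent per AU; AU28 (presence-only) gets its own latent
        latents = _ar1(n, n_int + 1, mu_a, sd_a, phi_a, rng)
        values = np.empty((n, len(REGISTRY)))
        values[:, 0:3] = pose
        latent_of: dict[str, int] = {}
        col = 0
        for j, ch in enumerate(REGISTRY.channels):
            if ch.kind == "au_intensity":
                latent_of[ch.name[:4]] = col
                col += 1
        latent_of["AU28"] = col  # presence-only AU

        if mask is not None:
            for name in effect.affected_channels:
                j = REGISTRY.index(name)
                if REGISTRY.kind(name) == "pose":
                    pose_col = j  # pose channels are the first three
                    values[mask, pose_col] += effect.effect_size * sd_p
                else:
                    latents[mask, latent_of[name[:4]]] += effect.effect_size * sd_a

        for j, ch in enumerate(REGISTRY.channels):
            if ch.kind == "pose":
                continue  # already filled (and shifted) above
            elif ch.kind == "au_intensity":
                values[:, j] = np.clip(latents[:, latent_of[ch.name[:4]]], 0.0, 5.0)
            else:  # au_presence
                values[:, j] = (latents[:, latent_of[ch.name[:4]]] > thr).astype(float)

        participants.append(
            FrameFeatureTable(
                participant_id=pid,
                fps=config.fps,
                t=np.arange(n) / config.fps,
                valid=np.ones(n, dtype=bool),
                values=values,
            )
        )
    return GroupRecord(session_id, group_id, participants, int(label))


def generate_dataset(config: SynthConfig, effect: EffectSpec = NULL_EFFECT) -> Dataset:
    """A full dataset with the requested session structure.

    Participant ids are drawn from a per-session pool whose size shrinks with
    ``participant_reuse``, so subjects recur across groups only within their
    session; labels are Bernoulli(``label_balance``).
    """
    rng = np.random.default_rng(config.seed)
    groups: list[GroupRecord] = []
    for si, size in enumerate(config.session_sizes(), start=1):
        sid = f"S{si:02d}"
        pool_size = max(4, int(round(4 * size * (1 - config.participant_reuse))))
        pool = [f"{sid}P{j + 1:03d}" for j in range(pool_size)]
        for gi in range(1, size + 1):
            gid = f"{sid}G{gi:02d}"
            pids = tuple(rng.choice(pool, size=4, replace=False))
            label = int(rng.random() < effect.label_balance)
            groups.append(
                generate_group(config, effect, label, rng, sid, gid, pids)
            )
    return Dataset(groups)


def write_dataset(data: Dataset, out_dir) -> str:
    """Export a dataset in the pipeline's CSV dialect plus a group-metadata
    CSV; returns the metadata path."""
    import os

    import pandas as pd

    from .io import write_feature_csv

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for g in data.groups:
        for p in g.participants:
            fname = f"{g.group_id}_{p.participant_id}.csv"
            write_feature_csv(p, os.path.join(out_dir, fname))
            rows.append(
                {
                    "session_id": g.session_id,
                    "group_id": g.group_id,
                    "participant_id": p.participant_id,
                    "feature_csv_path": fname,
                    "label": g.label,
                }
            )
    meta_path = os.path.join(out_dir, "groups.csv")
    pd.DataFrame(rows).to_csv(meta_path, index=False)
    return meta_path
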