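"""Synthetic pose-estimation trials with known configuration-to-motif structure.

Each electrode configuration drives one latent movement motif: a stable
order-1 vector-autoregressive (VAR) process in a 3-dimensional latent space,
emitted through a linear map as keypoint offsets around a hindlimb rest
pose.  Trials alternate stimulation-ON epochs (motif dynamics) with OFF
epochs (exponential relaxation to rest), mirroring a 5 s ON / 5 s OFF duty
cycle recorded at 60 fps.  Two regimes are available:

* selective  — the configuration-to-motif assignment is injective, so each
  configuration elicits its own motor output (TIS-like behavior);
* nonselective — many configurations share few motifs, so distinct
  configurations collapse onto similar movements (biphasic-like behavior).

Tracking imperfections are emulated with additive Gaussian coordinate noise
and likelihood dropouts: a fraction of (frame, keypoint) cells receive a
confidence below 0.5 together with large erroneous coordinate jumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_BODYPARTS,
    KeypointSeries,
    read_dlc_csv,
    read_sweep_log,
    write_dlc_csv,
    write_sweep_log,
)

__all__ = [
    "Motif",
    "MotifLibrary",
    "TrialSpec",
    "MissingAssignmentError",
    "make_motif_library",
    "make_rest_pose",
    "generate_trial",
    "read_dlc_csv",
    "write_dlc_csv",
    "read_sweep_log",
    "write_sweep_log",
]

#: OFF-epoch relaxation time constant toward the rest pose (s).
OFF_RELAX_TAU_S = 0.25

#: Corrupted low-likelihood cells jump uniformly by up to this multiple of
#: the tracking-noise SD, emulating erroneous keypoint detections.
DROPOUT_JUMP_FACTOR = 20.0


class MissingAssignmentError(KeyError):
    """A scheduled configuration label has no motif assigned."""


@dataclass(frozen=True)
class Motif:
    """Stable order-1 VAR generator over a 3-dim latent.

    z_{t+1} = A z_t + d + noise_scale * N(0, I); spectral radius of A must
    be < 1 so trajectories stay bounded.
    """

    A: np.ndarray
    drive: np.ndarray
    noise_scale: float = 0.3

    def __post_init__(self) -> None:
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        object.__setattr__(self, "drive", np.asarray(self.drive, dtype=float))
        rho = np.max(np.abs(np.linalg.eigvals(self.A)))
        if rho >= 1:
            raise ValueError(f"motif AR matrix unstable (spectral radius {rho:.3f})")

    def latent_mean(self) -> np.ndarray:
        """Stationary mean (I - A)^-1 d of the deterministic recursion."""
        d = self.A.shape[0]
        return np.linalg.solve(np.eye(d) - self.A, self.drive)


@dataclass(frozen=True)
class MotifLibrary:
    """Motif generators, shared emission map, rest pose and label assignment."""

    motifs: tuple[Motif, ...]
    emission: np.ndarray  # (K, 2, latent_dim): latent -> keypoint offsets (px)
    rest_pose: np.ndarray  # (K, 2) baseline coordinates (px)
    assignment: dict[int, int]  # configuration label -> motif index
    bodyparts: tuple[str, ...] = DEFAULT_BODYPARTS

    def __post_init__(self) -> None:
        for label, idx in self.assignment.items():
            if not 0 <= idx < len(self.motifs):
                raise ValueError(f"label {label} assigned to missing motif {idx}")

    def motif_for(self, label: int) -> tuple[int, Motif]:
        if label not in self.assignment:
            raise MissingAssignmentError(
                f"configuration label {label} has no motif assigned"
            )
        idx = self.assignment[label]
        return idx, self.motifs[idx]


@dataclass(frozen=True)
class TrialSpec:
    """Study conditions for one synthetic trial.

    Defaults follow the recording protocol: 5 s stimulation ON then 5 s OFF
    per configuration, video at 60 fps.
    """

    n_configs: int
    mode: str = "TIS4"
    on_s: float = 5.0
    off_s: float = 5.0
    fps: float = 60.0
    dropout_rate: float = 0.02
    noise_px: float = 2.0
    seed: int = 0
    subject_id: str = "subject01"
    labels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.on_s <= 0 or self.off_s <= 0:
            raise ValueError("on_s and off_s must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.mode not in {"TIS4", "BP2", "TT3", "TL3"}:
            raise ValueError(f"unknown stimulation mode {self.mode!r}")

    @property
    def frames_per_config(self) -> int:
        return int(round((self.on_s + self.off_s) * self.fps))

    @property
    def n_frames(self) -> int:
        return self.n_configs * self.frames_per_config


def make_rest_pose(bodyparts: tuple[str, ...] = DEFAULT_BODYPARTS) -> np.ndarray:
    """Hindlimb-like arc: hip top-left, joints descending, toes fanned out."""
    K = len(bodyparts)
    # proximal chain hip->instep then a fan of five toes
    chain = np.array(
        [[180.0, 120.0], [230.0, 160.0], [270.0, 210.0], [260.0, 250.0], [300.0, 260.0]]
    )
    fan_angles = np.linspace(-0.5, 0.5, 5)
    toes = np.stack(
        [300.0 + 55 * np.cos(fan_angles), 260.0 + 55 * np.sin(fan_angles) + 20],
        axis=1,
    )
    pose = np.vstack([chain, toes])
    if K != pose.shape[0]:
        raise ValueError("rest pose is defined for the 10-keypoint hindlimb schema")
    return pose


def _stable_oscillator(rng: np.random.Generator, dim: int = 3) -> np.ndarray:
    """Random stable AR(1) matrix with damped-oscillation eigenstructure."""
    theta = rng.uniform(0.05, 0.35)
    rho = rng.uniform(0.85, 0.95)
    block = rho * np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    A = np.zeros((dim, dim))
    A[:2, :2] = block
    for i in range(2, dim):
        A[i, i] = rng.uniform(0.7, 0.9)
    # mix axes with a random rotation so motion is not axis-aligned
    Q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
    return Q @ A @ Q.T


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n well-spread unit vectors on the 2-sphere (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def make_motif_library(
    labels: list[int] | tuple[int, ...],
    regime: str = "selective",
    n_motifs: int | None = None,
    seed: int = 0,
    offset_px: float = 45.0,
    noise_scale: float = 0.1,
    latent_dim: int = 3,
    bodyparts: tuple[str, ...] = DEFAULT_BODYPARTS,
) -> MotifLibrary:
    """Build a motif library covering ``labels``.

    ``selective`` assigns one motif per label (injective); ``nonselective``
    maps the labels round-robin onto ``n_motifs`` (default 2) shared motifs.
    ``offset_px`` sets the typical keypoint displacement of a motif's
    stationary pose from rest, the dominant scale of stimulation-evoked limb
    movement relative to ~2 px tracking noise.  Motif stationary poses are
    placed at well-spread directions of the latent space (golden-angle
    spiral under a seeded random rotation) so that, by construction,
    different motifs are different movements; ``noise_scale`` sets the
    within-motif wobble around each stationary pose.
    """
    labels = tuple(int(v) for v in labels)
    if regime == "selective":
        n_motifs = len(labels)
        assignment = {lab: i for i, lab in enumerate(labels)}
    elif regime == "nonselective":
        n_motifs = n_motifs or 2
        assignment = {lab: i % n_motifs for i, lab in enumerate(labels)}
    else:
        raise ValueError(f"unknown regime {regime!r}")

    rng = np.random.default_rng(seed)
    K = len(bodyparts)
    emission = rng.normal(size=(K, 2, latent_dim))
    # normalize so a unit latent displaces keypoints by ~offset_px RMS
    emission *= offset_px / np.sqrt((emission**2).sum(axis=2).mean())

    if latent_dim != 3:
        raise ValueError("motif libraries are defined for a 3-dim latent")
    if regime == "selective":
        # well-spread stationary poses: each configuration its own movement
        directions = _fibonacci_sphere(n_motifs)
        rotation, _ = np.linalg.qr(rng.normal(size=(latent_dim, latent_dim)))
        directions = directions @ rotation.T
    else:
        # the shared motifs of a non-selective paradigm are variations of
        # the same gross movement: directions within a narrow cone
        u0 = rng.normal(size=latent_dim)
        u0 /= np.linalg.norm(u0)
        directions = u0 + 0.35 * rng.normal(size=(n_motifs, latent_dim))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)

    motifs = []
    for m in range(n_motifs):
        A = _stable_oscillator(rng, latent_dim)
        target_mean = directions[m]  # unit-norm mean -> ~offset_px displacement
        drive = (np.eye(latent_dim) - A) @ target_mean
        motifs.append(Motif(A=A, drive=drive, noise_scale=noise_scale))

    return MotifLibrary(
        motifs=tuple(motifs),
        emission=emission,
        rest_pose=make_rest_pose(bodyparts),
        assignment=assignment,
        bodyparts=bodyparts,
    )


def generate_trial(
    spec: TrialSpec, library: MotifLibrary
) -> tuple[KeypointSeries, pd.DataFrame, np.ndarray]:
    """Simulate one trial: keypoint series, epoch table, ground-truth states.

    During each configuration's ON epoch the latent follows that motif's VAR
    recursion from the origin; during OFF the emitted keypoint offset decays
    exponentially to the rest pose (time constant 0.25 s).  Tracking noise is
    additive Gaussian per coordinate; dropout cells get likelihood drawn in
    [0, 0.5) and a uniform coordinate jump up to 20x the noise SD.  Ground
    truth is the motif index per frame (-1 during OFF).
    """
    labels = spec.labels if spec.labels is not None else tuple(
        sorted(library.assignment)[: spec.n_configs]
    )
    if len(labels) != spec.n_configs:
        raise ValueError("label schedule length must equal n_configs")
    for lab in labels:
        library.motif_for(lab)  # raises MissingAssignmentError early

    rng = np.random.default_rng(spec.seed)
    fps = spec.fps
    on_f = int(round(spec.on_s * fps))
    off_f = int(round(spec.off_s * fps))
    T = spec.n_frames
    K = len(library.bodyparts)
    latent_dim = library.emission.shape[2]

    offsets = np.zeros((T, K, 2))
    states = np.full(T, -1, dtype=int)
    decay = float(np.exp(-1.0 / (OFF_RELAX_TAU_S * fps)))

    epoch_rows = []
    frame = 0
    for lab in labels:
        midx, motif = library.motif_for(lab)
        z = np.zeros(latent_dim)
        for t in range(frame, frame + on_f):
            eps = motif.noise_scale * rng.standard_normal(latent_dim)
            z = motif.A @ z + motif.drive + eps
            offsets[t] = library.emission @ z
            states[t] = midx
        last = offsets[frame + on_f - 1]
        for i, t in enumerate(range(frame + on_f, frame + on_f + off_f)):
            offsets[t] = last * decay ** (i + 1)
        epoch_rows.append(
            {
                "label": lab,
                "mode": spec.mode,
                "on_start": frame,
                "on_stop": frame + on_f,
                "off_start": frame + on_f,
                "off_stop": frame + on_f + off_f,
                "subject_id": spec.subject_id,
                "channels": "",
                "timestamp": pd.Timestamp("2000-01-01")
                + pd.to_timedelta(frame / fps, unit="s"),
            }
        )
        frame += on_f + off_f

    coords = library.rest_pose[None, :, :] + offsets
    if spec.noise_px > 0:
        coords = coords + spec.noise_px * rng.standard_normal(coords.shape)

    likelihood = rng.uniform(0.8, 1.0, size=(T, K))
    if spec.dropout_rate > 0:
        drop = rng.random((T, K)) < spec.dropout_rate
        likelihood[drop] = rng.uniform(0.0, 0.5, size=int(drop.sum()))
        jump = rng.uniform(
            -DROPOUT_JUMP_FACTOR * spec.noise_px,
            DROPOUT_JUMP_FACTOR * spec.noise_px,
            size=(int(drop.sum()), 2),
        )
        coords = coords.copy()
        coords[drop] += jump

    epochs = pd.DataFrame(epoch_rows)
    epochs["timestamp"] = epochs["timestamp"].astype(str)
    series = KeypointSeries(
        x=coords[:, :, 0],
        y=coords[:, :, 1],
        likelihood=likelihood,
        bodyparts=library.bodyparts,
        fps=fps,
        subject_id=spec.subject_id,
    )
    return series, epochs, states
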