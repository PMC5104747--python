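"""Offline rendering of the three filtered-noise sound models.

Movement drives sound: the speed of the tracked marker is normalized,
mapped to the center frequency and Q of a two-pole filter excited by white
noise, and to output amplitude (log-scaled, hard silence at rest).  The
models differ in band, Q range and amplitude behavior:

* **S1** — wind-like: resonant filter 50-1100 Hz, Q 1.8-4.0, slow (3 Hz)
  band-limited random amplitude envelope.
* **S2** — rougher: resonant filter 100-900 Hz, Q 0.1-0.3, fast (18 Hz)
  random amplitude envelope.
* **S3** — choppy/clicking: band-pass 100-3000 Hz, Q 0.01-0.6, amplitude
  gated by convex 250 ms ramps triggered every 800 ms (at rest) down to
  50 ms (full speed).

Position feeds an 8-speaker ring: the bearing from room center sets the
panning azimuth (pairwise constant-power), distance from center widens the
source toward uniform spread.  All randomness is seeded, so renders are
bit-reproducible.  Filters update block-wise at the control rate (10 ms
blocks at the default 100 Hz), which is below any audible stepping for
these glacial (movement-rate) parameter changes.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .features import FeatureConfig, speed
from .preprocess import AREA_HEIGHT, AREA_WIDTH
from .trajectory_io import Trajectory

__all__ = [
    "SoundModelParams",
    "ControlSignal",
    "RenderedAudio",
    "S1",
    "S2",
    "S3",
    "sound_model",
    "control_from_trajectory",
    "map_control",
    "amplitude_from_velocity",
    "render_model",
    "spatialize",
    "stereo_downmix",
    "write_audio",
    "read_audio",
]


@dataclass(frozen=True)
class SoundModelParams:
    """Synthesis parameters of one sound model."""

    model_id: str
    f_min: float
    f_max: float
    q_min: float
    q_max: float
    filter_kind: str                      # "resonant" | "bandpass"
    am_rate: float | None = None          # Hz; None = no random envelope
    ramp_length: float | None = None      # seconds (triggered-ramp models)
    trigger_interval_min: float | None = None
    trigger_interval_max: float | None = None
    ramp_curve: float = 4.0               # convexity of the trigger ramp
    faster_with_speed: bool = True        # triggers densify as speed rises

    def __post_init__(self) -> None:
        if not self.f_min < self.f_max:
            raise ValueError("need f_min < f_max")
        if not self.q_min <= self.q_max:
            raise ValueError("need q_min <= q_max")
        if self.filter_kind not in ("resonant", "bandpass"):
            raise ValueError(f"unknown filter_kind {self.filter_kind!r}")
        if self.trigger_interval_min is not None:
            if not self.trigger_interval_min < self.trigger_interval_max:
                raise ValueError("need trigger_interval_min < trigger_interval_max")


S1 = SoundModelParams("S1", 50.0, 1100.0, 1.8, 4.0, "resonant", am_rate=3.0)
S2 = SoundModelParams("S2", 100.0, 900.0, 0.1, 0.3, "resonant", am_rate=18.0)
S3 = SoundModelParams("S3", 100.0, 3000.0, 0.01, 0.6, "bandpass",
                      ramp_length=0.25, trigger_interval_min=0.05,
                      trigger_interval_max=0.8)

_MODELS = {"S1": S1, "S2": S2, "S3": S3}


def sound_model(model_id: str) -> SoundModelParams:
    """Preset parameters for S1, S2 or S3."""
    try:
        return _MODELS[model_id]
    except KeyError:
        raise ValueError(f"unknown model_id {model_id!r}") from None


@dataclass(frozen=True)
class ControlSignal:
    """Movement controls resampled to the audio control rate.

    v_norm in [0,1] is speed clipped at the full-scale reference speed;
    azimuth is the bearing from room center (radians, atan2 convention);
    spread_ctl in [0,1] is distance from center over the area
    half-diagonal.
    """

    t: np.ndarray
    v_norm: np.ndarray
    azimuth: np.ndarray
    spread_ctl: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        for name in ("v_norm", "spread_ctl"):
            a = getattr(self, name)
            if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def constant(cls, v_norm: float, duration: float, rate: float = 100.0,
                 azimuth: float = 0.0, spread: float = 0.0) -> "ControlSignal":
        """Constant controls, for tests and model exploration."""
        t = np.arange(int(round(duration * rate))) / rate
        ones = np.ones_like(t)
        return cls(t=t, v_norm=v_norm * ones, azimuth=azimuth * ones,
                   spread_ctl=spread * ones, rate=rate)


@dataclass(frozen=True)
class RenderedAudio:
    """Multichannel float audio in [-1, 1]."""

    samples: np.ndarray          # (n_channels, n_samples)
    sample_rate: float
    channel_layout: str = "mono"

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", s)
        if s.shape[0] not in (1, 2, 8):
            raise ValueError("channel count must be 1, 2 or 8")
        if np.max(np.abs(s), initial=0.0) > 1.0 + 1e-9:
            raise ValueError("samples must lie in [-1, 1]")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sample_rate


#: Reference speed mapped to full scale, m/s (fast child locomotion).
V_REF = 2.0
#: Amplitude floor of the log gain map, dB.
FLOOR_DB = -60.0
DEFAULT_CONTROL_RATE = 100.0


def control_from_trajectory(
    traj: Trajectory,
    control_rate: float = DEFAULT_CONTROL_RATE,
    v_ref: float = V_REF,
    area: tuple[float, float] = (AREA_WIDTH, AREA_HEIGHT),
    cfg: FeatureConfig = FeatureConfig(),
) -> ControlSignal:
    """Derive the sonification controls from a trajectory.

    Speed is clipped at ``v_ref`` and scaled to [0,1]; azimuth and spread
    come from the position relative to room center; everything is
    linearly resampled to ``control_rate``.
    """
    if not v_ref > 0:
        raise ValueError("v_ref must be positive")
    v = speed(traj, cfg)
    tc = np.arange(int(np.floor(traj.duration * control_rate)) + 1) / control_rate
    tc = tc + traj.t[0]
    v_norm = np.clip(np.interp(tc, traj.t, v) / v_ref, 0.0, 1.0)
    x = np.interp(tc, traj.t, traj.x)
    y = np.interp(tc, traj.t, traj.y)
    azimuth = np.arctan2(y, x)
    half_diag = 0.5 * float(np.hypot(*area))
    spread = np.clip(np.hypot(x, y) / half_diag, 0.0, 1.0)
    return ControlSignal(t=tc - tc[0], v_norm=v_norm, azimuth=azimuth,
                         spread_ctl=spread, rate=control_rate)


def map_control(ctrl: ControlSignal, params: SoundModelParams
                ) -> tuple[np.ndarray, np.ndarray]:
    """Linear velocity-to-filter mapping: center frequency and Q series."""
    fc = params.f_min + ctrl.v_norm * (params.f_max - params.f_min)
    q = params.q_min + ctrl.v_norm * (params.q_max - params.q_min)
    return fc, q


def amplitude_from_velocity(ctrl: ControlSignal, floor_db: float = FLOOR_DB
                            ) -> np.ndarray:
    """Log-scaled amplitude gain in [0, 1]; exactly 0 at rest.

    Nonzero v_norm maps through ``20 log10(v_norm)`` affinely from
    [floor_db, 0] dB onto [0, 1] amplitude, clipped.
    """
    if not floor_db < 0:
        raise ValueError("floor_db must be negative")
    gain = np.zeros_like(ctrl.v_norm)
    nz = ctrl.v_norm > 0
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(ctrl.v_norm[nz])
    gain[nz] = np.clip(1.0 - db / floor_db, 0.0, 1.0)
    return gain


def _biquad_coeffs(fc: float, q: float, sr: float, kind: str):
    """RBJ audio-cookbook two-pole band-pass sections.

    "resonant" is the constant 0 dB peak-gain form; "bandpass" the
    constant-skirt-gain form (peak gain = Q).
    """
    fc = min(max(fc, 1.0), 0.45 * sr)
    q = max(q, 1e-4)
    w0 = 2.0 * np.pi * fc / sr
    alpha = np.sin(w0) / (2.0 * q)
    cw = np.cos(w0)
    if kind == "resonant":
        b = np.array([alpha, 0.0, -alpha])
    else:
        b = np.array([q * alpha, 0.0, -q * alpha])
    a = np.array([1.0 + alpha, -2.0 * cw, 1.0 - alpha])
    return b / a[0], a / a[0]


def _random_envelope(n_samples: int, sr: float, am_rate: float, rng) -> np.ndarray:
    """Band-limited random amplitude envelope: uniform [0,1] targets drawn
    at am_rate, linearly interpolated between targets."""
    n_targets = int(np.ceil(n_samples / sr * am_rate)) + 2
    targets = rng.uniform(0.0, 1.0, n_targets)
    t_targets = np.arange(n_targets) * (sr / am_rate)
    return np.interp(np.arange(n_samples), t_targets, targets)


def _ramp_shape(n: int, curve: float) -> np.ndarray:
    """Convex slow-start ramp rising 0 -> 1 over n samples, then cut."""
    u = np.linspace(0.0, 1.0, n, endpoint=True)
    return (np.exp(curve * u) - 1.0) / (np.exp(curve) - 1.0)


def _trigger_envelope(ctrl_v: np.ndarray, ctrl_rate: float, n_samples: int,
                      sr: float, params: SoundModelParams) -> np.ndarray:
    """Ramp-train envelope whose inter-onset interval follows velocity.

    At v_norm=0 ramps fire every trigger_interval_max seconds, at v_norm=1
    every trigger_interval_min (or the reverse when faster_with_speed is
    False).  Each ramp rises over ramp_length with the convex shape and
    drops to zero at its end -- the abrupt release is what makes the model
    choppy and clicking.
    """
    i_min, i_max = params.trigger_interval_min, params.trigger_interval_max
    env = np.zeros(n_samples)
    ramp = _ramp_shape(int(round(params.ramp_length * sr)), params.ramp_curve)
    t, t_end = 0.0, n_samples / sr
    while t < t_end:
        i0 = int(round(t * sr))
        seg = ramp[: max(n_samples - i0, 0)]
        env[i0 : i0 + len(seg)] = np.maximum(env[i0 : i0 + len(seg)], seg)
        vi = np.interp(t, np.arange(len(ctrl_v)) / ctrl_rate, ctrl_v)
        if params.faster_with_speed:
            interval = i_max + vi * (i_min - i_max)
        else:
            interval = i_min + vi * (i_max - i_min)
        t += interval
    return env


def render_model(ctrl: ControlSignal, params: SoundModelParams,
                 sr: float = 44100.0, seed: int = 0) -> RenderedAudio:
    """Render one sound model to mono audio.

    White noise passes through the velocity-steered two-pole filter
    (coefficients updated each control frame, filter state carried
    across frames), then the model's amplitude behavior, then the
    log-velocity gain.  Output is peak-normalized only if it would clip.
    """
    if sr < 8000:
        raise ValueError("sample rate must be >= 8000 Hz")
    rng = np.random.default_rng(seed)
    n_frames = len(ctrl.t)
    spf = int(round(sr / ctrl.rate))          # samples per control frame
    n_samples = n_frames * spf
    noise = rng.standard_normal(n_samples)

    fc, q = map_control(ctrl, params)
    out = np.empty(n_samples)
    zi = np.zeros(2)
    for f in range(n_frames):
        b, a = _biquad_coeffs(fc[f], q[f], sr, params.filter_kind)
        sl = slice(f * spf, (f + 1) * spf)
        out[sl], zi = sps.lfilter(b, a, noise[sl], zi=zi)

    if params.am_rate is not None:
        out *= _random_envelope(n_samples, sr, params.am_rate, rng)
    if params.trigger_interval_min is not None:
        out *= _trigger_envelope(ctrl.v_norm, ctrl.rate, n_samples, sr, params)

    gain_f = amplitude_from_velocity(ctrl)
    out *= np.repeat(gain_f, spf)

    peak = np.max(np.abs(out), initial=0.0)
    if peak > 0.99:
        out *= 0.99 / peak
    return RenderedAudio(samples=out[np.newaxis, :], sample_rate=sr,
                         channel_layout="mono")


def _ring_gains(azimuth: float, spread: float, n_speakers: int = 8) -> np.ndarray:
    """Unit-energy gains on a speaker ring.

    Pairwise constant-power panning between the two speakers adjacent to
    the azimuth; spread blends toward the uniform distribution, with a
    final energy renormalization so the gain vector always has unit norm.
    """
    sector = 2.0 * np.pi / n_speakers
    pos = (azimuth % (2.0 * np.pi)) / sector
    i = int(np.floor(pos)) % n_speakers
    frac = pos - np.floor(pos)
    g = np.zeros(n_speakers)
    g[i] = np.cos(frac * np.pi / 2.0)
    g[(i + 1) % n_speakers] = np.sin(frac * np.pi / 2.0)
    if spread > 0.0:
        g = (1.0 - spread) * g + spread / np.sqrt(n_speakers)
        g /= np.linalg.norm(g)
    return g


def spatialize(mono: RenderedAudio, ctrl: ControlSignal,
               n_speakers: int = 8) -> RenderedAudio:
    """Pan a mono render onto the 8-speaker ring following the controls.

    Per control frame the gain vector satisfies sum(g**2) = 1 (constant
    power); gains are held constant within a frame.
    """
    if mono.n_channels != 1:
        raise ValueError("spatialize expects mono input")
    n_samples = mono.samples.shape[1]
    n_frames = len(ctrl.t)
    spf = max(n_samples // n_frames, 1)
    out = np.zeros((n_speakers, n_samples))
    mono_s = mono.samples[0]
    for f in range(n_frames):
        sl = slice(f * spf, n_samples if f == n_frames - 1 else (f + 1) * spf)
        g = _ring_gains(float(ctrl.azimuth[f]), float(ctrl.spread_ctl[f]),
                        n_speakers)
        out[:, sl] = g[:, np.newaxis] * mono_s[np.newaxis, sl]
    peak = np.max(np.abs(out), initial=0.0)
    if peak > 0.99:
        out *= 0.99 / peak
    return RenderedAudio(samples=out, sample_rate=mono.sample_rate,
                         channel_layout=f"ring{n_speakers}")


def stereo_downmix(ring: RenderedAudio) -> RenderedAudio:
    """Fold an 8-channel ring render to stereo with constant-power weights
    (desk-listening convenience)."""
    n = ring.n_channels
    angles = 2.0 * np.pi * np.arange(n) / n
    # left weight peaks at +90 deg, right at -90 deg
    wl = np.clip(np.sin(angles) * 0.5 + 0.5, 0.0, 1.0)
    left = np.sqrt(wl) @ ring.samples / np.sqrt(n / 2)
    right = np.sqrt(1.0 - wl) @ ring.samples / np.sqrt(n / 2)
    out = np.vstack([left, right])
    peak = np.max(np.abs(out), initial=0.0)
    if peak > 0.99:
        out *= 0.99 / peak
    return RenderedAudio(samples=out, sample_rate=ring.sample_rate,
                         channel_layout="stereo")


def write_audio(audio: RenderedAudio, path: str | Path,
                bit_depth: int = 16) -> None:
    """Write PCM WAV (16- or 24-bit), channel count preserved."""
    if str(path) == "":
        raise ValueError("empty output path")
    data = audio.samples.T          # (n_samples, n_channels)
    if bit_depth == 16:
        scaled = np.round(data * 32767.0).astype(np.int16)
        wavfile.write(str(path), int(audio.sample_rate), scaled)
    elif bit_depth == 24:
        scaled = np.round(data * 8388607.0).astype(np.int32)
        raw = scaled.astype("<i4").tobytes()
        frames = bytearray()
        for off in range(0, len(raw), 4):
            frames += raw[off : off + 3]      # little-endian: drop the MSB
        with wave.open(str(path), "wb") as w:
            w.setnchannels(data.shape[1])
            w.setsampwidth(3)
            w.setframerate(int(audio.sample_rate))
            w.writeframes(bytes(frames))
    else:
        raise ValueError("bit_depth must be 16 or 24")


def read_audio(path: str | Path) -> RenderedAudio:
    """Read a PCM WAV written by write_audio back to float."""
    with wave.open(str(path), "rb") as w:
        width = w.getsampwidth()
    if width == 3:
        with wave.open(str(path), "rb") as w:
            nch, nfr = w.getnchannels(), w.getnframes()
            raw = w.readframes(nfr)
        b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        vals = (b[:, 0].astype(np.int32) | (b[:, 1].astype(np.int32) << 8)
                | (b[:, 2].astype(np.int32) << 16))
        vals = np.where(vals >= 1 << 23, vals - (1 << 24), vals)
        data = (vals / 8388607.0).reshape(-1, nch)
        sr = wave.open(str(path), "rb").getframerate()
    else:
        sr, data = wavfile.read(str(path))
        if data.dtype == np.int16:
            data = data / 32767.0
        data = np.atleast_2d(data.T) if data.ndim == 1 else data.T
        layout = {1: "mono", 2: "stereo"}.get(data.shape[0], "ring8")
        return RenderedAudio(samples=np.clip(data, -1, 1), sample_rate=float(sr),
                             channel_layout=layout)
    layout = {1: "mono", 2: "stereo"}.get(nch, "ring8")
    return RenderedAudio(samples=np.clip(data.T, -1, 1), sample_rate=float(sr),
                         channel_layout=layout)
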