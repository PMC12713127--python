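"""Synthetic ICN time-series generator with known ground truth.

Emulates the statistical structure of resting-state network time courses:
infraslow band-limited Gaussian background (0.01-0.15 Hz), an optional
shared global signal, a recurrent ~24 s spatiotemporal template planted
quasi-periodically with jitter, per-ICN amplitude involvement that can be
attenuated per domain to mimic staged degeneration, and a linear-phase
traveling wave for exercising phase-delay estimation. Every stochastic
operation is a pure function of its arguments and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import DEFAULT_BAND, bandlimit_array
from .timeseries import ICNTimeSeries


@dataclass(frozen=True)
class PlantedGroundTruth:
    """Ground-truth record of a planted quasi-periodic pattern.

    ``template`` is ``N x W`` (ICNs by window frames); ``occurrence_starts``
    are 0-based timepoint indices of each planted copy; ``amplitude_map``
    scales each ICN's row at injection; ``phase_lag_map`` holds per-ICN
    integer frame lags (TR units) applied at injection.
    """

    template: np.ndarray
    occurrence_starts: tuple[int, ...]
    amplitude_map: np.ndarray
    phase_lag_map: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        starts = tuple(int(s) for s in self.occurrence_starts)
        W = self.template.shape[1]
        if any(b - a < W for a, b in zip(starts, starts[1:])):
            raise ValueError("occurrence starts must be sorted with gaps >= W")
        if np.any(np.asarray(self.amplitude_map) < 0):
            raise ValueError("amplitude_map entries must be non-negative")
        object.__setattr__(self, "occurrence_starts", starts)

    @property
    def window_frames(self) -> int:
        return self.template.shape[1]


def _unit_sd_columns(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return x / sd


def generate_background(n_icn: int, n_timepoints: int, tr_seconds: float,
                        global_signal_weight: float = 0.5,
                        noise_sd: float = 1.0, *, seed: int,
                        low_hz: float = DEFAULT_BAND[0],
                        high_hz: float = DEFAULT_BAND[1]) -> ICNTimeSeries:
    """Band-limited Gaussian background plus a shared global component.

    Each ICN receives independent Gaussian noise band-passed to the
    infraslow range and rescaled to unit sample SD, weighted by
    ``noise_sd``; a single band-limited global signal, shared by all ICNs,
    is added with weight ``global_signal_weight``.
    """
    if n_icn < 2:
        raise ValueError(f"n_icn must be >= 2, got {n_icn}")
    if n_timepoints < 16:
        raise ValueError(f"n_timepoints must be >= 16, got {n_timepoints}")
    if tr_seconds <= 0:
        raise ValueError(f"tr_seconds must be positive, got {tr_seconds}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_timepoints, n_icn))
    glob = rng.standard_normal((n_timepoints, 1))
    noise = _unit_sd_columns(bandlimit_array(noise, tr_seconds, low_hz, high_hz))
    glob = _unit_sd_columns(bandlimit_array(glob, tr_seconds, low_hz, high_hz))
    data = noise_sd * noise + global_signal_weight * glob
    return ICNTimeSeries(data=data, tr_seconds=tr_seconds)


def plant_qpp(ts: ICNTimeSeries, template: np.ndarray, mean_interval_tr: int,
              jitter_tr: int, amplitude_map: np.ndarray | float = 1.0, *,
              seed: int,
              phase_lag_map: np.ndarray | None = None
              ) -> tuple[ICNTimeSeries, PlantedGroundTruth]:
    """Add quasi-periodic copies of ``template`` (``N x W``) into ``ts``.

    Occurrence starts follow a renewal process: successive gaps are
    ``mean_interval_tr`` plus uniform jitter in ``[-jitter_tr, +jitter_tr]``,
    floored at ``W`` so copies never overlap. Each ICN's row is scaled by
    ``amplitude_map`` before injection; injection is purely additive (no
    filtering afterwards), so output minus input equals the scheduled
    copies exactly.
    """
    template = np.asarray(template, dtype=float)
    T, N = ts.data.shape
    if template.shape[0] != N:
        raise ValueError(f"template has {template.shape[0]} rows, series has {N} ICNs")
    W = template.shape[1]
    if W > T // 2:
        raise ValueError(f"template width {W} exceeds half the series length {T}")
    if mean_interval_tr < W:
        raise ValueError(f"mean_interval_tr {mean_interval_tr} must be >= W={W}")
    amp = np.broadcast_to(np.asarray(amplitude_map, dtype=float), (N,)).copy()
    if np.any(amp < 0):
        raise ValueError("amplitude_map entries must be non-negative")
    lags = (np.zeros(N, dtype=int) if phase_lag_map is None
            else np.asarray(np.round(phase_lag_map), dtype=int))
    max_lag = int(lags.max(initial=0))
    if int(lags.min(initial=0)) < 0:
        raise ValueError("phase_lag_map lags must be >= 0 frames")

    rng = np.random.default_rng(seed)
    starts: list[int] = []
    pos = int(rng.integers(0, max(1, mean_interval_tr - W)))
    while pos + W + max_lag <= T:
        starts.append(pos)
        gap = int(round(mean_interval_tr + rng.uniform(-jitter_tr, jitter_tr)))
        pos += max(W, gap)

    out = ts.data.copy()
    scaled = template * amp[:, None]
    for s in starts:
        for i in range(N):
            lo = s + lags[i]
            out[lo:lo + W, i] += scaled[i]
    truth = PlantedGroundTruth(template=template, occurrence_starts=tuple(starts),
                               amplitude_map=amp, phase_lag_map=lags, seed=seed)
    return ts.with_data(out), truth


def make_traveling_wave(n_icn: int, n_timepoints: int, tr_seconds: float,
                        freq_hz: float, phase_step_rad: float,
                        noise_sd: float = 0.0, *, seed: int = 0) -> ICNTimeSeries:
    """Sinusoidal traveling wave with a linear phase gradient across ICNs.

    ICN ``m`` is ``cos(2*pi*freq_hz*t - m*phase_step_rad)`` plus white
    Gaussian noise: each successive ICN lags the previous one by
    ``phase_step_rad`` radians.
    """
    nyq = 1.0 / (2.0 * tr_seconds)
    if not (0 < freq_hz < nyq):
        raise ValueError(f"freq_hz must lie in (0, {nyq}) Hz, got {freq_hz}")
    if n_icn < 2 or n_timepoints < 4:
        raise ValueError("need n_icn >= 2 and n_timepoints >= 4")
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints) * tr_seconds
    m = np.arange(n_icn)
    data = np.cos(2 * np.pi * freq_hz * t[:, None] - m[None, :] * phase_step_rad)
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return ICNTimeSeries(data=data, tr_seconds=tr_seconds)
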