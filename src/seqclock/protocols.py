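"""Stimulation schedules and target-signal generators.

Stage 1 trains the recurrent clock: clusters receive a strong external
Poisson drive one after the other (10 ms stimulation, 5 ms gaps, circular
order), while all other clusters receive a lateral external inhibitory
input.  Stretching the timing to 50/50 ms removes the pre/post pairing
between adjacent clusters and yields the slow-switching control regime.

Stage 2 trains the read-out: supervisor neurons are driven by a
multi-channel target rate signal, replayed in register with the clock
(playback restarts whenever the first cluster activates), while the
interneurons receive a fixed drive that keeps potentiation gradual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import Network
from .params import ExternalDriveParams

__all__ = [
    "StepRates",
    "TargetSignal",
    "SpontaneousProtocol",
    "Stage1Protocol",
    "Stage2Protocol",
    "make_stage1_protocol",
    "make_stage2_protocol",
    "make_letter_target",
    "make_synthetic_spectrogram_target",
    "readout_learning_time_s",
]


def readout_learning_time_s(N_C: int) -> float:
    """Total supervised learning time for cluster size N_C (960 s / N_C).

    Smaller clusters need larger read-out weight changes to drive the same
    read-out neuron, hence proportionally longer training.
    """
    return 960.0 / N_C

MAX_TARGET_RATE_KHZ = 10.0
NOMINAL_CLUSTER_DWELL_MS = 15.0


@dataclass
class StepRates:
    """External Poisson rates (kHz) for one time step; None = channel off."""

    e_exc: float | np.ndarray | None = None
    e_inh: float | np.ndarray | None = None
    i_exc: float | None = None
    s_exc: np.ndarray | None = None
    h_exc: float | None = None


@dataclass
class TargetSignal:
    """Multi-channel piecewise-constant rate signal on a uniform grid.

    ``rates`` has shape (n_bins, D) in kHz; channel ``labels`` name the D
    read-out dimensions.
    """

    rates: np.ndarray
    bin_ms: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if not self.labels:
            self.labels = [str(i) for i in range(self.D)]
        if np.any(self.rates < 0) or np.any(self.rates > MAX_TARGET_RATE_KHZ + 1e-9):
            raise ValueError(
                f"target rates must lie in [0, {MAX_TARGET_RATE_KHZ}] kHz; normalize first"
            )

    @property
    def D(self) -> int:
        return self.rates.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.rates.shape[0] * self.bin_ms

    def rate_at(self, t_ms: float) -> np.ndarray:
        """Channel rates at time t since signal onset (zero outside)."""
        k = int(t_ms // self.bin_ms)
        if t_ms < 0 or k >= self.rates.shape[0]:
            return np.zeros(self.D)
        return self.rates[k]

    def normalized(self, peak_khz: float = MAX_TARGET_RATE_KHZ) -> "TargetSignal":
        """Min-zero max-``peak_khz`` rescaled copy (identity for a zero signal)."""
        m = self.rates.max()
        scaled = self.rates * (peak_khz / m) if m > 0 else self.rates.copy()
        return TargetSignal(scaled, self.bin_ms, list(self.labels))

    def to_frame(self):
        import pandas as pd

        n = self.rates.shape[0]
        t = np.repeat(np.arange(n) * self.bin_ms, self.D)
        ch = np.tile(np.arange(self.D), n)
        return pd.DataFrame({
            "time_ms": t,
            "channel": [self.labels[c] for c in ch],
            "rate_khz": self.rates.ravel(),
        })


class SpontaneousProtocol:
    """Unstructured external drive: fixed excitatory Poisson input only."""

    def __init__(self, drive: ExternalDriveParams | None = None,
                 e_rate_scale: float = 1.0):
        self.drive = drive or ExternalDriveParams()
        self.e_rate_scale = e_rate_scale
        self._rates: StepRates | None = None

    def begin(self, net: Network) -> None:
        self.drive = net.cfg.drive
        self._rates = StepRates(
            e_exc=self.drive.r_ext_E * self.e_rate_scale,
            i_exc=self.drive.r_ext_I,
        )

    def rates(self, t: float) -> StepRates:
        if self._rates is None:
            self._rates = StepRates(
                e_exc=self.drive.r_ext_E * self.e_rate_scale,
                i_exc=self.drive.r_ext_I,
            )
        return self._rates

    def describe(self) -> dict:
        return {"protocol": "spontaneous", "e_rate_scale": self.e_rate_scale}


class Stage1Protocol:
    """Sequential cluster stimulation with lateral inhibition (circular)."""

    def __init__(self, C: int, stim_ms: float = 10.0, gap_ms: float = 5.0,
                 rate_khz: float = 18.0, lateral_rate_khz: float = 4.5,
                 duration_ms: float | None = None,
                 baseline_rate_khz: float | None = None):
        if stim_ms <= 0 or gap_ms < 0:
            raise ValueError("stimulation and gap durations must be positive")
        # the unstructured excitatory drive stays on during training by
        # default (None = the spontaneous rate); set to 0 to drive the
        # network through the cluster stimulus alone
        self.baseline_rate_khz = baseline_rate_khz
        self.C = C
        self.stim_ms = stim_ms
        self.gap_ms = gap_ms
        self.rate_khz = rate_khz
        self.lateral_rate_khz = lateral_rate_khz
        self.cycle_ms = C * (stim_ms + gap_ms)
        if duration_ms is not None and duration_ms < self.cycle_ms:
            raise ValueError(
                f"duration {duration_ms} ms is shorter than one cycle "
                f"({self.cycle_ms} ms)"
            )
        if gap_ms >= 20.0:
            warnings.warn(
                f"gap of {gap_ms} ms exceeds the STDP pairing window; the "
                "schedule trains slow-switching rather than sequential "
                "dynamics", stacklevel=2)
        self._net: Network | None = None
        self._key: tuple[int, bool] | None = None
        self._cached: StepRates | None = None

    def begin(self, net: Network) -> None:
        if net.cfg.C != self.C:
            raise ValueError(
                f"protocol built for C = {self.C} clusters, network has {net.cfg.C}")
        self._net = net
        self._key = None

    def cluster_at(self, t: float) -> tuple[int, bool]:
        """(cluster index, stimulation-window flag) at time t."""
        slot_ms = self.stim_ms + self.gap_ms
        phase = t % self.cycle_ms
        k = int(phase // slot_ms)
        in_stim = (phase - k * slot_ms) < self.stim_ms
        return k % self.C, in_stim

    def rates(self, t: float) -> StepRates:
        net = self._net
        k, in_stim = self.cluster_at(t)
        key = (k, in_stim)
        if key != self._key:
            drv = net.cfg.drive
            base_rate = (drv.r_ext_E if self.baseline_rate_khz is None
                         else self.baseline_rate_khz)
            base = np.full(net.cfg.N_E, base_rate)
            if in_stim:
                members = net.clusters == k
                e_exc = base + self.rate_khz * members
                e_inh = np.where(members, 0.0, self.lateral_rate_khz)
            else:
                e_exc = base if base_rate else None
                e_inh = None
            self._cached = StepRates(e_exc=e_exc, e_inh=e_inh, i_exc=drv.r_ext_I)
            self._key = key
        return self._cached

    def describe(self) -> dict:
        return {"protocol": "stage1", "C": self.C, "stim_ms": self.stim_ms,
                "gap_ms": self.gap_ms, "rate_khz": self.rate_khz,
                "lateral_rate_khz": self.lateral_rate_khz,
                "cycle_ms": self.cycle_ms}


class Stage2Protocol:
    """Supervised read-out training, target aligned to clock reactivations.

    Playback of the target signal (through the supervisor neurons' external
    Poisson rate) starts whenever the first cluster of the recurrent network
    activates, emulating a shared start signal for the clock and the
    supervisor input.  With several targets, presentation alternates in
    fixed-length blocks.
    """

    def __init__(self, targets: list[TargetSignal],
                 total_learning_s: float,
                 block_s: float = 2.0,
                 interneuron_rate_khz: float = 1.0,
                 detect_tau_ms: float = 2.0,
                 detect_threshold: float = 0.1):
        if not targets:
            raise ValueError("at least one target required")
        D = targets[0].D
        if any(tg.D != D for tg in targets):
            raise ValueError("all targets must share the channel space")
        self.targets = targets
        self.total_learning_ms = total_learning_s * 1000.0
        self.block_ms = block_s * 1000.0
        self.interneuron_rate_khz = interneuron_rate_khz
        self.detect_tau_ms = detect_tau_ms
        self.detect_threshold = detect_threshold
        self._net: Network | None = None
        self._t_begin = 0.0
        self._ema = 0.0
        self._play_from: float | None = None
        self._cluster1: np.ndarray | None = None

    def begin(self, net: Network) -> None:
        nominal_period = net.cfg.C * NOMINAL_CLUSTER_DWELL_MS
        for tg in self.targets:
            if tg.duration_ms > nominal_period:
                raise ValueError(
                    f"target of {tg.duration_ms} ms cannot be clocked by a "
                    f"sequence with nominal period {nominal_period} ms")
        self._net = net
        self._t_begin = net.t
        self._cluster1 = np.flatnonzero(net.clusters == 0)
        self._ema = 0.0
        self._play_from = None

    # -- clock alignment --------------------------------------------------

    def observe_spikes(self, t: float, e_spike_idx: np.ndarray) -> None:
        net = self._net
        dt = net.cfg.dt
        count = np.count_nonzero(net.clusters[e_spike_idx] == 0) if e_spike_idx.size else 0
        self._ema = self._ema * np.exp(-dt / self.detect_tau_ms) + count
        target = self._current_target(t)
        if self._play_from is not None and t - self._play_from >= target.duration_ms:
            self._play_from = None
        if (self._play_from is None
                and self._ema >= self.detect_threshold * self._cluster1.size):
            self._play_from = t
            self._ema = 0.0

    def _current_target(self, t: float) -> TargetSignal:
        if len(self.targets) == 1:
            return self.targets[0]
        block = int((t - self._t_begin) // self.block_ms)
        return self.targets[block % len(self.targets)]

    def learning_active(self, t: float) -> bool:
        return (t - self._t_begin) < self.total_learning_ms

    def rates(self, t: float) -> StepRates:
        drv = self._net.cfg.drive
        if not self.learning_active(t):
            return StepRates(e_exc=drv.r_ext_E, i_exc=drv.r_ext_I)
        s = None
        if self._play_from is not None:
            s = self._current_target(t).rate_at(t - self._play_from)
        return StepRates(e_exc=drv.r_ext_E, i_exc=drv.r_ext_I,
                         s_exc=s, h_exc=self.interneuron_rate_khz)

    def describe(self) -> dict:
        return {"protocol": "stage2",
                "n_targets": len(self.targets),
                "total_learning_s": self.total_learning_ms / 1000.0,
                "block_s": self.block_ms / 1000.0,
                "interneuron_rate_khz": self.interneuron_rate_khz}


def make_stage1_protocol(C: int, stim_ms: float = 10.0, gap_ms: float = 5.0,
                         rate_khz: float = 18.0,
                         lateral_rate_khz: float = 4.5,
                         duration_ms: float | None = None) -> Stage1Protocol:
    """Sequential stimulation schedule of the first learning stage."""
    return Stage1Protocol(C, stim_ms=stim_ms, gap_ms=gap_ms, rate_khz=rate_khz,
                          lateral_rate_khz=lateral_rate_khz,
                          duration_ms=duration_ms)


def make_stage2_protocol(target: TargetSignal | list[TargetSignal],
                         total_learning_s: float,
                         alternation_block_s: float = 2.0,
                         interneuron_rate_khz: float = 1.0) -> Stage2Protocol:
    """Supervised read-out schedule; a list of targets alternates in blocks."""
    targets = target if isinstance(target, list) else [target]
    return Stage2Protocol(targets, total_learning_s,
                          block_s=alternation_block_s,
                          interneuron_rate_khz=interneuron_rate_khz)


def make_letter_target(sequence: str, step_ms: float = 75.0,
                       amplitude_khz: float = 10.0,
                       channels: str | list[str] | None = None) -> TargetSignal:
    """Piecewise-constant letter sequence target (one channel per letter).

    Each letter drives its channel at ``amplitude_khz`` for ``step_ms``;
    exactly one channel is active per step.  ``channels`` fixes the channel
    order (default: sorted unique letters of the sequence).
    """
    labels = list(channels) if channels is not None else sorted(set(sequence))
    index = {c: i for i, c in enumerate(labels)}
    unknown = [c for c in sequence if c not in index]
    if unknown:
        raise ValueError(f"unknown channel label(s) {sorted(set(unknown))}")
    rates = np.zeros((len(sequence), len(labels)))
    for k, c in enumerate(sequence):
        rates[k, index[c]] = amplitude_khz
    return TargetSignal(rates, step_ms, labels)


def make_synthetic_spectrogram_target(
    D: int = 45,
    duration_ms: float = 600.0,
    rng: np.random.Generator | None = None,
    n_components: int = 8,
    components: list[dict] | None = None,
    bin_ms: float = 5.0,
    freq_base_hz: float = 684.0,
    freq_step_hz: float = 171.0,
) -> TargetSignal:
    """A smooth multi-ridge time-frequency surface as a stand-in spectrogram.

    Emulates the statistics of a birdsong spectrogram: ``n_components``
    ridges of varying onset, duration, spectral width, frequency drift and
    amplitude, summed and normalized to a 10 kHz peak rate.  Channel i is
    labelled with its frequency band [freq_base + i*step, freq_base +
    (i+1)*step] Hz.  ``components`` bypasses the random draw with explicit
    ridge specs (keys: onset, duration, channel, width, amplitude, drift,
    envelope); width 0 confines a ridge to a single channel and envelope
    "flat" makes it constant over its extent.
    """
    rng = rng or np.random.default_rng()
    n_bins = int(round(duration_ms / bin_ms))
    surface = np.zeros((n_bins, D))
    tgrid = np.arange(n_bins) * bin_ms
    if components is None:
        components = [
            dict(
                duration=rng.uniform(40.0, 180.0),
                channel=rng.uniform(0.1 * (D - 1), 0.9 * (D - 1)),
                drift=rng.uniform(-8.0, 8.0) / 1000.0,  # channels per ms
                width=rng.uniform(1.0, 4.0),            # channels
                amplitude=rng.uniform(0.3, 1.0),
            )
            for _ in range(max(0, n_components))
        ]
        for comp in components:
            comp["onset"] = rng.uniform(0.0, max(duration_ms - comp["duration"], 1.0))
    for comp in components:
        dur = comp["duration"]
        onset = comp.get("onset", 0.0)
        width = comp.get("width", 1.0)
        amp = comp.get("amplitude", 1.0)
        drift = comp.get("drift", 0.0)
        active = (tgrid >= onset) & (tgrid < onset + dur)
        centers = comp["channel"] + drift * (tgrid - onset)
        ch = np.arange(D)
        if comp.get("envelope", "arch") == "flat":
            envelope = np.ones_like(tgrid, dtype=float)
        else:
            envelope = np.sin(np.pi * np.clip((tgrid - onset) / dur, 0, 1)) ** 0.5
        if width > 0:
            profile = np.exp(-0.5 * ((ch[None, :] - centers[:, None]) / width) ** 2)
        else:
            profile = (np.round(centers[:, None]) == ch[None, :]).astype(float)
        surface += amp * (envelope * active)[:, None] * profile
    labels = [
        f"{freq_base_hz + i * freq_step_hz:.0f}-"
        f"{freq_base_hz + (i + 1) * freq_step_hz:.0f}Hz"
        for i in range(D)
    ]
    target = TargetSignal(np.zeros_like(surface), bin_ms, labels)
    target.rates = surface
    return target.normalized()
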