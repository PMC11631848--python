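"""Neural-mass (Jansen-Rit) interictal-spike simulator.

Each region is an independent Jansen-Rit cortical-column model: pyramidal
cells coupled to excitatory and inhibitory interneuron populations through
second-order synaptic kinetics and a sigmoidal potential-to-rate map.  At
the canonical operating point the column produces alpha-band activity;
raising the average excitatory synaptic gain A from 3.25 to 3.6 pushes the
column into a regime that emits interictal-spike-like transients.

Dataset construction mirrors the usual two-stage recipe: (1) build a bank
of 1-s spike snippets per region by simulating long portions with that
region's gain elevated, decimating 2000 Hz -> 500 Hz, and keeping windows
that contain a spike in the active region and none elsewhere; (2) per
sample, grow an extended patch on the region graph, paste a randomly drawn
seed-region spike onto the members with Gaussian distance decay, rescale
so the spike rows sit 15 dB above the resting background rows, project
(spikes + background) to the electrodes and add white sensor noise.

The stored ground truth keeps only the active rows (the background enters
the EEG but never the training target).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import decimate, find_peaks

from .data import SimulationSample, add_noise, derive_seed
from .head_model import HeadModel, project_forward
from .sereega import assign_extended_activity, grow_region, mean_adjacent_spacing

__all__ = ["JansenRitParams", "NMMConfig", "SpikeBank", "jansen_rit_simulate",
           "detect_spikes", "build_spike_bank", "simulate_sample_nmm"]


@dataclass
class JansenRitParams:
    """Jansen-Rit column parameters (SI units: s^-1, mV).

    Defaults are the canonical constants (B = 22 mV, a = 100 s^-1,
    b = 50 s^-1, C = 135 with the 1 / 0.8 / 0.25 / 0.25 split, v0 = 6 mV,
    e0 = 2.5 s^-1, r = 0.56 mV^-1) with the standard mean afferent drive
    of 220 pulses/s (std 22), which yields alpha-band output at A = 3.25.
    """

    A: float = 3.25            # excitatory synaptic gain (mV)
    B: float = 22.0            # inhibitory synaptic gain (mV)
    a: float = 100.0           # excitatory rate constant (1/s)
    b: float = 50.0            # inhibitory rate constant (1/s)
    C1: float = 135.0
    C2: float = 0.8 * 135.0
    C3: float = 0.25 * 135.0
    C4: float = 0.25 * 135.0
    v0: float = 6.0            # sigmoid threshold (mV)
    e0: float = 2.5            # half max firing rate (1/s)
    r: float = 0.56            # sigmoid steepness (1/mV)
    input_mu: float = 220.0    # mean drive (pulses/s)
    input_sigma: float = 22.0  # per-step drive noise std (pulses/s)

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("rate constants must be positive")
        if self.e0 <= 0:
            raise ValueError("e0 must be positive")

    def with_gain(self, A: float) -> "JansenRitParams":
        return JansenRitParams(A=A, B=self.B, a=self.a, b=self.b, C1=self.C1,
                               C2=self.C2, C3=self.C3, C4=self.C4, v0=self.v0,
                               e0=self.e0, r=self.r, input_mu=self.input_mu,
                               input_sigma=self.input_sigma)


@dataclass
class NMMConfig:
    """Study conditions of the neural-mass generator.

    2000 Hz simulation decimated to 500 Hz, 6 portions of 10 s per region,
    15 dB source-vs-background power ratio, sensor SNR drawn from
    {5, 10, 15, 20} dB, two extended patches of order 3.  The dataset
    drive (mu = 87 pulses/s, i.e. 0.087/ms) sits below the alpha regime:
    at A = 3.25 the column rests quietly, at A = 3.6 it fires spikes.
    The drive noise std (100 pulses/s) is the package's calibration of the
    unit-less printed noise scale; see the methods note.
    """

    fs_sim: float = 2000.0
    fs_out: float = 500.0
    portions_per_region: int = 6
    portion_length: float = 10.0          # s
    source_background_snr_db: float = 15.0
    sensor_snr_db_choices: tuple = (5.0, 10.0, 15.0, 20.0)
    fixed_sensor_snr_db: float | None = None
    n_regions_active: int = 2
    order: int = 3
    A_active: float = 3.6
    A_background: float = 3.25
    drive_mu: float = 87.0                # pulses/s (= 0.087 per ms)
    drive_sigma: float = 100.0            # pulses/s
    spike_threshold_mads: float = 6.0
    spike_refractory_s: float = 0.25
    decay_sigma: float | None = None      # mm; None -> mean adjacent spacing
    rng_seed: int = 0

    def __post_init__(self):
        if self.fs_sim % self.fs_out:
            raise ValueError("fs_sim must be an integer multiple of fs_out")

    @property
    def decimation(self) -> int:
        return int(self.fs_sim // self.fs_out)

    def params_active(self) -> JansenRitParams:
        return JansenRitParams(A=self.A_active, input_mu=self.drive_mu,
                               input_sigma=self.drive_sigma)

    def params_background(self) -> JansenRitParams:
        return JansenRitParams(A=self.A_background, input_mu=self.drive_mu,
                               input_sigma=self.drive_sigma)


@dataclass
class SpikeBank:
    """Per-region pools of 1-s spike and resting-background snippets."""

    spikes: dict                       # region -> (n_windows, T) array
    background: dict                   # region -> (n_windows, T) array
    fs: float
    excluded_regions: list = field(default_factory=list)
    rng_seed: int = 0

    def covers(self, region: int) -> bool:
        return region in self.spikes and len(self.spikes[region]) > 0


class IntegrationError(RuntimeError):
    """Jansen-Rit state became non-finite (step-size instability)."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite Jansen-Rit state at step {step}")


def jansen_rit_simulate(params: JansenRitParams, duration: float,
                        fs_sim: float, rng: np.random.Generator,
                        n_units: int = 1, burn_in: float = 2.0,
                        initial_state: np.ndarray | None = None) -> np.ndarray:
    """Euler-Maruyama integration of the 6-state Jansen-Rit system.

    The stochastic afferent drive is drawn N(input_mu, input_sigma^2) per
    step.  A burn-in (default 2 s) is simulated and discarded.  Returns the
    net pyramidal membrane potential y1 - y2, shape (n_samples,) for one
    unit or (n_units, n_samples) otherwise.  Units evolve independently
    (shared parameters, independent noise).
    """
    n_total = int(round((duration + burn_in) * fs_sim))
    if int(round(duration * fs_sim)) < 2000:
        raise ValueError("need at least 2000 output samples")
    dt = 1.0 / fs_sim
    p = params
    if initial_state is not None:
        y = np.array(initial_state, dtype=float).reshape(6, 1) * \
            np.ones((6, n_units))
    else:
        y = np.zeros((6, n_units))
    out = np.empty((n_units, n_total))
    two_e0 = 2.0 * p.e0

    def sigm(v):
        return two_e0 / (1.0 + np.exp(p.r * (p.v0 - v)))

    a2, b2 = p.a * p.a, p.b * p.b
    Aa, Bb = p.A * p.a, p.B * p.b
    for i in range(n_total):
        y0, y1, y2, y3, y4, y5 = y
        drive = p.input_mu + p.input_sigma * rng.standard_normal(n_units)
        d3 = Aa * sigm(y1 - y2) - 2 * p.a * y3 - a2 * y0
        d4 = Aa * (drive + p.C2 * sigm(p.C1 * y0)) - 2 * p.a * y4 - a2 * y1
        d5 = Bb * p.C4 * sigm(p.C3 * y0) - 2 * p.b * y5 - b2 * y2
        y = y + dt * np.vstack((y3, y4, y5, d3, d4, d5))
        if not np.all(np.isfinite(y)):
            raise IntegrationError(i)
        out[:, i] = y[1] - y[2]
    out = out[:, int(round(burn_in * fs_sim)):]
    return out[0] if n_units == 1 else out


def detect_spikes(signal: np.ndarray, fs: float, threshold_mads: float = 6.0,
                  refractory_s: float = 0.25) -> np.ndarray:
    """Spike events: local maxima above median + k*MAD, spaced >= refractory.

    A constant signal yields an empty event list (MAD = 0 guarded by
    requiring strictly positive prominence over the threshold).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < fs:
        raise ValueError("signal must be at least 1 s long")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0 and np.ptp(x) == 0:
        return np.array([], dtype=int)
    thr = med + threshold_mads * mad
    idx, _ = find_peaks(x, height=thr, distance=max(1, int(refractory_s * fs)))
    return idx


def _harvest_windows(trace: np.ndarray, events: np.ndarray, fs: int):
    """1-s windows centered on events, baseline(median)-corrected."""
    T = int(fs)
    half = T // 2
    wins, centers = [], []
    for e in events:
        start = int(e) - half
        if start < 0 or start + T > trace.size:
            continue
        w = trace[start:start + T].copy()
        wins.append(w - np.median(w))
        centers.append(half)
    return wins, centers


def build_spike_bank(head: HeadModel, cfg: NMMConfig) -> SpikeBank:
    """Simulate every region's spiking and resting activity; harvest snippets.

    The uncoupled columns are independent, so one vectorized run per
    portion simulates all regions at the elevated gain and a second run
    all regions at the background gain; a window is kept for region r only
    if r's elevated-gain trace spikes inside it while no other region's
    background trace does.  Background pools collect event-free 1-s
    stretches of the resting traces.  Deterministic given cfg.rng_seed.
    """
    nr = head.n_regions
    fs_out = int(cfg.fs_out)
    spikes = {r: [] for r in range(1, nr + 1)}
    background = {r: [] for r in range(1, nr + 1)}
    for portion in range(cfg.portions_per_region):
        rng_a = np.random.default_rng(derive_seed(cfg.rng_seed, "bank-active", portion))
        rng_b = np.random.default_rng(derive_seed(cfg.rng_seed, "bank-bg", portion))
        act = jansen_rit_simulate(cfg.params_active(), cfg.portion_length,
                                  cfg.fs_sim, rng_a, n_units=nr)
        bg = jansen_rit_simulate(cfg.params_background(), cfg.portion_length,
                                 cfg.fs_sim, rng_b, n_units=nr)
        act = decimate(act, cfg.decimation, n=8, axis=-1, zero_phase=True)
        bg = decimate(bg, cfg.decimation, n=8, axis=-1, zero_phase=True)
        bg_events = [detect_spikes(bg[r], fs_out, cfg.spike_threshold_mads,
                                   cfg.spike_refractory_s) for r in range(nr)]
        for r in range(nr):
            events = detect_spikes(act[r], fs_out, cfg.spike_threshold_mads,
                                   cfg.spike_refractory_s)
            wins, _ = _harvest_windows(act[r], events, fs_out)
            for w, e in zip(wins, events[: len(wins)]):
                start = int(e) - fs_out // 2
                clash = any(np.any((ev >= start) & (ev < start + fs_out))
                            for j, ev in enumerate(bg_events) if j != r)
                if not clash:
                    spikes[r + 1].append(w)
            # event-free resting snippets for the background pool
            ev = bg_events[r]
            n_win = bg.shape[1] // fs_out
            for k in range(n_win):
                s0, s1 = k * fs_out, (k + 1) * fs_out
                if not np.any((ev >= s0) & (ev < s1)):
                    w = bg[r, s0:s1]
                    background[r + 1].append(w - np.median(w))
    excluded = [r for r in spikes if len(spikes[r]) == 0]
    for r in excluded:
        warnings.warn(f"region {r} yielded no valid spike window; excluded")
        spikes.pop(r)
    return SpikeBank(
        spikes={r: np.asarray(v) for r, v in spikes.items()},
        background={r: np.asarray(v) for r, v in background.items()},
        fs=cfg.fs_out, excluded_regions=excluded, rng_seed=cfg.rng_seed)


def simulate_sample_nmm(head: HeadModel, bank: SpikeBank, cfg: NMMConfig,
                        rng: np.random.Generator) -> SimulationSample:
    """One interictal-spike sample from the snippet bank.

    Ground truth keeps only the active patch rows, rescaled so the spike
    rows sit ``source_background_snr_db`` above the resting rows in
    Frobenius power; the EEG projects spikes + background and then gets
    white sensor noise at an SNR drawn from the configured choices.
    """
    nr = head.n_regions
    T = int(cfg.fs_out)
    if cfg.n_regions_active > len(bank.spikes):
        raise ValueError("not enough bank-covered regions")
    sigma = cfg.decay_sigma if cfg.decay_sigma is not None else mean_adjacent_spacing(head)
    covered = np.array(sorted(bank.spikes))
    seeds = rng.choice(covered, size=cfg.n_regions_active, replace=False)

    X_spike = np.zeros((nr, T))
    active = []
    for s in seeds:
        if not bank.covers(int(s)):
            raise KeyError(f"seed region {s} absent from spike bank")
        members = grow_region(int(s), cfg.order, head.region_adjacency)
        pool = bank.spikes[int(s)]
        wf = pool[int(rng.integers(len(pool)))]
        rows = assign_extended_activity(members, int(s), wf,
                                        head.region_centroids, sigma)
        for r, row in rows.items():
            X_spike[r - 1] += row
        active.append((int(s), cfg.order, sorted(members)))

    members_all = sorted({m for _, _, mem in active for m in mem})
    inactive = [r for r in range(1, nr + 1) if r not in members_all]
    X_bg = np.zeros((nr, T))
    for r in inactive:
        pool = bank.background.get(r)
        if pool is None or len(pool) == 0:
            continue
        X_bg[r - 1] = pool[int(rng.integers(len(pool)))]

    p_spike = np.linalg.norm(X_spike) ** 2
    p_bg = np.linalg.norm(X_bg) ** 2
    if p_spike == 0:
        raise RuntimeError("drawn spike waveform is identically zero")
    if p_bg > 0:
        X_spike *= np.sqrt(10 ** (cfg.source_background_snr_db / 10.0) * p_bg
                           / p_spike)

    Y_clean = project_forward(head.leadfield_regional, X_spike + X_bg)
    if cfg.fixed_sensor_snr_db is not None:
        snr = float(cfg.fixed_sensor_snr_db)
    else:
        snr = float(rng.choice(np.asarray(cfg.sensor_snr_db_choices, dtype=float)))
    Y, _ = add_noise(Y_clean, snr, rng)
    return SimulationSample(X=X_spike, Y_clean=Y_clean, Y=Y,
                            active_regions=active, snr_db=snr,
                            generator_tag="nmm", rng_seed=-1, fs=cfg.fs_out)
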