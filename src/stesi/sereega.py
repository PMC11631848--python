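"""Event-related source simulator (physical-model style).

Generates training pairs in the manner of event-related-potential
simulators: a small number of extended active patches grown over the
region adjacency graph, each sharing a Gaussian-in-time waveform whose
amplitude decays with distance from the patch seed, projected to the
electrodes and corrupted by white sensor noise at a fixed SNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data import SimulationSample, add_noise
from .head_model import HeadModel, project_forward

__all__ = ["ERWaveformParams", "SereegaConfig", "grow_region", "er_waveform",
           "assign_extended_activity", "simulate_sample_sereega"]

_NAM = 1e-9  # nA*m -> A*m


@dataclass
class ERWaveformParams:
    """Gaussian event-related waveform: amplitude a, center c, width w = 6 sigma."""

    a: float      # A*m
    c: float      # s
    w: float      # s

    def __post_init__(self):
        if not np.isfinite(self.a):
            raise ValueError("amplitude must be finite")
        if self.w <= 0:
            raise ValueError("width must be positive")


@dataclass
class SereegaConfig:
    """Study conditions of the event-related generator.

    Amplitudes are drawn in 0.5-1.5 nA*m and divided by the head model's
    mean region size (the region-level source space assumes equal activity
    of member sources, so a region's moment is the per-source moment times
    its size). Waveform center 49-51 ms, width 125-375 ms, 1 s at 500 Hz,
    sensor SNR 5 dB, two active patches of extension order 1-3.
    """

    n_regions_active: int = 2
    order_range: tuple = (1, 3)
    amplitude_range_nam: tuple = (0.5, 1.5)   # nA*m, before size division
    center_range: tuple = (0.049, 0.051)      # s
    width_range: tuple = (0.125, 0.375)       # s
    fs: float = 500.0
    duration: float = 1.0
    snr_db: float = 5.0
    decay_sigma: float | None = None          # mm; None -> mean adjacent spacing
    region_size_divisor: float | None = None  # None -> head.mean_region_size()
    rng_seed: int = 0

    @property
    def n_times(self) -> int:
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * duration must be integral")
        return int(round(n))

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs


def grow_region(seed_region: int, order: int, adjacency: nx.Graph) -> set:
    """Graph ball: the seed plus all regions within graph distance <= order."""
    if seed_region not in adjacency:
        raise KeyError(f"unknown region id {seed_region!r}")
    if order < 0:
        raise ValueError("order must be >= 0")
    lengths = nx.single_source_shortest_path_length(adjacency, seed_region,
                                                    cutoff=order)
    return set(lengths)


def er_waveform(p: ERWaveformParams, t_grid: np.ndarray) -> np.ndarray:
    """Gaussian pulse a * exp(-(1/2) (6 (t - c) / w)^2)."""
    t = np.asarray(t_grid, dtype=float)
    return p.a * np.exp(-0.5 * (6.0 * (t - p.c) / p.w) ** 2)


def assign_extended_activity(members, seed_region: int, waveform: np.ndarray,
                             centroids: np.ndarray, decay_sigma: float) -> dict:
    """Distance-decayed copies of the seed waveform for each member region.

    Region r receives waveform * exp(-d(r, seed)^2 / (2 sigma^2)) with d the
    Euclidean centroid distance; the seed keeps the full amplitude.
    Returns {region_label: row vector}.
    """
    if decay_sigma <= 0:
        raise ValueError("decay_sigma must be positive")
    members = sorted(set(int(m) for m in members))
    if seed_region not in members:
        raise ValueError("seed must belong to the member set")
    seed_pos = centroids[seed_region - 1]
    rows = {}
    for r in members:
        d = np.linalg.norm(centroids[r - 1] - seed_pos)
        rows[r] = waveform * np.exp(-d * d / (2.0 * decay_sigma ** 2))
    return rows


def mean_adjacent_spacing(head: HeadModel) -> float:
    """Mean centroid distance over region adjacency edges (mm)."""
    c = head.region_centroids
    d = [np.linalg.norm(c[a - 1] - c[b - 1])
         for a, b in head.region_adjacency.edges()]
    return float(np.mean(d))


def simulate_sample_sereega(head: HeadModel, cfg: SereegaConfig,
                            rng: np.random.Generator) -> SimulationSample:
    """One event-related sample: patches -> waveforms -> projection -> noise.

    Draws distinct seed regions and one extension order and waveform per
    patch (all members of a patch share its waveform); overlapping patches
    sum. Fully reproducible from the generator state.
    """
    nr = head.n_regions
    if cfg.n_regions_active > nr:
        raise ValueError("more active regions requested than regions exist")
    t_grid = cfg.time_grid()
    sigma = cfg.decay_sigma if cfg.decay_sigma is not None else mean_adjacent_spacing(head)
    divisor = (cfg.region_size_divisor if cfg.region_size_divisor is not None
               else head.mean_region_size())

    seeds = rng.choice(np.arange(1, nr + 1), size=cfg.n_regions_active,
                       replace=False)
    X = np.zeros((nr, t_grid.size))
    active = []
    for s in seeds:
        order = int(rng.integers(cfg.order_range[0], cfg.order_range[1] + 1))
        members = grow_region(int(s), order, head.region_adjacency)
        p = ERWaveformParams(
            a=rng.uniform(*cfg.amplitude_range_nam) * _NAM / divisor,
            c=rng.uniform(*cfg.center_range),
            w=rng.uniform(*cfg.width_range))
        wf = er_waveform(p, t_grid)
        for r, row in assign_extended_activity(members, int(s), wf,
                                               head.region_centroids, sigma).items():
            X[r - 1] += row
        active.append((int(s), order, sorted(members)))

    Y_clean = project_forward(head.leadfield_regional, X)
    Y, _ = add_noise(Y_clean, cfg.snr_db, rng)
    return SimulationSample(X=X, Y_clean=Y_clean, Y=Y, active_regions=active,
                            snr_db=cfg.snr_db, generator_tag="sereega",
                            rng_seed=-1, fs=cfg.fs)
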