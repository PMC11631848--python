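"""Shared simulation containers: samples, datasets, sensor noise, splits."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["SimulationSample", "Dataset", "add_noise", "generate_dataset",
           "derive_seed"]


def derive_seed(master_seed: int, *keys) -> int:
    """Stable per-stage / per-sample seed below 2**31.

    Hashing (master seed, stage name, index) with SeedSequence means adding
    methods or stages never perturbs the seeds of existing ones.
    """
    import zlib
    ints = [int(master_seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2 ** 31))


@dataclass
class SimulationSample:
    """One paired (source, EEG) example.

    ``X`` is the ground-truth regional source matrix (Nr x T, A*m),
    ``Y_clean`` the projected EEG before sensor noise and ``Y`` after.
    For the neural-mass generator ``Y_clean`` includes the background
    source activity (it is what the sensor noise is scaled against),
    while ``X`` keeps only the active regions.
    """

    X: np.ndarray
    Y_clean: np.ndarray
    Y: np.ndarray
    active_regions: list            # [(seed_region, order, sorted member list)]
    snr_db: float
    generator_tag: str              # "sereega" | "nmm"
    rng_seed: int
    fs: float = 500.0

    @property
    def active_members(self) -> set:
        out = set()
        for _, _, members in self.active_regions:
            out.update(int(m) for m in members)
        return out

    @property
    def seed_regions(self) -> list:
        return [int(s) for s, _, _ in self.active_regions]


@dataclass
class Dataset:
    """A list of samples with a deterministic train/validation split."""

    samples: list
    split: float = 0.8
    master_seed: int = 0
    generator_tag: str = ""

    def __len__(self):
        return len(self.samples)

    @property
    def n_train(self) -> int:
        return int(round(self.split * len(self.samples)))

    @property
    def train(self) -> list:
        return self.samples[: self.n_train]

    @property
    def validation(self) -> list:
        return self.samples[self.n_train:]

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["meta"] = json.dumps({
                "n_samples": len(self.samples), "split": self.split,
                "master_seed": self.master_seed,
                "generator_tag": self.generator_tag,
            })
            for i, s in enumerate(self.samples):
                g = f.create_group(f"sample_{i:06d}")
                g.create_dataset("X", data=s.X.astype(np.float32))
                g.create_dataset("Y", data=s.Y.astype(np.float32))
                g.create_dataset("Y_clean", data=s.Y_clean.astype(np.float32))
                g.attrs["meta"] = json.dumps({
                    "active_regions": [[int(a), int(o), [int(m) for m in mem]]
                                       for a, o, mem in s.active_regions],
                    "snr_db": float(s.snr_db), "generator_tag": s.generator_tag,
                    "rng_seed": int(s.rng_seed), "fs": float(s.fs),
                })

    @classmethod
    def load(cls, path: str) -> "Dataset":
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            samples = []
            for i in range(meta["n_samples"]):
                g = f[f"sample_{i:06d}"]
                sm = json.loads(g.attrs["meta"])
                samples.append(SimulationSample(
                    X=g["X"][()].astype(float), Y=g["Y"][()].astype(float),
                    Y_clean=g["Y_clean"][()].astype(float),
                    active_regions=[(a, o, mem) for a, o, mem in sm["active_regions"]],
                    snr_db=sm["snr_db"], generator_tag=sm["generator_tag"],
                    rng_seed=sm["rng_seed"], fs=sm["fs"]))
        return cls(samples=samples, split=meta["split"],
                   master_seed=meta["master_seed"],
                   generator_tag=meta["generator_tag"])


def add_noise(Y_clean: np.ndarray, snr_db: float, rng: np.random.Generator):
    """Additive white sensor noise at an exact Frobenius-power SNR.

    epsilon is drawn i.i.d. standard normal and rescaled so that
    10 log10(||Y_clean||_F^2 / ||eps||_F^2) equals ``snr_db`` exactly.
    Returns (Y, epsilon).
    """
    norm_clean = np.linalg.norm(Y_clean)
    if norm_clean == 0:
        raise ValueError("SNR undefined for all-zero clean signal")
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    eps = rng.standard_normal(Y_clean.shape)
    eps *= norm_clean / (np.linalg.norm(eps) * 10 ** (snr_db / 20.0))
    return Y_clean + eps, eps


def generate_dataset(head, cfg, n_samples: int, split: float = 0.8,
                     master_seed: int | None = None) -> Dataset:
    """Simulate ``n_samples`` with per-sample derived seeds and split them.

    ``cfg`` selects the generator (SereegaConfig or NMMConfig); the split
    is by sample index (first ``split`` fraction trains). Deterministic
    given the master seed.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if not 0 < split < 1:
        raise ValueError("split must lie in (0, 1)")
    # local imports avoid a circular dependency
    from .sereega import SereegaConfig, simulate_sample_sereega
    from .nmm import NMMConfig, build_spike_bank, simulate_sample_nmm

    if master_seed is None:
        master_seed = cfg.rng_seed
    if isinstance(cfg, SereegaConfig):
        tag = "sereega"
        make = lambda rng: simulate_sample_sereega(head, cfg, rng)
    elif isinstance(cfg, NMMConfig):
        tag = "nmm"
        bank = build_spike_bank(head, cfg)
        make = lambda rng: simulate_sample_nmm(head, bank, cfg, rng)
    else:
        raise TypeError(f"unknown generator config {type(cfg)!r}")

    samples = []
    for i in range(n_samples):
        s = derive_seed(master_seed, tag, i)
        sample = make(np.random.default_rng(s))
        sample.rng_seed = s
        samples.append(sample)
    return Dataset(samples=samples, split=split, master_seed=master_seed,
                   generator_tag=tag)
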