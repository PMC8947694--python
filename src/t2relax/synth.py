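"""Synthetic multi-echo decay generation from the calibrated priors.

Samples are stored columnar in fixed-width arrays of length 15 with a ``-1``
pad (the same convention the neural network uses on its input nodes) plus an
explicit ``n`` column, so one serialization serves both the least-squares
fitters and the network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import EchoTrain
from .priors import PriorConfig

__all__ = [
    "SampleSet",
    "sample_echo_config",
    "generate_sampleset",
    "generate_fixed_snr_testset",
]

PAD = -1.0
MAX_N = 15


@dataclass
class SampleSet:
    """Columnar collection of echo trains with their true decay parameters.

    Arrays ``te`` and ``magnitude`` have shape ``(n_samples, 15)`` and are
    padded with ``-1`` beyond each sample's echo count ``n``.  ``snr`` is
    ``s0 / sigma`` (``inf`` where sigma is 0).  ``split`` tags each sample
    as ``'train'``, ``'val'`` or ``'test'``.
    """

    te: np.ndarray
    magnitude: np.ndarray
    n: np.ndarray
    s0: np.ndarray
    t2: np.ndarray
    sigma: np.ndarray
    snr: np.ndarray
    split: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.n)

    def subset(self, mask_or_split) -> "SampleSet":
        """Rows selected by a boolean mask or by split name."""
        if isinstance(mask_or_split, str):
            mask = self.split == mask_or_split
        else:
            mask = np.asarray(mask_or_split)
        return SampleSet(
            te=self.te[mask], magnitude=self.magnitude[mask], n=self.n[mask],
            s0=self.s0[mask], t2=self.t2[mask], sigma=self.sigma[mask],
            snr=self.snr[mask], split=self.split[mask], meta=dict(self.meta),
        )

    def echo_train(self, i: int) -> EchoTrain:
        """The i-th sample as an :class:`~t2relax.decay.EchoTrain`."""
        k = int(self.n[i])
        return EchoTrain(self.te[i, :k], self.magnitude[i, :k])

    def iter_trains(self):
        for i in range(len(self)):
            yield self.echo_train(i)

    # ---- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Write arrays to ``<path>.npz`` and metadata to ``<path>.json``."""
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"), te=self.te, magnitude=self.magnitude,
            n=self.n, s0=self.s0, t2=self.t2, sigma=self.sigma,
            snr=self.snr, split=self.split.astype("U5"),
        )
        path.with_suffix(".json").write_text(json.dumps(self.meta, indent=2))

    @classmethod
    def load(cls, path) -> "SampleSet":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as z:
            arrays = {k: z[k] for k in z.files}
        meta_file = path.with_suffix(".json")
        meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
        return cls(meta=meta, **arrays)

    def to_frame(self) -> pd.DataFrame:
        """Flat DataFrame view (one row per sample) for CSV export."""
        cols = {"n": self.n, "s0": self.s0, "t2": self.t2,
                "sigma": self.sigma, "snr": self.snr, "split": self.split}
        for k in range(MAX_N):
            cols[f"te_{k}"] = self.te[:, k]
        for k in range(MAX_N):
            cols[f"mag_{k}"] = self.magnitude[:, k]
        return pd.DataFrame(cols)


def sample_echo_config(
    rng: np.random.Generator, config: PriorConfig | None = None, size: int = 1
):
    """Draw echo-train configurations ``(te_start, te_step, n)``.

    ``te_start ~ U(5, 15)`` ms, ``te_step ~ U(2, 15)`` ms and the echo count
    ``n`` discrete-uniform on {5..15}; echo times follow as
    ``te_k = te_start + k * te_step``.
    """
    config = config or PriorConfig()
    te_start = rng.uniform(*config.te_start_range, size=size)
    te_step = rng.uniform(*config.te_step_range, size=size)
    n = rng.integers(config.n_range[0], config.n_range[1] + 1, size=size)
    if size == 1:
        return float(te_start[0]), float(te_step[0]), int(n[0])
    return te_start, te_step, n


def _draw_s0(rng: np.random.Generator, config: PriorConfig, size: int) -> np.ndarray:
    body = rng.uniform(0.0, config.s0_uniform_cap, size=size)
    tail = config.s0_uniform_cap + rng.exponential(config.s0_tail_scale, size=size)
    s0 = np.where(rng.random(size) < 0.5, body, tail)
    # exact zeros are excluded from every dataset (degenerate SNR / no signal)
    while np.any(s0 == 0.0):
        zero = s0 == 0.0
        s0[zero] = rng.uniform(0.0, config.s0_uniform_cap, size=int(zero.sum()))
    return s0


def _draw_t2(rng: np.random.Generator, config: PriorConfig, size: int) -> np.ndarray:
    return config.t2_shift + rng.lognormal(config.t2_log_mu, config.t2_log_sd, size=size)


def _assemble(
    rng: np.random.Generator,
    config: PriorConfig,
    s0: np.ndarray,
    t2: np.ndarray,
    sigma: np.ndarray,
    split: str,
) -> SampleSet:
    """Echo-time layout, noise-free decay and Rician corruption (vectorized)."""
    size = len(s0)
    te_start, te_step, n = sample_echo_config(rng, config, size=size)
    if size == 1:  # sample_echo_config returns scalars for size 1
        te_start, te_step, n = np.array([te_start]), np.array([te_step]), np.array([n])
    k = np.arange(MAX_N)[None, :]
    te = te_start[:, None] + te_step[:, None] * k
    valid = k < n[:, None]
    clean = s0[:, None] * np.exp(-te / t2[:, None])
    g1 = rng.normal(0.0, 1.0, size=(size, MAX_N)) * sigma[:, None]
    g2 = rng.normal(0.0, 1.0, size=(size, MAX_N)) * sigma[:, None]
    noisy = np.hypot(clean + g1, g2)
    with np.errstate(divide="ignore"):
        snr = np.where(sigma > 0, s0 / np.where(sigma > 0, sigma, 1.0), np.inf)
    return SampleSet(
        te=np.where(valid, te, PAD),
        magnitude=np.where(valid, noisy, PAD),
        n=n.astype(np.int64),
        s0=s0, t2=t2, sigma=sigma, snr=snr,
        split=np.full(size, split, dtype="U5"),
    )


def _concat(sets: list[SampleSet], meta: dict) -> SampleSet:
    return SampleSet(
        te=np.concatenate([s.te for s in sets]),
        magnitude=np.concatenate([s.magnitude for s in sets]),
        n=np.concatenate([s.n for s in sets]),
        s0=np.concatenate([s.s0 for s in sets]),
        t2=np.concatenate([s.t2 for s in sets]),
        sigma=np.concatenate([s.sigma for s in sets]),
        snr=np.concatenate([s.snr for s in sets]),
        split=np.concatenate([s.split for s in sets]),
        meta=meta,
    )


def generate_sampleset(
    counts: dict[str, int] | tuple[int, int, int],
    config: PriorConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> SampleSet:
    """Draw a train/val/test dataset from the calibrated priors.

    Per sample: ``S0`` from the mixture prior (exact zeros rejected), ``T2``
    from the shifted log-normal, ``sigma ~ U(0, 300]``, a random echo-time
    layout, then Rician corruption of the noise-free decay.  Fully
    reproducible given the seed/generator.

    Parameters
    ----------
    counts
        Mapping ``{'train': n, 'val': n, 'test': n}`` (splits with zero or
        missing count are omitted) or a (train, val, test) tuple.
    """
    config = config or PriorConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if not isinstance(counts, dict):
        counts = dict(zip(("train", "val", "test"), counts))
    sets = []
    for split in ("train", "val", "test"):
        size = int(counts.get(split, 0))
        if size == 0:
            continue
        s0 = _draw_s0(rng, config, size)
        t2 = _draw_t2(rng, config, size)
        lo, hi = config.sigma_range
        sigma = hi - rng.uniform(0.0, hi - lo, size=size)  # uniform on (lo, hi]
        sets.append(_assemble(rng, config, s0, t2, sigma, split))
    if not sets:
        raise ValueError("at least one split must have a positive count")
    return _concat(sets, {"counts": counts, "kind": "prior"})


def generate_fixed_snr_testset(
    snr: float,
    count: int,
    config: PriorConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> SampleSet:
    """Test set in which every sample sits exactly at the requested SNR.

    ``S0``, ``T2`` and the echo layout are drawn from the priors but the
    noise level is tied to the amplitude, ``sigma = S0 / snr``, so estimator
    error can be summarized as a function of a single SNR value.  Passing
    ``snr = inf`` yields noise-free decays (sigma = 0).
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    config = config or PriorConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    s0 = _draw_s0(rng, config, count)
    t2 = _draw_t2(rng, config, count)
    sigma = np.zeros(count) if np.isinf(snr) else s0 / snr
    out = _assemble(rng, config, s0, t2, sigma, "test")
    out.meta = {"counts": {"test": count}, "kind": "fixed_snr", "snr": snr}
    return out
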