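"""Synthetic labeled-fingerprint generators.

Real training sets for these models are curated compound libraries; the
generators here emulate their statistical structure so every model and
evaluation routine is testable without any download:

* :func:`gen_tox_data` — balanced binary-toxicity fingerprints in which a
  small set of informative bits carries a class signature (toxic = bit set),
  degraded by a configurable flip noise, over a Bernoulli background.  This
  mimics the separable toxic/non-toxic bit-pattern structure a fingerprint
  classifier exploits.
* :func:`gen_sascore_data` — fingerprints whose set-bit count is an affine,
  invertible function of a synthetic-accessibility score drawn from a skewed
  per-unit-bin distribution (28.3% of mass in the 2–3 range, matching the
  skew of real drug-like libraries), with Gaussian label noise.

Both are pure functions of their config: the same seed always reproduces the
same dataset (numpy PCG64 stream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SA_MAX, SA_MIN, LabeledDataset

#: per-unit-bin mass on [1,2), [2,3), ..., [9,10]; 0.283 on [2,3) by design,
#: with a decreasing tail above 5 emulating the skew of drug-like libraries
DEFAULT_BIN_WEIGHTS = (0.09, 0.283, 0.27, 0.15, 0.09, 0.06, 0.03, 0.017, 0.01)


@dataclass(frozen=True)
class ToxGenConfig:
    n_per_class: int = 200
    n_bits: int = 1024
    n_informative_bits: int = 8
    background_p: float = 0.1
    flip_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_informative_bits > self.n_bits:
            raise ValueError("n_informative_bits exceeds n_bits")
        for p in (self.background_p, self.flip_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SaGenConfig:
    n: int = 2000
    n_bits: int = 1024
    noise_sd: float = 0.5
    bin_weights: tuple[float, ...] = DEFAULT_BIN_WEIGHTS
    seed: int = 0

    def __post_init__(self):
        w = np.asarray(self.bin_weights, dtype=float)
        if w.size != 9 or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError("bin_weights must be 9 non-negative values summing to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def count_offset(self) -> int:
        """Set-bit count at SAscore 1."""
        return max(1, round(0.02 * self.n_bits))

    @property
    def count_slope(self) -> int:
        """Additional set bits per unit of SAscore; keeps counts <= 0.8*n_bits."""
        return max(1, (int(0.8 * self.n_bits) - self.count_offset) // 9)


def gen_tox_data(config: ToxGenConfig) -> LabeledDataset:
    """Balanced binary-toxicity fingerprints with planted informative bits.

    Informative bit positions (recorded in ``meta['informative_bits']``) are
    set equal to the class label (1 = toxic) and then flipped independently
    with probability ``flip_noise``; the remaining bits are iid
    Bernoulli(background_p).  Exactly ``n_per_class`` records per class.
    """
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_per_class
    y = np.array([0] * config.n_per_class + [1] * config.n_per_class, dtype=int)
    X = (rng.random((n, config.n_bits)) < config.background_p).astype(np.uint8)
    info = rng.choice(config.n_bits, size=config.n_informative_bits, replace=False)
    info = np.sort(info)
    X[:, info] = y[:, None]
    flips = rng.random((n, config.n_informative_bits)) < config.flip_noise
    X[:, info] ^= flips.astype(np.uint8)
    order = rng.permutation(n)
    X, y = X[order], y[order]
    ids = [f"synth-tox-{i}" for i in range(n)]
    return LabeledDataset(ids, X, y, meta={
        "generator": "gen_tox_data/v1",
        "informative_bits": info.tolist(),
        "config": config,
    })


def sascore_from_count(counts, config: SaGenConfig) -> np.ndarray:
    """Inverse of the affine score -> set-bit-count map."""
    return 1.0 + (np.asarray(counts, dtype=float) - config.count_offset) / config.count_slope


def gen_sascore_data(config: SaGenConfig) -> LabeledDataset:
    """Skew-distributed SAscore fingerprints with count-coded scores.

    A score is drawn by choosing a unit bin from ``bin_weights`` and a
    uniform position within it, quantized onto the grid induced by the
    integer count map (so the noiseless label is exactly recoverable from
    the set-bit count), and recorded with additive Gaussian noise clamped
    to [1, 10].  Set-bit positions are chosen uniformly at random.
    """
    rng = np.random.default_rng(config.seed)
    bins = rng.choice(9, size=config.n, p=np.asarray(config.bin_weights))
    raw = 1.0 + bins + rng.random(config.n)
    counts = config.count_offset + np.rint((raw - 1.0) * config.count_slope).astype(int)
    clean = sascore_from_count(counts, config)
    labels = clean + (rng.normal(0.0, config.noise_sd, config.n)
                      if config.noise_sd > 0 else 0.0)
    labels = np.clip(labels, SA_MIN, SA_MAX)
    X = np.zeros((config.n, config.n_bits), dtype=np.uint8)
    for i, c in enumerate(counts):
        X[i, rng.choice(config.n_bits, size=c, replace=False)] = 1
    ids = [f"synth-sa-{i}" for i in range(config.n)]
    return LabeledDataset(ids, X, np.asarray(labels, dtype=float), meta={
        "generator": "gen_sascore_data/v1",
        "count_offset": config.count_offset,
        "count_slope": config.count_slope,
        "config": config,
    })
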