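"""Bin-wise over/under-sampling of skewed SAscore-labeled datasets.

Synthetic-accessibility labels are heavily concentrated in the 2–5 range, so
a regressor trained on the raw distribution barely sees hard-to-make
molecules.  Balancing duplicates under-represented score ranges (exact whole
copies, no interpolation) and uniformly subsamples the over-represented 2–5
range, per-unit-range actions:

=========  ======================
[1, 2)     oversample x2
[2, 5)     undersample to 90,000
[5, 6)     unchanged
[6, 7)     oversample x2
[7, 8)     oversample x5
[8, 9)     oversample x20
[9, 10]    oversample x100
=========  ======================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import SA_MAX, SA_MIN, LabeledDataset

OVERSAMPLE = "oversample"
UNDERSAMPLE = "undersample"
UNCHANGED = "unchanged"

DEFAULT_UNDERSAMPLE_CAP = 90_000


@dataclass(frozen=True)
class Bin:
    """One score range and its action.

    ``value`` is the integer oversample ratio, the undersample cap, or
    ignored for unchanged bins.  The range is half-open ``[lower, upper)``
    except that the final bin of a plan includes its upper edge.
    """

    lower: float
    upper: float
    action: str
    value: int = 0

    def __post_init__(self):
        if self.action not in (OVERSAMPLE, UNDERSAMPLE, UNCHANGED):
            raise ValueError(f"unknown action {self.action!r}")
        if self.action != UNCHANGED and self.value < 1:
            raise ValueError(f"{self.action} value must be a positive integer")


@dataclass(frozen=True)
class ResamplingPlan:
    bins: tuple[Bin, ...]

    def __post_init__(self):
        bins = tuple(self.bins)
        object.__setattr__(self, "bins", bins)
        lo = SA_MIN
        for b in bins:
            if b.lower != lo or b.upper <= b.lower:
                raise ValueError("bins must be ordered, disjoint and cover [1, 10]")
            lo = b.upper
        if lo != SA_MAX:
            raise ValueError("bins must cover [1, 10]")

    def bin_index(self, score: float) -> int:
        for i, b in enumerate(self.bins):
            last = i == len(self.bins) - 1
            if b.lower <= score < b.upper or (last and score == b.upper):
                return i
        raise ValueError(f"SAscore {score} outside [1, 10]")

    def to_config(self) -> list[dict]:
        return [
            {"lower": b.lower, "upper": b.upper, "action": b.action, "value": b.value}
            for b in self.bins
        ]

    @classmethod
    def from_config(cls, items) -> "ResamplingPlan":
        return cls(tuple(Bin(**it) for it in items))


def default_plan(undersample_cap: int = DEFAULT_UNDERSAMPLE_CAP) -> ResamplingPlan:
    """The published balancing plan; cap overridable for desk-scale runs."""
    return ResamplingPlan((
        Bin(1, 2, OVERSAMPLE, 2),
        Bin(2, 5, UNDERSAMPLE, undersample_cap),
        Bin(5, 6, UNCHANGED),
        Bin(6, 7, OVERSAMPLE, 2),
        Bin(7, 8, OVERSAMPLE, 5),
        Bin(8, 9, OVERSAMPLE, 20),
        Bin(9, 10, OVERSAMPLE, 100),
    ))


def resample(ds: LabeledDataset, plan: ResamplingPlan | None = None,
             seed: int = 0) -> LabeledDataset:
    """Apply a resampling plan; deterministic for a given seed.

    An oversampled bin of size m with ratio r yields exactly r*m rows, each
    original duplicated r times; an undersampled bin yields min(m, cap)
    distinct rows drawn uniformly without replacement.  The result is
    shuffled with the seed.
    """
    if plan is None:
        plan = default_plan()
    if ds.y is None:
        raise ValueError("resample requires SAscore labels")
    y = np.asarray(ds.y, dtype=float)
    bad = np.where((y < SA_MIN) | (y > SA_MAX))[0]
    if bad.size:
        raise ValueError(
            f"SAscore outside [1, 10] for record '{ds.ids[bad[0]]}' ({y[bad[0]]})"
        )
    rng = np.random.default_rng(seed)
    members: list[list[int]] = [[] for _ in plan.bins]
    for i, s in enumerate(y):
        members[plan.bin_index(float(s))].append(i)

    out: list[np.ndarray] = []
    for b, idx in zip(plan.bins, members):
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            continue
        if b.action == OVERSAMPLE:
            out.append(np.repeat(idx, b.value))
        elif b.action == UNDERSAMPLE:
            if idx.size > b.value:
                idx = rng.choice(idx, size=b.value, replace=False)
            out.append(idx)
        else:
            out.append(idx)
    all_idx = np.concatenate(out) if out else np.empty(0, dtype=int)
    rng.shuffle(all_idx)
    return ds.subset(all_idx)
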