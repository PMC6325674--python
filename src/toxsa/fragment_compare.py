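"""Fragment-composition comparison between non-toxic and toxic compound sets.

Molecules decomposed into chemical fragments (canonical SMILES keys; the
decomposition itself is an input, one occurrence per row) yield per-set
frequency tables: frequency = occurrences of a fragment / total fragment
occurrences in the set.  Comparing the two tables on the union of keys gives
the Pearson correlation of the frequency profiles and, via a regression
line through the scatter, a signed-residual ranking: fragments below the
line are enriched in the non-toxic set, fragments above it in the toxic set.

The default line is the standardized-major-axis (geometric-mean) regression,
which treats both axes symmetrically so that swapping the sets exactly
negates every residual; ordinary least squares of toxic on non-toxic
frequency is available with ``line="ols"``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics_eval import pcc


@dataclass
class FragmentFrequencyTable:
    entries: dict[str, float]
    total_occurrences: int

    def __post_init__(self):
        s = sum(self.entries.values())
        if self.entries and abs(s - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {s}, not 1")


def frequencies(fragment_lists) -> FragmentFrequencyTable:
    """Occurrence frequencies over per-molecule fragment-key lists."""
    counts: Counter[str] = Counter()
    for frags in fragment_lists:
        counts.update(frags)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no fragment occurrences in input")
    return FragmentFrequencyTable(
        {k: v / total for k, v in counts.items()}, total
    )


def read_fragment_file(path) -> list[list[str]]:
    """Read ``molecule_id<TAB>fragment_smiles`` rows (one per occurrence)."""
    per_mol: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>fragment'")
            mol_id, frag = parts
            per_mol.setdefault(mol_id, []).append(frag.strip())
    return list(per_mol.values())


@dataclass
class ComparisonReport:
    table: pd.DataFrame = field(repr=False)
    pcc: float
    slope: float
    intercept: float
    line: str


def compare(non_toxic: FragmentFrequencyTable, toxic: FragmentFrequencyTable,
            line: str = "sma") -> ComparisonReport:
    """Correlate and rank fragment frequencies of the two sets.

    Tables are aligned on the union of fragment keys (absent key ->
    frequency 0).  The report table has one row per fragment with both
    frequencies, the signed residual of the toxic frequency about the
    fitted line (negative = enriched in the non-toxic set), and the rank by
    ascending residual (rank 1 = most non-toxic-enriched).
    """
    keys = sorted(set(non_toxic.entries) | set(toxic.entries))
    if len(keys) < 3:
        raise ValueError(f"need >= 3 fragment keys to compare, got {len(keys)}")
    x = np.array([non_toxic.entries.get(k, 0.0) for k in keys])
    y = np.array([toxic.entries.get(k, 0.0) for k in keys])
    r = pcc(y, x)
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        raise ValueError("constant frequency profile; no regression possible")
    if line == "sma":
        # positive-slope SMA line: swapping the tables maps a residual r to
        # -(sx/sy)*r, so the enrichment sign is exactly role-antisymmetric
        slope = float(sy / sx)
    elif line == "ols":
        slope = float(np.cov(x, y, bias=True)[0, 1] / sx**2)
    else:
        raise ValueError(f"unknown line type {line!r}")
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    order = np.argsort(resid, kind="stable")
    rank = np.empty(len(keys), dtype=int)
    rank[order] = np.arange(1, len(keys) + 1)
    table = pd.DataFrame({
        "fragment": keys,
        "freq_non_toxic": x,
        "freq_toxic": y,
        "residual": resid,
        "rank": rank,
    }).sort_values("rank").reset_index(drop=True)
    return ComparisonReport(table, r, float(slope), intercept, line)
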