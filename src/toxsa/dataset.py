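"""Labeled fingerprint datasets and their on-disk CSV form.

A :class:`LabeledDataset` aligns molecule identifiers, a binary fingerprint
matrix and per-molecule labels (continuous synthetic-accessibility scores in
[1, 10] or binary toxicity flags, 1 = toxic).  It is the single in-memory
container every model and evaluation routine in this package consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_BITS_DEFAULT = 1024

SA_MIN, SA_MAX = 1.0, 10.0


@dataclass
class LabeledDataset:
    """Aligned ids, fingerprints and labels.

    Parameters
    ----------
    ids
        Molecule identifiers, unique within the dataset.
    X
        ``(n, n_bits)`` array of {0, 1} fingerprint bits.
    y
        Per-record label: float SAscore in [1, 10] or int toxicity in {0, 1}
        (1 = toxic).  ``None`` for unlabeled prediction sets.
    """

    ids: list[str]
    X: np.ndarray
    y: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise ValueError("fingerprint matrix must be 2-D")
        if len(self.ids) != self.X.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but {self.X.shape[0]} fingerprint rows"
            )
        if self.y is not None:
            self.y = np.asarray(self.y)
            if self.y.shape[0] != self.X.shape[0]:
                raise ValueError("labels not aligned with fingerprints")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate molecule ids in dataset")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_bits(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        ids = [self.ids[i] for i in idx]
        # duplicated rows (oversampling) need unique ids for the invariant;
        # disambiguate repeats with a copy suffix
        seen: dict[str, int] = {}
        out_ids = []
        for s in ids:
            k = seen.get(s, 0)
            out_ids.append(s if k == 0 else f"{s}#dup{k}")
            seen[s] = k + 1
        y = None if self.y is None else self.y[idx]
        return LabeledDataset(out_ids, self.X[idx], y, dict(self.meta))


def to_fingerprint_csv(ds: LabeledDataset, path) -> None:
    """Write ``id,<label?>,b0..b{n-1}`` rows; the interchange fixture format."""
    cols = {"id": ds.ids}
    if ds.y is not None:
        name = "sascore" if np.issubdtype(ds.y.dtype, np.floating) else "tox"
        cols[name] = ds.y
    df = pd.DataFrame(cols)
    bits = pd.DataFrame(
        ds.X.astype(np.uint8), columns=[f"b{i}" for i in range(ds.n_bits)]
    )
    pd.concat([df, bits], axis=1).to_csv(path, index=False)


def from_fingerprint_csv(path) -> LabeledDataset:
    df = pd.read_csv(path)
    bit_cols = [c for c in df.columns if c.startswith("b") and c[1:].isdigit()]
    bit_cols.sort(key=lambda c: int(c[1:]))
    X = df[bit_cols].to_numpy(dtype=np.uint8)
    y = None
    if "sascore" in df.columns:
        y = df["sascore"].to_numpy(dtype=float)
    elif "tox" in df.columns:
        y = df["tox"].to_numpy(dtype=int)
    return LabeledDataset(list(df["id"].astype(str)), X, y)


def read_label_table(path) -> pd.DataFrame:
    """Read an id/sascore/tox label table (CSV or TSV, sniffed by header)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "id" not in df.columns:
        raise ValueError(f"label table {path} lacks an 'id' column")
    known = {"id", "sascore", "tox"}
    if not (set(df.columns) & known - {"id"}):
        raise ValueError(f"label table {path} has neither 'sascore' nor 'tox'")
    df["id"] = df["id"].astype(str)
    if "tox" in df.columns and not set(df["tox"].unique()) <= {0, 1}:
        raise ValueError("tox labels must be binary {0,1} (1 = toxic)")
    return df
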