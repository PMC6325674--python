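"""Molecule I/O, fingerprints, Tanimoto similarity and dataset curation.

Molecules are read from ``.smi`` files (one ``SMILES<whitespace>ID`` per
line) and encoded as 1024-bit hashed linear-path fingerprints — the
Daylight-style scheme in which every atom-bond path of up to seven bonds is
hashed onto a fixed-length bit vector.  Curation follows the conventions of
non-redundant compound-library construction: a 100–600 Da molecular-weight
window and greedy redundancy removal at a Tanimoto coefficient of 0.8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .dataset import LabeledDataset

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

N_BITS = 1024
MAX_PATH = 7
#: identifies the hashing scheme; stored in model metadata so train and
#: predict can never silently mix fingerprint definitions
FINGERPRINT_SCHEME = f"rdkit-linear-path/{N_BITS}bit/maxpath{MAX_PATH}/v1"

WEIGHT_LO_DEFAULT = 100.0
WEIGHT_HI_DEFAULT = 600.0
TC_THRESHOLD_DEFAULT = 0.8


@dataclass
class MoleculeRecord:
    """One molecule: identifier, SMILES, and lazily computed weight."""

    id: str
    smiles: str
    _mol_weight: float | None = None

    def mol(self):
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:
            raise ValueError(f"unparseable SMILES for record '{self.id}': {self.smiles!r}")
        return m

    @property
    def mol_weight(self) -> float:
        if self._mol_weight is None:
            self._mol_weight = Descriptors.MolWt(self.mol())
        return self._mol_weight


def read_smiles_file(path) -> list[MoleculeRecord]:
    """Parse a ``.smi`` file into records, skipping unparseable lines.

    Blank and ``#``-comment lines are ignored; a line is
    ``SMILES [identifier]`` and missing identifiers are assigned
    ``mol<line-number>`` (1-based).  Lines whose SMILES fails to parse are
    logged and skipped.  Raises ``ValueError`` if no valid molecule remains.
    """
    records: list[MoleculeRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            if Chem.MolFromSmiles(smiles) is None:
                logger.warning("line %d of %s: unparseable SMILES %r, skipped",
                               lineno, path, smiles)
                n_skipped += 1
                continue
            records.append(MoleculeRecord(mol_id, smiles))
    if n_skipped:
        logger.info("%s: skipped %d unparseable line(s)", path, n_skipped)
    if not records:
        raise ValueError(f"no valid molecules in {path}")
    return records


def compute_fingerprint(record: MoleculeRecord, n_bits: int = N_BITS) -> np.ndarray:
    """1024-bit hashed linear-path fingerprint (paths of 1..7 bonds).

    Deterministic, and invariant to SMILES re-spelling: two spellings of the
    same molecule canonicalize to the same graph and therefore hash to the
    same bits.
    """
    mol = record.mol()
    fp = Chem.RDKFingerprint(mol, minPath=1, maxPath=MAX_PATH, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr


def fingerprint_matrix(records, n_bits: int = N_BITS) -> np.ndarray:
    return np.vstack([compute_fingerprint(r, n_bits) for r in records])


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two bit vectors.

    Two all-zero fingerprints are defined to be identical (TC = 1.0) so that
    duplicate empty fingerprints are treated as redundant.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    inter = int(np.count_nonzero(a & b))
    return inter / union


def filter_by_weight(records, lo: float = WEIGHT_LO_DEFAULT,
                     hi: float = WEIGHT_HI_DEFAULT) -> list[MoleculeRecord]:
    """Keep records with ``lo <= molecular weight <= hi`` (bounds inclusive)."""
    if not lo < hi:
        raise ValueError(f"invalid weight window [{lo}, {hi}]")
    kept = []
    for r in records:
        try:
            w = r.mol_weight
        except ValueError:
            logger.warning("weight filter: skipping unparseable record %s", r.id)
            continue
        if lo <= w <= hi:
            kept.append(r)
    return kept


def redundancy_filter(ds: LabeledDataset,
                      tc_threshold: float = TC_THRESHOLD_DEFAULT) -> LabeledDataset:
    """Greedy non-redundant subset at a Tanimoto cutoff.

    Scanning in input order, a record is kept iff its similarity to every
    previously kept record is strictly below ``tc_threshold``; consequently
    all pairwise similarities among survivors are < threshold.
    """
    if not 0.0 < tc_threshold <= 1.0:
        raise ValueError("tc_threshold must be in (0, 1]")
    kept_idx: list[int] = []
    X = ds.X
    for i in range(len(ds)):
        if all(tanimoto(X[i], X[j]) < tc_threshold for j in kept_idx):
            kept_idx.append(i)
    return ds.subset(kept_idx)
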