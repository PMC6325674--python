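"""Model persistence: a single joblib archive per model.

Each archive stores the format version, the model kind, the fingerprint
scheme used at training time, and the model payload.  Loading refuses a
mismatched format version, and — when the caller states the scheme of the
fingerprints it is about to predict on — a mismatched fingerprint scheme,
so a model can never silently score fingerprints hashed differently from
its training data.
"""

from __future__ import annotations

import joblib

from .dbn_sascore import DbnModel
from .et_toxscore import ForestModel

FORMAT_VERSION = 1


def save_model(model, path, fingerprint_scheme: str | None = None,
               extra: dict | None = None) -> None:
    if isinstance(model, DbnModel):
        kind = "dbn_sascore"
        scheme = fingerprint_scheme or model.metadata.get("fingerprint_scheme")
    elif isinstance(model, ForestModel):
        kind = "et_toxscore"
        scheme = fingerprint_scheme or model.metadata.get("fingerprint_scheme")
    else:
        raise TypeError(f"cannot persist {type(model).__name__}")
    joblib.dump({
        "format_version": FORMAT_VERSION,
        "kind": kind,
        "fingerprint_scheme": scheme,
        "model": model,
        "extra": extra or {},
    }, path)


def load_model(path, expect_scheme: str | None = None):
    """Load an archive; returns ``(model, payload_dict)``."""
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format version {version} not supported "
            f"(expected {FORMAT_VERSION})"
        )
    if expect_scheme is not None and payload.get("fingerprint_scheme") != expect_scheme:
        raise ValueError(
            f"{path}: fingerprint scheme mismatch: model trained with "
            f"{payload.get('fingerprint_scheme')!r}, run uses {expect_scheme!r}"
        )
    return payload["model"], payload
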