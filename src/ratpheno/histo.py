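"""Histomorphometric indices.

Two proportions summarize muscle histology here: the pathological index
(fraction of segmented fibre events that are not normal-shaped fibres, from
haematoxylin-eosin sections) and the fibrosis area fraction (stained pixels
over tissue pixels, from Sirius-red sections).  Both consume pre-segmented
inputs — an event table with a binary category, and binary masks — and both
are plain percentages, permutation-invariant and bounded in [0, 100].
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError

NORMAL_CATEGORY = "normal_fibre"


def pathological_index(events: pd.DataFrame) -> float:
    """Percentage of events whose category is not ``normal_fibre``.

    ``events`` needs a ``category`` column; every other value (necrotic,
    regenerating, infiltrate, ...) counts as abnormal.
    """
    if "category" not in events.columns:
        raise ValidationError("events table needs a 'category' column")
    n = len(events)
    if n == 0:
        raise DegenerateInputError("zero events: pathological index undefined")
    n_abn = int((events["category"] != NORMAL_CATEGORY).sum())
    return n_abn / n * 100.0


def fibrosis_fraction(tissue_mask: np.ndarray, stained_mask: np.ndarray) -> float:
    """Stained area as a percentage of tissue area.

    Masks are boolean (or 0/1) arrays of identical shape; every stained
    pixel must lie inside the tissue.
    """
    tissue = np.asarray(tissue_mask).astype(bool)
    stained = np.asarray(stained_mask).astype(bool)
    if tissue.shape != stained.shape:
        raise ValidationError("tissue and stained masks must have the same shape")
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise DegenerateInputError("empty tissue mask")
    if np.any(stained & ~tissue):
        raise ValidationError("stained pixels found outside the tissue mask")
    return int(stained.sum()) / n_tissue * 100.0


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event CSV (columns: event_id, category[, subtype])."""
    df = pd.read_csv(path, dtype=str)
    if "category" not in df.columns:
        raise ValidationError(f"events file {path}: missing 'category' column")
    return df


def read_mask_csv(path: str | Path) -> np.ndarray:
    """Read a binary mask stored as a headerless 0/1 CSV grid."""
    arr = pd.read_csv(path, header=None).to_numpy()
    return arr.astype(bool)


def write_mask_csv(mask: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(mask).astype(int)).to_csv(path, header=False, index=False)
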