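"""Animal records and cohort CSV input/output.

The cohort table is the anchor of the whole analysis: one row per animal per
timepoint, carrying the growth corrector (tibia length), body mass and any
number of organ masses.  The on-disk schema embeds units in the column names
(`tibia_length_mm`, `body_mass_g`, `<organ>_mass_g`) so that a mis-exported
table fails loudly instead of silently shifting a decade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import SchemaError, ValidationError

GENOTYPES = ("WT", "DMD")

#: mandatory cohort columns, in canonical order
COHORT_COLUMNS = ("animal_id", "genotype", "timepoint", "tibia_length_mm", "body_mass_g")

ORGAN_SUFFIX = "_mass_g"


@dataclass(frozen=True)
class AnimalRecord:
    """One animal observed at one timepoint.

    Parameters
    ----------
    animal_id : str
        Stable identifier, unique together with ``timepoint``.
    genotype : str
        ``"WT"`` or ``"DMD"``.
    timepoint : str
        Age label, e.g. ``"6mo"``.
    tibia_length_mm : float
        Tibia length in millimetres; strictly positive.  Its cube is the
        growth corrector used throughout.
    body_mass_g : float
        Whole-body mass in grams.
    organ_masses_g : dict
        Organ name -> mass in grams.  Any subset of organs may be present.
    """

    animal_id: str
    genotype: str
    timepoint: str
    tibia_length_mm: float
    body_mass_g: float
    organ_masses_g: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(
                f"animal {self.animal_id!r}: genotype must be one of {GENOTYPES}, "
                f"got {self.genotype!r}"
            )
        if not self.tibia_length_mm > 0:
            raise ValidationError(
                f"animal {self.animal_id!r}: tibia_length_mm must be > 0, "
                f"got {self.tibia_length_mm}"
            )
        if not self.body_mass_g > 0:
            raise ValidationError(
                f"animal {self.animal_id!r}: body_mass_g must be > 0, got {self.body_mass_g}"
            )
        for organ, mass in self.organ_masses_g.items():
            if not mass > 0:
                raise ValidationError(
                    f"animal {self.animal_id!r}: organ {organ!r} mass must be > 0, got {mass}"
                )

    @property
    def tl3_mm3(self) -> float:
        """Cubic tibia length (mm^3), the growth corrector."""
        return self.tibia_length_mm**3


def read_cohort(path: str | Path) -> list[AnimalRecord]:
    """Read a cohort CSV into a list of :class:`AnimalRecord`.

    Raises
    ------
    SchemaError
        If a mandatory column is absent (the message names it).
    ValidationError
        If a row violates an invariant; the message cites the 1-based data
        row number.
    """
    df = pd.read_csv(path, dtype={"animal_id": str, "genotype": str, "timepoint": str})
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cohort file {path}: missing mandatory column {col!r}")
    organ_cols = [
        c for c in df.columns if c.endswith(ORGAN_SUFFIX) and c not in COHORT_COLUMNS
    ]
    records: list[AnimalRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = row._asdict()
        organs = {
            c[: -len(ORGAN_SUFFIX)]: float(rowd[c])
            for c in organ_cols
            if pd.notna(rowd[c])
        }
        try:
            rec = AnimalRecord(
                animal_id=str(rowd["animal_id"]),
                genotype=str(rowd["genotype"]),
                timepoint=str(rowd["timepoint"]),
                tibia_length_mm=float(rowd["tibia_length_mm"]),
                body_mass_g=float(rowd["body_mass_g"]),
                organ_masses_g=organs,
            )
        except ValidationError as exc:
            raise ValidationError(f"cohort file {path}, row {i}: {exc}") from exc
        key = (rec.animal_id, rec.timepoint)
        if key in seen:
            raise ValidationError(
                f"cohort file {path}, row {i}: duplicate (animal_id, timepoint) {key}"
            )
        seen.add(key)
        records.append(rec)
    return records


def cohort_frame(records: Iterable[AnimalRecord]) -> pd.DataFrame:
    """Render records as a flat DataFrame with the canonical column layout."""
    records = list(records)
    organs = sorted({o for r in records for o in r.organ_masses_g})
    rows = []
    for r in records:
        row: dict[str, object] = {
            "animal_id": r.animal_id,
            "genotype": r.genotype,
            "timepoint": r.timepoint,
            "tibia_length_mm": r.tibia_length_mm,
            "body_mass_g": r.body_mass_g,
        }
        for o in organs:
            row[o + ORGAN_SUFFIX] = r.organ_masses_g.get(o, float("nan"))
        rows.append(row)
    cols = list(COHORT_COLUMNS) + [o + ORGAN_SUFFIX for o in organs]
    return pd.DataFrame(rows, columns=cols)


def write_cohort(records: Iterable[AnimalRecord], path: str | Path) -> None:
    """Write records to CSV (UTF-8, '.' decimal, 12 significant digits)."""
    cohort_frame(records).to_csv(path, index=False, float_format="%.12g")
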