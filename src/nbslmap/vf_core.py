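"""Domain types and inclusion filters for 24-2 visual-field records.

Coordinates follow the right-eye field convention: ``h_deg`` is horizontal
visual angle in degrees with positive values temporal (the physiological
blind spot sits near +15), ``v_deg`` is vertical visual angle with positive
values in the superior field.  All analysis code assumes records have been
normalized to this convention; left-eye records are mirrored about the
vertical meridian by :func:`transpose_to_right_eye`.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

#: Humphrey default blind-spot location (right-eye format).  Returned by the
#: perimeter when the blind-spot test fails or is switched off, and therefore
#: indistinguishable from a genuine result at the same cell.
DEFAULT_NBSL = (15, -1)

# Inclusion thresholds used in clinical practice; rates are fractions.
MAX_FIXATION_LOSS = 0.33
MAX_FALSE_NEGATIVE = 0.20
MAX_FALSE_POSITIVE = 0.20
MIN_MD_DB = -1.0


@dataclass(frozen=True, order=True)
class VFLocation:
    """One 24-2 test location; both coordinates are odd multiples of 3."""

    h_deg: int
    v_deg: int

    def __post_init__(self) -> None:
        for c in (self.h_deg, self.v_deg):
            if c % 3 != 0 or (c // 3) % 2 == 0:
                raise ValueError(
                    f"24-2 coordinates are odd multiples of 3, got {(self.h_deg, self.v_deg)}"
                )


@dataclass(frozen=True, order=True)
class BlindSpotLocation:
    """Reported blind-spot center, at the perimeter's 1-degree resolution."""

    h_deg: int
    v_deg: int

    @property
    def is_default(self) -> bool:
        return (self.h_deg, self.v_deg) == DEFAULT_NBSL


@dataclass
class VFRecord:
    """A single visual-field test with reliability/global indices and NBSL.

    ``pd_values`` holds pattern-deviation values (dB) for exactly the 52
    analysis locations (the two locations adjacent to the default blind spot
    are never tested against norms).  ``eye`` records the tested eye;
    ``right_eye_format`` says whether coordinates have been mirrored into
    right-eye convention.
    """

    patient_id: str
    eye: str  # "L" or "R"
    test_date: _dt.date
    age: float
    se_diopters: float
    md_db: float
    psd_abnormal: bool
    ght: str  # "WNL" or "OTHER"
    fixation_loss_rate: float
    fp_rate: float
    fn_rate: float
    nbsl: BlindSpotLocation
    pd_values: dict[VFLocation, float]
    right_eye_format: bool = False


@dataclass(frozen=True)
class Grid24_2:
    all_locations: tuple[VFLocation, ...]
    analysis_locations: tuple[VFLocation, ...]
    excluded_pair: tuple[VFLocation, VFLocation]


_GRID: Grid24_2 | None = None


def location_grid_24_2() -> Grid24_2:
    """Return the canonical 24-2 layout (54 points, 52 analysis locations).

    The two excluded points are the members of the layout nearest (by
    Euclidean distance) to the default blind-spot location (15, -1).
    """
    global _GRID
    if _GRID is not None:
        return _GRID
    with resources.files("nbslmap.data").joinpath("grid24_2.csv").open() as fh:
        df = pd.read_csv(fh)
    locs = [VFLocation(int(r.h_deg), int(r.v_deg)) for r in df.itertuples()]
    if len(locs) != 54:
        raise RuntimeError(f"grid fixture has {len(locs)} locations, expected 54")
    by_dist = sorted(locs, key=lambda p: math.hypot(p.h_deg - 15, p.v_deg + 1))
    excluded = tuple(sorted(by_dist[:2]))
    analysis = tuple(p for p in _pd_column_order(locs) if p not in excluded)
    _GRID = Grid24_2(tuple(locs), analysis, excluded)  # type: ignore[arg-type]
    return _GRID


def _pd_column_order(locs: Iterable[VFLocation]) -> list[VFLocation]:
    """Row-major order: v descending, then h ascending (the file order)."""
    return sorted(locs, key=lambda p: (-p.v_deg, p.h_deg))


def transpose_to_right_eye(record: VFRecord) -> VFRecord:
    """Mirror a left-eye record about the vertical meridian.

    Right-eye records (or records already normalized) are returned with only
    the ``right_eye_format`` flag set.  Idempotent after the first call.
    """
    if record.right_eye_format or record.eye == "R":
        return dataclasses.replace(record, right_eye_format=True)
    nbsl = BlindSpotLocation(-record.nbsl.h_deg, record.nbsl.v_deg)
    pd_values = {
        VFLocation(-loc.h_deg, loc.v_deg): val for loc, val in record.pd_values.items()
    }
    return dataclasses.replace(
        record, nbsl=nbsl, pd_values=pd_values, right_eye_format=True
    )


def nbsl_distance(nbsl: BlindSpotLocation) -> float:
    """Euclidean distance (degrees) of the blind-spot center from fixation."""
    return math.hypot(nbsl.h_deg, nbsl.v_deg)


def nbsl_angle(nbsl: BlindSpotLocation) -> float:
    """Polar angle (degrees) of the blind-spot center, in (-180, 180].

    Zero lies on the horizontal meridian toward the temporal field; negative
    angles are inferior.  Undefined at fixation.
    """
    if nbsl.h_deg == 0 and nbsl.v_deg == 0:
        raise ValueError("angle undefined for a blind spot at fixation")
    return math.degrees(math.atan2(nbsl.v_deg, nbsl.h_deg))


@dataclass
class ExclusionEntry:
    record: VFRecord
    reason: str


@dataclass
class FilterResult:
    included: list[VFRecord]
    excluded: list[ExclusionEntry] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.excluded:
            out[e.reason] = out.get(e.reason, 0) + 1
        return out


def _validate(record: VFRecord) -> str | None:
    rates = (record.fixation_loss_rate, record.fp_rate, record.fn_rate)
    if any(not (0.0 <= r <= 1.0) or not np.isfinite(r) for r in rates):
        return "malformed: reliability rate outside [0, 1]"
    if len(record.pd_values) != 52:
        return f"malformed: {len(record.pd_values)} PD values, expected 52"
    if record.eye not in ("L", "R"):
        return f"malformed: unknown eye code {record.eye!r}"
    return None


def apply_inclusion_filters(
    records: Iterable[VFRecord],
    seed: int,
    *,
    max_fl: float = MAX_FIXATION_LOSS,
    max_fn: float = MAX_FALSE_NEGATIVE,
    max_fp: float = MAX_FALSE_POSITIVE,
    min_md: float = MIN_MD_DB,
) -> FilterResult:
    """Apply the cohort selection pipeline and keep an exclusion log.

    Order: (1) reliability (FL <= 0.33, FN <= 0.20, FP <= 0.20);
    (2) most recent surviving test per eye; (3) clinically unaffected
    (MD >= -1 dB, PSD not abnormal, GHT within normal limits); (4) drop
    default blind-spot results; (5) one eye per patient by a seeded draw.
    Reliability precedes recency because the most recent *reliable* test is
    wanted, not the most recent test outright.

    Every input record appears either in ``included`` or in ``excluded``.
    """
    result = FilterResult(included=[])
    reliable: list[VFRecord] = []
    for rec in records:
        problem = _validate(rec)
        if problem is not None:
            result.excluded.append(ExclusionEntry(rec, problem))
        elif (
            rec.fixation_loss_rate > max_fl
            or rec.fn_rate > max_fn
            or rec.fp_rate > max_fp
        ):
            result.excluded.append(ExclusionEntry(rec, "reliability"))
        else:
            reliable.append(rec)

    # most recent reliable test per eye; ties broken by input order (later wins)
    latest: dict[tuple[str, str], VFRecord] = {}
    for rec in reliable:
        key = (rec.patient_id, rec.eye)
        if key not in latest or rec.test_date >= latest[key].test_date:
            if key in latest:
                result.excluded.append(ExclusionEntry(latest[key], "superseded"))
            latest[key] = rec
        else:
            result.excluded.append(ExclusionEntry(rec, "superseded"))

    normal: list[VFRecord] = []
    for rec in latest.values():
        if rec.md_db < min_md or rec.psd_abnormal or rec.ght != "WNL":
            result.excluded.append(ExclusionEntry(rec, "normality"))
            continue
        normalized = transpose_to_right_eye(rec)
        if normalized.nbsl.is_default:
            result.excluded.append(ExclusionEntry(rec, "default_nbsl"))
        else:
            normal.append(normalized)

    by_patient: dict[str, list[VFRecord]] = {}
    for rec in normal:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    rng = np.random.default_rng(seed)
    for pid in sorted(by_patient):
        eyes = sorted(by_patient[pid], key=lambda r: r.eye)
        if len(eyes) == 1:
            result.included.append(eyes[0])
        else:
            keep = int(rng.integers(len(eyes)))
            for i, rec in enumerate(eyes):
                if i == keep:
                    result.included.append(rec)
                else:
                    result.excluded.append(ExclusionEntry(rec, "fellow_eye"))
    return result


# ---------------------------------------------------------------------------
# Delimited-text record I/O

_META_COLUMNS = [
    "patient_id",
    "eye",
    "test_date",
    "age",
    "se_diopters",
    "md_db",
    "psd_abnormal",
    "ght",
    "fixation_loss_rate",
    "fp_rate",
    "fn_rate",
    "nbsl_h",
    "nbsl_v",
    "right_eye_format",
]


def pd_column_names() -> list[str]:
    grid = location_grid_24_2()
    return [f"pd_{p.h_deg}_{p.v_deg}" for p in grid.analysis_locations]


def _needs_mirror(eye: str, right_eye_format: bool) -> bool:
    return eye == "L" and not right_eye_format


def read_records(path, *, delimiter: str = ",") -> list[VFRecord]:
    """Read visual-field records from a delimited text table.

    One row per test; see :func:`write_records` for the column layout.
    Raises ``ValueError`` naming the column / line for structural problems.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"patient_id": str})
    expected = _META_COLUMNS + pd_column_names()
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    grid = location_grid_24_2()
    records = []
    pd_cols = pd_column_names()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        values = dict(zip(df.columns, row))
        eye = str(values["eye"])
        if eye not in ("L", "R"):
            raise ValueError(f"line {i}: unknown eye code {eye!r}")
        ref = bool(int(values["right_eye_format"]))
        mirror = _needs_mirror(eye, ref)
        pdv = {}
        for col, loc in zip(pd_cols, grid.analysis_locations):
            raw = values[col]
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"line {i}: non-numeric PD value {raw!r} in column {col}"
                ) from None
            key = VFLocation(-loc.h_deg, loc.v_deg) if mirror else loc
            pdv[key] = val
        records.append(
            VFRecord(
                patient_id=str(values["patient_id"]),
                eye=eye,
                test_date=_dt.date.fromisoformat(str(values["test_date"])),
                age=float(values["age"]),
                se_diopters=float(values["se_diopters"]),
                md_db=float(values["md_db"]),
                psd_abnormal=bool(int(values["psd_abnormal"])),
                ght=str(values["ght"]),
                fixation_loss_rate=float(values["fixation_loss_rate"]),
                fp_rate=float(values["fp_rate"]),
                fn_rate=float(values["fn_rate"]),
                nbsl=BlindSpotLocation(int(values["nbsl_h"]), int(values["nbsl_v"])),
                pd_values=pdv,
                right_eye_format=ref,
            )
        )
    return records


def write_records(records: Iterable[VFRecord], path, *, delimiter: str = ",") -> None:
    """Write records as delimited text (inverse of :func:`read_records`).

    PD columns are named ``pd_<h>_<v>`` in right-eye-format labels, ordered
    row-major over the 52 analysis locations (v descending, h ascending).
    For raw left-eye rows (``right_eye_format`` 0) the column labelled
    ``pd_<h>_<v>`` holds the value measured at the mirrored location
    ``(-h, v)``; ``nbsl_h`` stays in the eye's own convention.
    """
    grid = location_grid_24_2()
    rows = []
    for rec in records:
        mirror = _needs_mirror(rec.eye, rec.right_eye_format)
        expected = {
            VFLocation(-p.h_deg, p.v_deg) if mirror else p
            for p in grid.analysis_locations
        }
        if set(rec.pd_values) != expected:
            raise ValueError(
                "record PD locations do not match the 52 analysis locations "
                f"for eye={rec.eye!r}, right_eye_format={rec.right_eye_format}"
            )
        row: dict[str, object] = {
            "patient_id": rec.patient_id,
            "eye": rec.eye,
            "test_date": rec.test_date.isoformat(),
            "age": rec.age,
            "se_diopters": rec.se_diopters,
            "md_db": rec.md_db,
            "psd_abnormal": int(rec.psd_abnormal),
            "ght": rec.ght,
            "fixation_loss_rate": rec.fixation_loss_rate,
            "fp_rate": rec.fp_rate,
            "fn_rate": rec.fn_rate,
            "nbsl_h": rec.nbsl.h_deg,
            "nbsl_v": rec.nbsl.v_deg,
            "right_eye_format": int(rec.right_eye_format),
        }
        for p in grid.analysis_locations:
            key = VFLocation(-p.h_deg, p.v_deg) if mirror else p
            row[f"pd_{p.h_deg}_{p.v_deg}"] = rec.pd_values[key]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
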