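"""Domain types and I/O for grid-based small-mammal live-trapping data.

The study design is a robust one: each summer contains a few widely spaced
*primary* trapping periods (population open between them) and each primary
period contains up to ten closely spaced *secondary* occasions (population
closed within).  Animals are trapped on rectangular grids of single-capture
live traps at 30-m spacing; station coordinates are grid-local metres with
the origin at the south-west station.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

ADULT_MASS_G = {"F": 28.0, "M": 30.0}
"""Adult body-mass threshold (g) at first capture, per sex."""

CLASSES = ("adult_female", "adult_male", "juvenile_female", "juvenile_male")

CAPTURE_COLUMNS = [
    "individual_id", "year", "primary", "occasion", "grid_id",
    "col", "row", "sex", "mass_g", "repro", "pregnant",
]


class ValidationError(ValueError):
    """A capture record is inconsistent with the grid geometry or trap semantics."""


@dataclass(frozen=True)
class TrapStation:
    grid_id: str
    col: int
    row: int
    x: float
    y: float


@dataclass
class TrapGrid:
    """A rectangular trapping grid (12x12 or 8x12 stations, 30-m spacing).

    ``exclosure_years`` marks summers in which this grid was fenced against
    predators; in those years the grid contributes a distinct level of the
    grid covariate in all downstream models.
    """

    grid_id: str
    habitat: str
    n_cols: int
    n_rows: int
    spacing_m: float = 30.0
    exclosure_years: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.exclosure_years = frozenset(self.exclosure_years)

    @property
    def n_stations(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def stations(self) -> list[TrapStation]:
        s = self.spacing_m
        return [
            TrapStation(self.grid_id, c, r, c * s, r * s)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
        ]

    def station_xy(self) -> np.ndarray:
        """(n_stations, 2) array of station coordinates, row-major by (row, col)."""
        cols, rows = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        return np.column_stack([cols.ravel(), rows.ravel()]).astype(float) * self.spacing_m

    def station_index(self, col: int, row: int) -> int:
        if not (0 <= col < self.n_cols and 0 <= row < self.n_rows):
            raise ValidationError(
                f"station ({col},{row}) outside {self.n_cols}x{self.n_rows} grid {self.grid_id!r}"
            )
        return row * self.n_cols + col

    def covariate_level(self, year: int) -> str:
        """Grid covariate level for a year: the grid id, or 'exclosure' in fenced years."""
        return "exclosure" if year in self.exclosure_years else self.grid_id


@dataclass
class CaptureEvent:
    individual_id: str
    year: int
    primary: int
    occasion: int
    grid_id: str
    col: int
    row: int
    sex: str
    mass_g: float | None = None
    repro: str | None = None
    pregnant: bool = False

    def xy(self, grid: TrapGrid) -> tuple[float, float]:
        return self.col * grid.spacing_m, self.row * grid.spacing_m


@dataclass
class SessionHistory:
    """Detections of one individual within one closed session (grid/year/primary).

    ``detections`` is a 0/1 matrix of shape (n_occasions, n_stations); a
    single-capture trap permits at most one detection per occasion, so each
    row sums to 0 or 1.
    """

    individual_id: str
    year: int
    primary: int
    grid_id: str
    detections: np.ndarray
    sex: str = "F"
    age_class: str = "adult"

    @property
    def n_captures(self) -> int:
        return int(self.detections.sum())

    @property
    def sexage(self) -> str:
        return f"{self.age_class}_{'female' if self.sex == 'F' else 'male'}"


@dataclass
class AnnualHistory:
    """Presence of one individual across the primary periods of one year."""

    individual_id: str
    year: int
    grid_id: str
    presence: np.ndarray  # 0/1, length = number of primaries that year
    sexage: str
    grid_level: str


def classify_age(sex: str, mass_g: float | None) -> str:
    """Age class from first-capture body mass: adult at >=28 g (F) / >=30 g (M).

    Missing mass gives ``"unknown"``; such individuals are excluded from
    class-specific analyses.
    """
    if mass_g is None or (isinstance(mass_g, float) and np.isnan(mass_g)):
        return "unknown"
    if mass_g <= 0:
        raise ValueError(f"mass must be positive, got {mass_g}")
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    return "adult" if mass_g >= ADULT_MASS_G[sex] else "juvenile"


def first_capture_class(events: Sequence[CaptureEvent]) -> str:
    """Sex-age class of an individual within a year, fixed at its first capture.

    The first capture is the earliest (primary, occasion); the class does not
    flip if the animal later crosses the mass threshold within the season.
    """
    ev = min(events, key=lambda e: (e.primary, e.occasion))
    age = classify_age(ev.sex, ev.mass_g)
    if age == "unknown":
        return "unknown"
    return f"{age}_{'female' if ev.sex == 'F' else 'male'}"


# ---------------------------------------------------------------------------
# File I/O

def read_grids(path: str | Path) -> list[TrapGrid]:
    """Read grid geometry from YAML/JSON: a list of grid mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    grids = []
    for g in raw["grids"] if isinstance(raw, dict) else raw:
        grids.append(TrapGrid(
            grid_id=str(g["id"]),
            habitat=g.get("habitat", "mesic1"),
            n_cols=int(g["n_cols"]),
            n_rows=int(g["n_rows"]),
            spacing_m=float(g.get("spacing_m", 30.0)),
            exclosure_years=frozenset(g.get("exclosure_years", []) or []),
        ))
    return grids


def write_grids(grids: Iterable[TrapGrid], path: str | Path) -> None:
    payload = {"grids": [
        {"id": g.grid_id, "habitat": g.habitat, "n_cols": g.n_cols,
         "n_rows": g.n_rows, "spacing_m": g.spacing_m,
         "exclosure_years": sorted(g.exclosure_years)}
        for g in grids
    ]}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def events_to_frame(events: Iterable[CaptureEvent]) -> pd.DataFrame:
    rows = [
        (e.individual_id, e.year, e.primary, e.occasion, e.grid_id, e.col,
         e.row, e.sex, e.mass_g, e.repro, e.pregnant)
        for e in events
    ]
    return pd.DataFrame(rows, columns=CAPTURE_COLUMNS)


def write_captures(events: Iterable[CaptureEvent], path: str | Path) -> None:
    df = events_to_frame(events)
    df = df.copy()
    df["pregnant"] = df["pregnant"].map({True: 1, False: 0})
    df.to_csv(path, index=False, na_rep="")


def read_captures(path: str | Path | io.IOBase, grid_defs: Sequence[TrapGrid]) -> list[CaptureEvent]:
    """Read the capture CSV dialect, validating every row against grid geometry.

    Raises :class:`ValidationError` listing offending line numbers for rows
    that reference unknown grids or stations outside the lattice.  Missing
    body mass is kept as ``None``.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "grid_id": str, "sex": str})
    missing = [c for c in CAPTURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"capture file missing columns: {missing}")
    grids = {g.grid_id: g for g in grid_defs}
    events: list[CaptureEvent] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        gid = str(row.grid_id)
        grid = grids.get(gid)
        if grid is None:
            errors.append(f"line {i}: unknown grid {gid!r}")
            continue
        col, r = int(row.col), int(row.row)
        if not (0 <= col < grid.n_cols and 0 <= r < grid.n_rows):
            errors.append(f"line {i}: station ({col},{r}) outside {grid.n_cols}x{grid.n_rows} grid {gid!r}")
            continue
        sex = str(row.sex)
        if sex not in ("M", "F"):
            errors.append(f"line {i}: bad sex {sex!r}")
            continue
        mass = None if pd.isna(row.mass_g) else float(row.mass_g)
        repro = None if pd.isna(row.repro) else str(row.repro)
        preg = False if pd.isna(row.pregnant) else bool(int(row.pregnant))
        events.append(CaptureEvent(
            individual_id=str(row.individual_id), year=int(row.year),
            primary=int(row.primary), occasion=int(row.occasion),
            grid_id=gid, col=col, row=r, sex=sex, mass_g=mass,
            repro=repro, pregnant=preg,
        ))
    if errors:
        raise ValidationError("; ".join(errors))
    _check_single_grid(events)
    return events


def _check_single_grid(events: Sequence[CaptureEvent]) -> None:
    seen: dict[str, str] = {}
    for e in events:
        g = seen.setdefault(e.individual_id, e.grid_id)
        if g != e.grid_id:
            raise ValidationError(
                f"individual {e.individual_id!r} captured on grids {g!r} and {e.grid_id!r};"
                " inter-grid recaptures are not supported"
            )


# ---------------------------------------------------------------------------
# Capture histories

def build_session_histories(
    events: Sequence[CaptureEvent],
    grid: TrapGrid,
    n_occasions: int | None = None,
) -> list[SessionHistory]:
    """Per-individual detection matrices for one closed session.

    All events must come from a single grid/year/primary.  Two detections of
    the same individual in one occasion violate single-capture trap semantics
    and raise :class:`ValidationError`.
    """
    if not events:
        return []
    keys = {(e.grid_id, e.year, e.primary) for e in events}
    if len(keys) > 1:
        raise ValidationError(f"events span multiple sessions: {sorted(keys)}")
    gid, year, primary = keys.pop()
    if gid != grid.grid_id:
        raise ValidationError(f"events are from grid {gid!r}, not {grid.grid_id!r}")
    if n_occasions is None:
        n_occasions = max(e.occasion for e in events)
    by_ind: dict[str, list[CaptureEvent]] = {}
    for e in events:
        by_ind.setdefault(e.individual_id, []).append(e)
    histories = []
    for ind, evs in sorted(by_ind.items()):
        det = np.zeros((n_occasions, grid.n_stations), dtype=np.int8)
        for e in evs:
            occ = e.occasion - 1
            if det[occ].sum() > 0:
                raise ValidationError(
                    f"individual {ind!r} detected twice in occasion {e.occasion}"
                    f" of session {year}/{primary}/{gid}"
                )
            det[occ, grid.station_index(e.col, e.row)] = 1
        cls = first_capture_class(evs)
        age, _, sexword = cls.partition("_") if cls != "unknown" else ("unknown", "", "")
        histories.append(SessionHistory(
            individual_id=ind, year=year, primary=primary, grid_id=gid,
            detections=det, sex=evs[0].sex,
            age_class=age,
        ))
    return histories


def sessions(events: Sequence[CaptureEvent]) -> dict[tuple[int, int, str], list[CaptureEvent]]:
    """Group events by (year, primary, grid_id)."""
    out: dict[tuple[int, int, str], list[CaptureEvent]] = {}
    for e in events:
        out.setdefault((e.year, e.primary, e.grid_id), []).append(e)
    return out


def build_annual_histories(
    events: Sequence[CaptureEvent],
    grids: Sequence[TrapGrid],
    n_primaries_by_year: dict[int, int] | None = None,
) -> list[AnnualHistory]:
    """Presence/absence across primary periods per individual-year.

    Sex-age class is fixed at the year's first capture; individuals with
    unknown class (missing mass) are dropped.
    """
    gmap = {g.grid_id: g for g in grids}
    by_iy: dict[tuple[str, int], list[CaptureEvent]] = {}
    for e in events:
        by_iy.setdefault((e.individual_id, e.year), []).append(e)
    if n_primaries_by_year is None:
        n_primaries_by_year = {}
        for e in events:
            n_primaries_by_year[e.year] = max(n_primaries_by_year.get(e.year, 0), e.primary)
    out = []
    for (ind, year), evs in sorted(by_iy.items()):
        cls = first_capture_class(evs)
        if cls == "unknown":
            continue
        T = n_primaries_by_year[year]
        pres = np.zeros(T, dtype=np.int8)
        for e in evs:
            pres[e.primary - 1] = 1
        grid = gmap[evs[0].grid_id]
        out.append(AnnualHistory(
            individual_id=ind, year=year, grid_id=grid.grid_id,
            presence=pres, sexage=cls, grid_level=grid.covariate_level(year),
        ))
    return out
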