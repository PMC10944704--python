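"""Reading, validating and structuring camera-trap deployment/detection tables.

Two delimited text tables are expected.  The deployment table has one row per
camera-trap deployment: a site identifier, an ISO-8601 start timestamp, either
an end timestamp or a duration in hours, and any number of numeric site
covariates (e.g. NDVI).  The detection table has one row per detection
sequence: site identifier, species label, and the sequence's starting
timestamp.  Raw per-photograph timestamps can be grouped into sequences with
:func:`collapse_to_sequences` (successive photos less than a fixed gap apart
belong to one sequence).

The likelihood needs two clocks per detection: elapsed hours since deployment
start (for the waiting times) and hour-of-day (for the diel Fourier basis).
Both are populated by :func:`build_dataset`.  Elapsed times are half-open in
[0, T): a detection exactly at deployment end is invalid.  Clock time is local
civil time as recorded; no timezone or DST logic is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "SPECIES",
    "Deployment",
    "DetectionHistory",
    "Dataset",
    "read_deployments",
    "read_detections",
    "write_deployments",
    "write_detections",
    "collapse_to_sequences",
    "build_dataset",
    "summarize_dataset",
]

logger = logging.getLogger(__name__)

#: modelled species labels: the prey and the predator
SPECIES = ("prey", "predator")


@dataclass
class Deployment:
    """One camera-trap sampling occasion."""

    site_id: str
    start: pd.Timestamp
    duration_hours: float
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.start = pd.Timestamp(self.start)
        if not (self.duration_hours > 0):
            raise ValidationError(
                f"deployment {self.site_id!r}: duration must be positive, "
                f"got {self.duration_hours}"
            )
        for k, v in self.covariates.items():
            if not np.isfinite(v):
                raise ValidationError(
                    f"deployment {self.site_id!r}: covariate {k!r} is not finite"
                )

    @property
    def start_clock(self) -> float:
        """Hour of day of deployment start, in [0, 24)."""
        s = self.start
        return (
            s.hour + s.minute / 60.0 + s.second / 3600.0 + s.microsecond / 3.6e9
        ) % 24.0


@dataclass
class DetectionHistory:
    """Ordered detection-sequence start times for one species at one site."""

    site_id: str
    species: str
    event_times_hours: np.ndarray
    event_clock_hours: np.ndarray

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValidationError(f"species must be one of {SPECIES}")
        self.event_times_hours = np.asarray(self.event_times_hours, dtype=float)
        self.event_clock_hours = np.asarray(self.event_clock_hours, dtype=float)
        t = self.event_times_hours
        if t.size and np.any(np.diff(t) <= 0):
            if np.any(np.diff(t) == 0):
                raise ValidationError(
                    f"duplicate timestamps for {self.species} at {self.site_id!r}; "
                    "group photographs with collapse_to_sequences first"
                )
            raise ValidationError("event times must be strictly increasing")
        if t.size and t[0] < 0:
            raise ValidationError("event times must be nonnegative")

    @property
    def n_events(self) -> int:
        return int(self.event_times_hours.size)


@dataclass
class Dataset:
    """Validated deployments plus per-(site, species) detection histories."""

    deployments: list[Deployment]
    histories: dict[tuple[str, str], DetectionHistory]

    def __post_init__(self):
        ids = [d.site_id for d in self.deployments]
        if len(set(ids)) != len(ids):
            raise ValidationError("site_id must be unique across deployments")
        self._by_id = {d.site_id: d for d in self.deployments}
        for (sid, sp), hist in self.histories.items():
            if sid not in self._by_id:
                raise ValidationError(f"history references unknown site {sid!r}")
            if sp not in SPECIES:
                raise ValidationError(f"history species {sp!r} not modelled")
            T = self._by_id[sid].duration_hours
            t = hist.event_times_hours
            if t.size and t[-1] >= T:
                raise ValidationError(
                    f"detection at or beyond deployment end for site {sid!r}"
                )

    def deployment(self, site_id: str) -> Deployment:
        return self._by_id[site_id]

    def history(self, site_id: str, species: str) -> DetectionHistory | None:
        return self.histories.get((site_id, species))

    def n_events(self, species: str) -> int:
        return sum(
            h.n_events for (sid, sp), h in self.histories.items() if sp == species
        )

    def naive_occupancy(self, species: str) -> float:
        det = {sid for (sid, sp), h in self.histories.items() if sp == species and h.n_events}
        return len(det) / len(self.deployments)

    def camera_days(self) -> float:
        return sum(d.duration_hours for d in self.deployments) / 24.0


_DEPLOY_COLS = {"site_id": "site_id", "start": "start", "end": "end",
                "duration_hours": "duration_hours"}


def read_deployments(
    path,
    dialect: Mapping[str, str] | None = None,
    sep: str = ",",
    covariate_columns: Sequence[str] | None = None,
) -> list[Deployment]:
    """Parse a deployment table.

    ``dialect`` maps standard names (site_id, start, end, duration_hours, and
    covariate names) to the file's column names.  Duration is computed from
    ``end - start`` when a duration column is absent.
    """
    cols = dict(_DEPLOY_COLS)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep=sep)
    for req in ("site_id", "start"):
        if cols[req] not in df.columns:
            raise ConfigurationError(f"deployment table lacks column {cols[req]!r}")
    has_dur = cols["duration_hours"] in df.columns
    has_end = cols["end"] in df.columns
    if not (has_dur or has_end):
        raise ConfigurationError(
            "deployment table needs a duration_hours or an end column"
        )
    start = pd.to_datetime(df[cols["start"]], format="ISO8601")
    if has_dur:
        duration = df[cols["duration_hours"]].astype(float)
    else:
        duration = (pd.to_datetime(df[cols["end"]], format="ISO8601")
                    - start).dt.total_seconds() / 3600.0
    known = {cols[k] for k in cols}
    if covariate_columns is None:
        covariate_columns = [
            c for c in df.columns
            if c not in known and pd.api.types.is_numeric_dtype(df[c])
        ]
    out = []
    for i, row in df.iterrows():
        dur = float(duration.iloc[i])
        if not dur > 0:
            raise ValidationError(
                f"row {i}: non-positive deployment duration ({dur} h) "
                f"for site {row[cols['site_id']]!r}"
            )
        out.append(
            Deployment(
                site_id=str(row[cols["site_id"]]),
                start=start.iloc[i],
                duration_hours=dur,
                covariates={c: float(row[c]) for c in covariate_columns},
            )
        )
    return out


def read_detections(
    path,
    dialect: Mapping[str, str] | None = None,
    sep: str = ",",
    species_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Parse a detection table into (site_id, species, timestamp) rows.

    ``species_map`` translates the file's species labels to the modelled
    labels ``"prey"``/``"predator"``; unmapped labels are dropped with a log
    message (other species in the photos are not modelled).
    """
    cols = {"site_id": "site_id", "species": "species", "timestamp": "timestamp"}
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep=sep)
    for req in cols.values():
        if req not in df.columns:
            raise ConfigurationError(f"detection table lacks column {req!r}")
    out = pd.DataFrame(
        {
            "site_id": df[cols["site_id"]].astype(str),
            "species": df[cols["species"]].astype(str),
            "timestamp": pd.to_datetime(df[cols["timestamp"]], format="ISO8601"),
        }
    )
    if species_map:
        out["species"] = out["species"].map(lambda s: species_map.get(s, s))
    keep = out["species"].isin(SPECIES)
    if (~keep).any():
        logger.info("dropping %d detections of unmodelled species", int((~keep).sum()))
        out = out[keep].reset_index(drop=True)
    return out


def write_deployments(deployments: Iterable[Deployment], path, sep: str = ",") -> None:
    rows = []
    for d in deployments:
        row = {
            "site_id": d.site_id,
            "start": d.start.isoformat(),
            "duration_hours": repr(d.duration_hours),
        }
        row.update({k: repr(v) for k, v in d.covariates.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_detections(detections: pd.DataFrame, path, sep: str = ",") -> None:
    out = detections.copy()
    out["timestamp"] = out["timestamp"].map(lambda t: pd.Timestamp(t).isoformat())
    out.to_csv(path, sep=sep, index=False)


def collapse_to_sequences(raw_times, gap_seconds: float = 60.0):
    """Group raw photograph timestamps into detection sequences.

    A sequence is a maximal run of photographs whose successive gaps are all
    strictly below ``gap_seconds``; the sequence's start time represents the
    detection event.  A run's total span may exceed ``gap_seconds``.  Accepts
    datetime-like or numeric (seconds) input; returns the same kind.
    """
    if gap_seconds <= 0:
        raise ValidationError("gap_seconds must be positive")
    arr = np.asarray(raw_times)
    if arr.size == 0:
        return arr
    if np.issubdtype(arr.dtype, np.datetime64) or arr.dtype == object:
        ts = pd.to_datetime(pd.Series(list(raw_times)))
        secs = ts.astype("int64").to_numpy() / 1e9
        if np.any(np.diff(secs) < 0):
            raise ValidationError("timestamps must be sorted ascending")
        starts = np.concatenate([[True], np.diff(secs) >= gap_seconds])
        return ts.to_numpy()[starts]
    secs = arr.astype(float)
    if np.any(np.diff(secs) < 0):
        raise ValidationError("timestamps must be sorted ascending")
    starts = np.concatenate([[True], np.diff(secs) >= gap_seconds])
    return secs[starts]


def build_dataset(
    deployments: Sequence[Deployment],
    detections: pd.DataFrame,
    tolerance_hours: float = 0.0,
) -> Dataset:
    """Assemble a validated :class:`Dataset` from parsed tables.

    Detections are converted to elapsed hours since their deployment's start
    and to hour-of-day.  Detections outside [0, T + tolerance) are dropped and
    counted in a log message; those within tolerance are clamped into [0, T).
    """
    by_id = {d.site_id: d for d in deployments}
    histories: dict[tuple[str, str], DetectionHistory] = {}
    n_dropped = 0
    if len(detections):
        for (sid, sp), grp in detections.groupby(["site_id", "species"], sort=True):
            if sid not in by_id:
                raise ValidationError(f"detection for unknown site {sid!r}")
            dep = by_id[sid]
            ts = pd.to_datetime(grp["timestamp"]).sort_values()
            elapsed = (ts - dep.start).dt.total_seconds().to_numpy() / 3600.0
            T = dep.duration_hours
            ok = (elapsed >= -tolerance_hours) & (elapsed < T + tolerance_hours)
            n_dropped += int((~ok).sum())
            elapsed = elapsed[ok]
            if elapsed.size == 0:
                continue
            elapsed = np.clip(elapsed, 0.0, np.nextafter(T, 0.0))
            clock = (dep.start_clock + elapsed) % 24.0
            histories[(sid, sp)] = DetectionHistory(
                site_id=sid, species=sp,
                event_times_hours=elapsed, event_clock_hours=clock,
            )
    if n_dropped:
        logger.warning("dropped %d detections outside deployment windows", n_dropped)
    return Dataset(deployments=list(deployments), histories=histories)


def summarize_dataset(dataset: Dataset) -> pd.DataFrame:
    """Per-site detection counts plus dataset-level occupancy/effort summary."""
    rows = []
    for d in dataset.deployments:
        rows.append(
            {
                "site_id": d.site_id,
                "duration_days": d.duration_hours / 24.0,
                "n_prey": (dataset.history(d.site_id, "prey") or
                           DetectionHistory(d.site_id, "prey", [], [])).n_events,
                "n_predator": (dataset.history(d.site_id, "predator") or
                               DetectionHistory(d.site_id, "predator", [], [])).n_events,
            }
        )
    return pd.DataFrame(rows)
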