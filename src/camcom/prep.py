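"""Camera-trap data preparation.

Reads image records, deployments, site covariates and species traits from
plain CSV; collapses bursts of images into independent passage events;
computes the relative abundance index (RAI, events per 100 camera-days)
and naive occupancy; and builds per-species detection histories at a
fixed occasion resolution (default 5 days) for occupancy modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_WINDOW_MINUTES = 60.0
DEFAULT_OCCASION_DAYS = 5


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_records(path) -> pd.DataFrame:
    """Read image records (site_id, species, timestamp).

    Raises :class:`DataError` naming the file and 1-based data line of
    the first malformed timestamp.
    """
    df = pd.read_csv(path, dtype={"site_id": str, "species": str})
    _require(df, ["site_id", "species", "timestamp"], path)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(ts.isna() & df["timestamp"].notna())
    if len(bad):
        raise DataError(
            f"{path}: malformed timestamp {df['timestamp'].iloc[bad[0]]!r} "
            f"on data line {bad[0] + 2}")
    df["timestamp"] = ts
    return df


def read_deployments(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str})
    _require(df, ["site_id", "start", "end", "functioning"], path)
    df["start"] = pd.to_datetime(df["start"], format="ISO8601")
    df["end"] = pd.to_datetime(df["end"], format="ISO8601")
    df["functioning"] = df["functioning"].astype(bool)
    if (df["end"] < df["start"]).any():
        raise DataError(f"{path}: deployment with end before start")
    return df


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str})
    _require(df, ["site_id"], path)
    return df


def read_traits(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"species": str})
    _require(df, ["species", "mass_kg", "guild"], path)
    if (df["mass_kg"] <= 0).any():
        raise DataError(f"{path}: non-positive body mass")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as CSV with ISO-8601 timestamps and no index."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# Events, RAI, naive occupancy
# ---------------------------------------------------------------------------

def collapse_events(records: pd.DataFrame,
                    window_minutes: float = DEFAULT_WINDOW_MINUTES) -> pd.DataFrame:
    """Collapse image bursts into independent passage events.

    Within each site x species stream (duplicate rows removed, sorted by
    time) a new event starts whenever the gap to the previous image
    strictly exceeds ``window_minutes``; the result is independent of
    input row order.  Returns (site_id, species, event_start, n_images).
    """
    if window_minutes < 0:
        raise ValueError("window_minutes must be non-negative")
    cols = ["site_id", "species", "event_start", "n_images"]
    if records.empty:
        return pd.DataFrame(columns=cols)
    df = (records.drop_duplicates(["site_id", "species", "timestamp"])
          .sort_values(["site_id", "species", "timestamp"], kind="mergesort"))
    gap = df.groupby(["site_id", "species"], sort=False)["timestamp"].diff()
    new_event = gap.isna() | (gap > pd.Timedelta(minutes=window_minutes))
    df = df.assign(_event=new_event.cumsum())
    ev = (df.groupby("_event", sort=False)
          .agg(site_id=("site_id", "first"), species=("species", "first"),
               event_start=("timestamp", "first"), n_images=("timestamp", "size"))
          .reset_index(drop=True))
    return ev[cols]


def compute_rai(n_events: int, effort_camera_days: float) -> float:
    """Relative abundance index: events per 100 camera-days, 2 decimals."""
    if effort_camera_days <= 0:
        raise ValueError("sampling effort must be positive")
    if n_events < 0:
        raise ValueError("event count must be non-negative")
    return round(100.0 * n_events / effort_camera_days, 2)


def naive_occupancy(n_occupied_sites: int, n_sites_sampled: int) -> float:
    """Fraction of sampled sites with at least one detection, 3 decimals."""
    if n_sites_sampled <= 0:
        raise ValueError("number of sampled sites must be positive")
    if not 0 <= n_occupied_sites <= n_sites_sampled:
        raise ValueError("occupied sites must be between 0 and sites sampled")
    return round(n_occupied_sites / n_sites_sampled, 3)


def deployment_days(deployments: pd.DataFrame) -> pd.Series:
    """Active camera-days per site (0 for non-functioning cameras)."""
    days = (deployments["end"] - deployments["start"]).dt.days
    days = days.where(deployments["functioning"], 0)
    return pd.Series(days.to_numpy(), index=deployments["site_id"].to_numpy())


def total_effort(deployments: pd.DataFrame) -> int:
    """Total sampling effort in camera-days over functioning cameras."""
    return int(deployment_days(deployments).sum())


# ---------------------------------------------------------------------------
# Detection matrices
# ---------------------------------------------------------------------------

@dataclass
class DetectionMatrix:
    """Sites x occasions detection history for one species.

    ``values`` holds 1.0 (detected), 0.0 (surveyed, not detected) or NaN
    (camera inactive for the whole occasion).  Occasions are indexed per
    site from its own deployment start unless built calendar-aligned.
    """

    species: str
    values: np.ndarray           # float array, sites x occasions
    sites: list[str]
    occasion_days: int = DEFAULT_OCCASION_DAYS
    occasion_starts: list[pd.Timestamp] | None = None

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.values.shape[1]

    def detections_per_site(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            return np.nansum(self.values, axis=1)

    def surveys_per_site(self) -> np.ndarray:
        return np.sum(~np.isnan(self.values), axis=1)

    def naive_occupancy(self) -> float:
        surveyed = self.surveys_per_site() > 0
        return naive_occupancy(int((self.detections_per_site()[surveyed] > 0).sum()),
                               int(surveyed.sum()))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"occ_{j + 1}" for j in range(self.n_occasions)]
        return pd.DataFrame(self.values, index=pd.Index(self.sites, name="site_id"),
                            columns=cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, species: str,
                   occasion_days: int = DEFAULT_OCCASION_DAYS) -> "DetectionMatrix":
        return cls(species=species, values=df.to_numpy(dtype=float),
                   sites=[str(s) for s in df.index], occasion_days=occasion_days)


def build_detection_matrix(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    species: str,
    occasion_days: int = DEFAULT_OCCASION_DAYS,
    align: str = "deployment",
    keep_partial: bool = True,
) -> DetectionMatrix:
    """Bin a species' events into a sites x occasions detection history.

    With ``align='deployment'`` occasion 1 starts at each site's own
    deployment start, so the staggered arrays line up as within-site
    replicates; ``align='calendar'`` bins all sites on a common calendar
    origin instead.  An occasion is missing (NaN) iff the camera was
    inactive for every day of it; a trailing partial occasion is scored
    from its active days, or dropped when ``keep_partial`` is false.
    """
    if occasion_days < 1:
        raise ValueError("occasion_days must be >= 1")
    if align not in ("deployment", "calendar"):
        raise ValueError(f"unknown alignment {align!r}")
    sp_events = events[events["species"] == species]
    unknown = set(sp_events["site_id"]) - set(deployments["site_id"])
    if unknown:
        raise DataError(f"events at sites not in deployments: {sorted(unknown)}")

    deps = deployments.reset_index(drop=True)
    days = deployment_days(deployments).to_numpy()
    origin = deps["start"].min()

    if align == "deployment":
        offsets = np.zeros(len(deps), dtype=int)
    else:
        offsets = (deps["start"] - origin).dt.days.to_numpy()
    n_occ = 0
    for n_days, off in zip(days, offsets):
        if n_days > 0:
            n_occ = max(n_occ, int(np.ceil((off + n_days) / occasion_days)))
    n_occ = max(n_occ, 1)

    values = np.full((len(deps), n_occ), np.nan)
    for i, (n_days, off) in enumerate(zip(days, offsets)):
        for j in range(n_occ):
            lo, hi = j * occasion_days, (j + 1) * occasion_days
            active = max(0, min(hi, off + int(n_days)) - max(lo, off))
            if active == occasion_days or (active > 0 and keep_partial):
                values[i, j] = 0.0

    site_row = {s: i for i, s in enumerate(deps["site_id"])}
    for _, ev in sp_events.iterrows():
        i = site_row[ev["site_id"]]
        start = deps.loc[i, "start"]
        day = (ev["event_start"].normalize() - start.normalize()).days
        if not deps.loc[i, "functioning"] or not 0 <= day < days[i]:
            raise DataError(
                f"event for {species!r} at {ev['site_id']} on "
                f"{ev['event_start']} falls outside the deployment window")
        j = (day + (0 if align == "deployment" else int(offsets[i]))) // occasion_days
        if not np.isnan(values[i, j]):
            values[i, j] = 1.0

    starts = [origin + pd.Timedelta(days=j * occasion_days) for j in range(n_occ)] \
        if align == "calendar" else None
    return DetectionMatrix(species=species, values=values,
                           sites=list(deps["site_id"]),
                           occasion_days=occasion_days, occasion_starts=starts)


def build_all_matrices(events, deployments, species_list=None, **kwargs):
    """Detection matrices for every (or the given) species, as a dict."""
    if species_list is None:
        species_list = sorted(events["species"].unique())
    return {sp: build_detection_matrix(events, deployments, sp, **kwargs)
            for sp in species_list}


# ---------------------------------------------------------------------------
# Covariate standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardization:
    """Stored means/SDs so prediction grids reuse the fit-time z-scoring."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col, m in self.means.items():
            if col in out.columns:
                out[col] = (out[col] - m) / self.sds[col]
        return out


def standardize_covariates(
    covs: pd.DataFrame,
    numeric_fields: list[str] | None = None,
) -> tuple[pd.DataFrame, Standardization]:
    """Z-score numeric covariates (sample SD, n-1 denominator).

    Returns the transformed table and the stored means/SDs.  A constant
    column cannot be standardized and is rejected as non-identifiable.
    """
    if numeric_fields is None:
        numeric_fields = [c for c in covs.columns
                          if c not in ("site_id", "habitat", "x", "y")
                          and pd.api.types.is_numeric_dtype(covs[c])]
    out = covs.copy()
    std = Standardization()
    for col in numeric_fields:
        x = covs[col].to_numpy(dtype=float)
        m, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise DataError(f"covariate {col!r} is constant: non-identifiable")
        out[col] = (x - m) / sd
        std.means[col], std.sds[col] = m, sd
    return out, std


def collapse_habitat(habitat: pd.Series) -> pd.Series:
    """Collapse the 3-class habitat to montane vs lowland for modelling."""
    return pd.Series(np.where(habitat == "montane", "montane", "lowland"),
                     index=habitat.index, name="habitat2")


# ---------------------------------------------------------------------------
# Community summary (raw abundance indices)
# ---------------------------------------------------------------------------

def summarize_community(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    n_images: int | None = None,
) -> pd.DataFrame:
    """Per-species raw abundance indices: events, RAI, naive occupancy.

    One row per detected species with its traits merged in (a species
    absent from the trait table triggers a warning and empty traits).
    Total sampling effort and image count are stored in ``df.attrs``.
    """
    if events.empty:
        raise DataError("no events: nothing to summarize")
    effort = total_effort(deployments)
    sampled = int((deployment_days(deployments) > 0).sum())
    g = events.groupby("species")
    summary = pd.DataFrame({
        "n_events": g.size(),
        "n_sites": g["site_id"].nunique(),
    }).reset_index()
    summary["RAI"] = [compute_rai(n, effort) for n in summary["n_events"]]
    summary["naive_occupancy"] = [naive_occupancy(k, sampled)
                                  for k in summary["n_sites"]]
    if traits is not None:
        missing = set(summary["species"]) - set(traits["species"])
        if missing:
            warnings.warn(f"species missing from traits: {sorted(missing)}")
        summary = summary.merge(traits, on="species", how="left")
        sort_cols = (["group", "species"] if "group" in summary.columns
                     else ["species"])
        summary = summary.sort_values(sort_cols, kind="mergesort")
    summary = summary.reset_index(drop=True)
    summary.attrs["effort_camera_days"] = effort
    summary.attrs["n_sites_sampled"] = sampled
    summary.attrs["n_images"] = int(n_images if n_images is not None
                                    else events["n_images"].sum())
    return summary
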