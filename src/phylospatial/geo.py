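"""Geographic tables and great-circle distance matrices.

Every spatial covariance and weights matrix in this package starts from a
:class:`GeoTable` (one row per culture/language: id, longitude, latitude,
outcome, covariates) and the pairwise great-circle :class:`DistanceMatrix`
derived from it.  Distances are haversine distances on a sphere of radius
``EARTH_RADIUS_KM`` (the IUGG mean Earth radius); ellipsoidal corrections
are deliberately out of scope at the ~10 000 km scales relevant here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoTable",
    "DistanceMatrix",
    "great_circle_distance",
    "distance_matrix",
    "read_geotable",
]

#: IUGG mean Earth radius in kilometres.
EARTH_RADIUS_KM = 6371.0088


class ValidationError(ValueError):
    """Raised when an input table or coordinate fails validation."""


def _check_coords(lon, lat) -> tuple[np.ndarray, np.ndarray]:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(~np.isfinite(lon)) or np.any(~np.isfinite(lat)):
        raise ValidationError("non-finite coordinate (lon/lat must be decimal degrees)")
    if np.any(np.abs(lat) > 90.0):
        bad = np.atleast_1d(lat)[np.abs(np.atleast_1d(lat)) > 90.0][0]
        raise ValidationError(f"lat out of range [-90, 90]: {bad}")
    # longitude is circular: any finite value is accepted and wrapped
    return lon, lat


def normalize_longitude(lon):
    """Map longitudes to [-180, 180)."""
    lon = np.asarray(lon, dtype=float)
    return (lon + 180.0) % 360.0 - 180.0


def great_circle_distance(lon1, lat1, lon2, lat2, radius: float = EARTH_RADIUS_KM):
    """Haversine great-circle distance in kilometres.

    Accepts scalars or broadcastable arrays of decimal-degree coordinates.
    Symmetric, zero iff the points coincide (after longitude wrapping), and
    bounded by half the circumference, pi * radius.
    """
    lon1, lat1 = _check_coords(lon1, lat1)
    lon2, lat2 = _check_coords(lon2, lat2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(normalize_longitude(lon2) - normalize_longitude(lon1))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # clip guards tiny negative / >1 rounding at antipodes
    return 2.0 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class GeoTable:
    """One row per observational unit: id, position, outcome, covariates.

    Parameters
    ----------
    data:
        DataFrame holding at least the id, lon and lat columns.  Longitudes
        are normalized to [-180, 180) on construction.
    id_col, lon_col, lat_col, outcome_col:
        Column names; ``outcome_col`` may be None for purely spatial tables.
    covariate_cols:
        Names of real-valued covariate columns (e.g. a humidity score).
    n_dropped:
        Rows removed upstream because of missing coordinates (listwise
        deletion; see :func:`read_geotable`).
    """

    data: pd.DataFrame
    id_col: str = "id"
    lon_col: str = "lon"
    lat_col: str = "lat"
    outcome_col: str | None = None
    covariate_cols: list[str] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for col in [self.id_col, self.lon_col, self.lat_col, self.outcome_col, *self.covariate_cols]:
            if col is not None and col not in self.data.columns:
                raise ValidationError(f"missing required column '{col}'")
        self.data = self.data.reset_index(drop=True).copy()
        ids = self.data[self.id_col].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate ids: {dupes[:5]}")
        if self.data[[self.lon_col, self.lat_col]].isna().any().any():
            raise ValidationError("missing lon/lat in retained rows")
        lon, lat = _check_coords(self.data[self.lon_col], self.data[self.lat_col])
        self.data[self.lon_col] = normalize_longitude(lon)
        self.data[self.lat_col] = lat

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> list[str]:
        return self.data[self.id_col].astype(str).tolist()

    @property
    def lon(self) -> np.ndarray:
        return self.data[self.lon_col].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.data[self.lat_col].to_numpy(dtype=float)

    @property
    def outcome(self) -> np.ndarray:
        if self.outcome_col is None:
            raise ValidationError("GeoTable has no outcome column configured")
        return self.data[self.outcome_col].to_numpy(dtype=float)

    def covariate(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def require_binary_outcome(self) -> np.ndarray:
        """Outcome as a 0/1 vector containing both classes."""
        y = self.outcome
        values = set(np.unique(y))
        if not values <= {0.0, 1.0}:
            raise ValidationError(f"outcome is not binary 0/1 (values {sorted(values)[:5]})")
        if len(values) < 2:
            raise ValidationError("binary outcome contains a single class")
        return y

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise great-circle distances (km) with an id order."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(self.values < 0.0):
            raise ValidationError("negative distance")

    @property
    def n(self) -> int:
        return len(self.ids)


def distance_matrix(table: GeoTable, radius: float = EARTH_RADIUS_KM) -> DistanceMatrix:
    """Pairwise haversine distance matrix for all rows of ``table``."""
    if table.n < 2:
        raise ValidationError("need at least 2 rows for a distance matrix")
    lon, lat = table.lon, table.lat
    d = great_circle_distance(lon[:, None], lat[:, None], lon[None, :], lat[None, :], radius=radius)
    d = 0.5 * (d + d.T)  # enforce exact symmetry against rounding
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, table.ids)


def read_geotable(
    path,
    id_col: str = "id",
    lon_col: str = "lon",
    lat_col: str = "lat",
    outcome_col: str | None = None,
    covariate_cols: list[str] | None = None,
    sep: str | None = None,
) -> GeoTable:
    """Read a CSV/TSV table into a :class:`GeoTable`.

    The separator is sniffed from the extension unless given (``.tsv`` ->
    tab).  Rows with missing lon/lat are dropped (listwise deletion) and the
    count recorded in ``n_dropped``.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in (id_col, lon_col, lat_col, outcome_col, *(covariate_cols or []))
               if c is not None and c not in df.columns]
    if missing:
        cols = ", ".join(f"'{c}'" for c in missing)
        raise ValidationError(f"missing required column(s) {cols} in {path}")
    complete = df[[lon_col, lat_col]].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    return GeoTable(
        df[complete],
        id_col=id_col,
        lon_col=lon_col,
        lat_col=lat_col,
        outcome_col=outcome_col,
        covariate_cols=list(covariate_cols or []),
        n_dropped=n_dropped,
    )
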