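"""Geometry of avian visual-field perimetry.

A visual-field perimeter locates, at 10-degree steps of elevation, the azimuth
at which each eye's retinal field ends.  This module turns those raw margin
readings into corrected per-elevation binocular widths, summary statistics
(maximum binocular overlap, its elevation, vertical extent, offset from the
eye--bill-tip projection) and closed planar outlines suitable for outline
morphometrics.

Coordinate frame
----------------
Azimuth is signed degrees from the median sagittal plane, positive toward the
bird's right.  Elevation is degrees from the horizontal through the eyes,
positive upward.  All public interfaces use degrees; trigonometry is done in
radians internally.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FieldProfile",
    "FieldSummary",
    "correct_to_infinity",
    "invert_infinity_correction",
    "binocular_width",
    "interpolate_blocked",
    "summarize_field",
    "outline_from_profile",
    "estimate_lower_bounds",
    "orthographic_project",
    "field_components",
    "profiles_from_records",
    "summaries_from_records",
    "species_mean_summaries",
    "read_perimeter_csv",
    "write_outlines",
    "read_outlines",
]

#: default elevation spacing of the measurement grid, degrees
GRID_STEP = 10.0

PERIMETER_COLUMNS = [
    "species",
    "individual",
    "eye",
    "eye_state",
    "elevation_deg",
    "margin_azimuth_deg",
    "apparatus_radius_m",
    "eye_separation_m",
]


def _require_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return arr


def correct_to_infinity(margin_azimuth, eye, apparatus_radius, eye_separation):
    """Correct a margin azimuth for a viewing point at infinity.

    The perimeter reports the angular position of the observer on an arc of
    radius ``apparatus_radius`` centred on the head, but the field margin
    belongs to the eye, which sits half the inter-eye separation off the
    median plane.  With the head centre at the origin, the forward axis y and
    the right axis x, the eye lies at ``(+/- s/2, 0)`` and the observer at
    ``(r sin(theta), r cos(theta))``; the corrected azimuth is the direction
    of the observer as seen from the eye::

        theta' = atan2(r sin(theta) -/+ s/2, r cos(theta))

    (upper sign for the right eye).  The correction vanishes as ``r -> inf``
    or ``s -> 0``.

    Parameters
    ----------
    margin_azimuth : float or array-like
        Measured azimuth, signed degrees.
    eye : {"left", "right"}
    apparatus_radius : float
        Perimeter arc radius (any length unit, same as ``eye_separation``).
    eye_separation : float
        Horizontal separation between the centres of the two eyes.

    Returns
    -------
    float or ndarray
        Corrected azimuth in degrees.
    """
    theta = _require_finite("margin_azimuth", margin_azimuth)
    r = float(_require_finite("apparatus_radius", apparatus_radius))
    s = float(_require_finite("eye_separation", eye_separation))
    if r <= 0:
        raise ValueError(f"apparatus_radius must be > 0, got {r}")
    if s < 0:
        raise ValueError(f"eye_separation must be >= 0, got {s}")
    if eye not in ("left", "right"):
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")
    offset = s / 2.0 if eye == "right" else -s / 2.0
    th = np.radians(theta)
    out = np.degrees(np.arctan2(r * np.sin(th) - offset, r * np.cos(th)))
    return float(out) if np.isscalar(margin_azimuth) else out


def invert_infinity_correction(corrected_azimuth, eye, apparatus_radius, eye_separation):
    """Inverse of :func:`correct_to_infinity`.

    Given the azimuth of a field margin *from the eye*, return the apparatus
    arc position at which the perimeter would have recorded it.  Used by the
    synthetic-data generator to emit raw measurements whose corrected values
    are known exactly.
    """
    thetap = _require_finite("corrected_azimuth", corrected_azimuth)
    r = float(apparatus_radius)
    s = float(eye_separation)
    if r <= 0:
        raise ValueError("apparatus_radius must be > 0")
    if s / 2.0 >= r:
        raise ValueError("eye_separation/2 must be smaller than apparatus_radius")
    ex = s / 2.0 if eye == "right" else -s / 2.0
    th = np.radians(thetap)
    dx, dy = np.sin(th), np.cos(th)
    # intersect the ray eye + u*(dx,dy) with the circle |p| = r
    b = ex * dx
    u = -b + np.sqrt(b * b - ex * ex + r * r)
    px, py = ex + u * dx, u * dy
    out = np.degrees(np.arctan2(px, py))
    return float(out) if np.isscalar(corrected_azimuth) else out


def binocular_width(left_margin, right_margin):
    """Binocular overlap width from the two medial (frontal) field margins.

    Overlap exists when the left eye's medial margin extends to the right of
    the right eye's medial margin; a negative gap is clamped to zero (the gap
    remains recoverable from the stored margins).
    """
    l = _require_finite("left_margin", left_margin)
    r = _require_finite("right_margin", right_margin)
    out = np.maximum(0.0, l - r)
    return float(out) if np.isscalar(left_margin) and np.isscalar(right_margin) else out


@dataclass
class FieldSummary:
    """Summary statistics of one binocular-field profile (degrees)."""

    species: str
    max_binocular_overlap: float
    elevation_of_max: float
    vertical_extent: float
    bill_tip_elevation: float
    max_overlap_offset: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "max_overlap_deg": self.max_binocular_overlap,
            "elevation_of_max_deg": self.elevation_of_max,
            "vertical_extent_deg": self.vertical_extent,
            "bill_tip_elevation_deg": self.bill_tip_elevation,
            "offset_deg": self.max_overlap_offset,
            "degenerate": self.degenerate,
        }


@dataclass
class FieldProfile:
    """Corrected per-elevation margins and binocular widths for one bird.

    ``binocular_width`` may hold NaN at elevations where the bill holder
    blocked the view; :func:`interpolate_blocked` fills them.  Margins are
    optional (width-only profiles are accepted everywhere except where the
    margins themselves are needed).
    """

    species: str
    elevation: np.ndarray
    binocular_width: np.ndarray
    left_margin: np.ndarray | None = None
    right_margin: np.ndarray | None = None
    interpolated: np.ndarray = field(default=None)
    estimated_lower_bound: np.ndarray = field(default=None)

    def __post_init__(self):
        self.elevation = np.asarray(self.elevation, dtype=float)
        self.binocular_width = np.asarray(self.binocular_width, dtype=float)
        n = self.elevation.size
        if self.binocular_width.size != n:
            raise ValueError("elevation and binocular_width must have equal length")
        if n and np.any(np.diff(self.elevation) <= 0):
            raise ValueError("elevations must be strictly increasing")
        w = self.binocular_width
        if np.any(w[np.isfinite(w)] < 0):
            raise ValueError("binocular widths must be non-negative")
        for attr in ("left_margin", "right_margin"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != n:
                    raise ValueError(f"{attr} length mismatch")
                setattr(self, attr, v)
        if self.interpolated is None:
            self.interpolated = np.zeros(n, dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if self.estimated_lower_bound is None:
            self.estimated_lower_bound = np.zeros(n, dtype=bool)
        else:
            self.estimated_lower_bound = np.asarray(self.estimated_lower_bound, dtype=bool)

    # -- convenience -------------------------------------------------------
    def blocked_elevations(self) -> np.ndarray:
        return self.elevation[~np.isfinite(self.binocular_width)]

    def signed_overlap(self) -> np.ndarray:
        """Signed overlap: ``left - right`` where margins exist, else width."""
        s = self.binocular_width.copy()
        if self.left_margin is not None and self.right_margin is not None:
            m = np.isfinite(self.left_margin) & np.isfinite(self.right_margin)
            s[m] = self.left_margin[m] - self.right_margin[m]
        return s

    def copy(self) -> "FieldProfile":
        return FieldProfile(
            self.species,
            self.elevation.copy(),
            self.binocular_width.copy(),
            None if self.left_margin is None else self.left_margin.copy(),
            None if self.right_margin is None else self.right_margin.copy(),
            self.interpolated.copy(),
            self.estimated_lower_bound.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        d = {
            "species": self.species,
            "elevation_deg": self.elevation,
            "binocular_width_deg": self.binocular_width,
            "interpolated": self.interpolated,
            "estimated_lower_bound": self.estimated_lower_bound,
        }
        if self.left_margin is not None:
            d["left_margin_deg"] = self.left_margin
        if self.right_margin is not None:
            d["right_margin_deg"] = self.right_margin
        return pd.DataFrame(d)


def interpolate_blocked(profile: FieldProfile, blocked_elevations=None) -> FieldProfile:
    """Fill widths at elevations blocked by the bill holder.

    The width at a blocked elevation is the arithmetic mean of the widths at
    the nearest measured elevations above and below.  Measured rows are never
    touched.  A blocked elevation at the grid boundary (no measured neighbour
    on one side) raises, because only lower-bound estimation can extend a
    profile (:func:`estimate_lower_bounds`).
    """
    out = profile.copy()
    if blocked_elevations is None:
        blocked_elevations = out.blocked_elevations()
    blocked = np.atleast_1d(np.asarray(blocked_elevations, dtype=float))
    if blocked.size == 0:
        return out
    measured = np.isfinite(out.binocular_width)
    for e in blocked:
        idx = np.flatnonzero(np.isclose(out.elevation, e))
        if idx.size == 0:
            raise ValueError(f"blocked elevation {e} not present in profile")
        i = int(idx[0])
        below = np.flatnonzero(measured[:i])
        above = np.flatnonzero(measured[i + 1 :])
        if below.size == 0 or above.size == 0:
            raise ValueError(
                f"blocked elevation {e} has no measured neighbour on one side; "
                "use estimate_lower_bounds for truncated profiles"
            )
        j_lo = int(below[-1])
        j_hi = int(above[0]) + i + 1
        out.binocular_width[i] = 0.5 * (
            out.binocular_width[j_lo] + out.binocular_width[j_hi]
        )
        out.interpolated[i] = True
    return out


def _zero_crossing(e0, s0, e1, s1):
    """Elevation where the signed overlap crosses zero between two rows."""
    if s0 == s1:  # pragma: no cover - guarded by callers
        return e0
    return e0 + (0.0 - s0) * (e1 - e0) / (s1 - s0)


def summarize_field(profile: FieldProfile, bill_tip_elevation: float = 0.0) -> FieldSummary:
    """Compute the three headline visual-field parameters.

    * maximum binocular overlap: largest width over elevations;
    * its elevation (ties broken toward the lowest elevation, consistent with
      the downward bill-tip reference);
    * vertical extent: angular distance between the lower and upper zero
      crossings of the overlap, interpolated linearly between grid rows using
      the signed overlap (margins) where available; a profile that ends with
      positive width uses its edge elevation as the field limit;
    * offset: magnitude of elevation-of-max minus the bill-tip projection.
    """
    w = profile.binocular_width
    if not np.all(np.isfinite(w)):
        raise ValueError("profile contains blocked rows; interpolate first")
    e = profile.elevation
    bt = float(bill_tip_elevation)
    if w.size == 0 or np.all(w == 0):
        return FieldSummary(profile.species, 0.0, 0.0, 0.0, bt, 0.0, degenerate=True)
    imax = int(np.argmax(w))  # first occurrence == lowest elevation
    s = profile.signed_overlap()
    i0 = imax
    while i0 > 0 and w[i0 - 1] > 0:
        i0 -= 1
    i1 = imax
    while i1 < w.size - 1 and w[i1 + 1] > 0:
        i1 += 1
    lo = e[0] if i0 == 0 else _zero_crossing(e[i0 - 1], s[i0 - 1], e[i0], s[i0])
    hi = e[-1] if i1 == w.size - 1 else _zero_crossing(e[i1], s[i1], e[i1 + 1], s[i1 + 1])
    return FieldSummary(
        species=profile.species,
        max_binocular_overlap=float(w[imax]),
        elevation_of_max=float(e[imax]),
        vertical_extent=float(hi - lo),
        bill_tip_elevation=bt,
        max_overlap_offset=abs(float(e[imax]) - bt),
    )


def outline_from_profile(profile: FieldProfile) -> np.ndarray:
    """Closed planar outline of the binocular field.

    The field is symmetric about the median plane in this representation:
    x = +/- width/2, y = elevation.  Traversal runs up the right limb and
    down the left limb; zero-width end rows close the contour.  The first
    point is repeated at the end.
    """
    w = profile.binocular_width
    e = profile.elevation
    if not np.all(np.isfinite(w)):
        raise ValueError("profile contains blocked rows; interpolate first")
    pos = np.flatnonzero(w > 0)
    if pos.size == 0:
        raise ValueError("degenerate profile: no rows of positive width")
    imax = int(np.argmax(w))
    i0 = imax
    while i0 > 0 and w[i0 - 1] > 0:
        i0 -= 1
    i1 = imax
    while i1 < w.size - 1 and w[i1 + 1] > 0:
        i1 += 1
    lo_i = i0 - 1 if i0 > 0 and w[i0 - 1] == 0 else i0
    hi_i = i1 + 1 if i1 < w.size - 1 and w[i1 + 1] == 0 else i1
    idx = np.arange(lo_i, hi_i + 1)
    right = [(w[i] / 2.0, e[i]) for i in idx]
    left = [(-w[i] / 2.0, e[i]) for i in idx[::-1] if w[i] > 0]
    pts = right + left
    pts.append(pts[0])
    arr = np.asarray(pts, dtype=float)
    if np.unique(arr[:-1], axis=0).shape[0] < 3:
        raise ValueError("degenerate profile: outline has fewer than 3 points")
    return arr


def estimate_lower_bounds(profile: FieldProfile, grid_step: float | None = None) -> FieldProfile:
    """Extend a truncated profile downward to an estimated zero crossing.

    The apparatus prevents observation at the lowest elevations for some
    species; the bottom of the field is then reconstructed by linearly
    extrapolating the two lowest measured widths until the width reaches
    zero.  Added rows are flagged ``estimated_lower_bound``.  If the widths
    do not decrease downward the extrapolation never terminates; a warning is
    issued and the field is closed one grid step below the lowest row.
    """
    w = profile.binocular_width
    e = profile.elevation
    if w.size < 2:
        raise ValueError("need at least 2 measured rows to extrapolate")
    if w[0] == 0:
        return profile.copy()
    step = float(grid_step) if grid_step is not None else float(np.median(np.diff(e)))
    e0, w0 = e[0], w[0]
    e1, w1 = e[1], w[1]
    if w1 <= w0:
        warnings.warn(
            "lower-bound extrapolation does not terminate (widths non-decreasing "
            "downward); forcing closure one grid step below",
            RuntimeWarning,
        )
        new_e = np.array([e0 - step])
        new_w = np.array([0.0])
    else:
        slope = (w1 - w0) / (e1 - e0)  # > 0
        e_zero = e0 - w0 / slope
        grid = []
        ee = e0 - step
        while ee > e_zero + 1e-9:
            grid.append(ee)
            ee -= step
        new_e = np.concatenate([[e_zero], np.sort(grid)]) if grid else np.array([e_zero])
        new_w = np.maximum(0.0, w0 + slope * (new_e - e0))
        new_w[0] = 0.0
    n_new = new_e.size
    lm = rm = None
    if profile.left_margin is not None and profile.right_margin is not None:
        lm = np.concatenate([new_w / 2.0, profile.left_margin])
        rm = np.concatenate([-new_w / 2.0, profile.right_margin])
    return FieldProfile(
        profile.species,
        np.concatenate([new_e, e]),
        np.concatenate([new_w, w]),
        lm,
        rm,
        np.concatenate([np.zeros(n_new, dtype=bool), profile.interpolated]),
        np.concatenate([np.ones(n_new, dtype=bool), profile.estimated_lower_bound]),
    )


def orthographic_project(latitude, longitude, view=(0.0, 0.0)):
    """Orthographic projection of sphere points onto the view plane.

    Standard map projection: with view centre ``(lat0, lon0)``,
    ``x = cos(lat) sin(lon - lon0)`` and
    ``y = cos(lat0) sin(lat) - sin(lat0) cos(lat) cos(lon - lon0)``.
    Points on the far hemisphere are flagged hidden.

    Returns ``(x, y, visible)``.
    """
    lat = np.radians(_require_finite("latitude", latitude))
    lon = np.radians(_require_finite("longitude", longitude))
    if np.any(np.abs(np.degrees(lat)) > 90 + 1e-9):
        raise ValueError("|latitude| must be <= 90")
    lat0, lon0 = np.radians(float(view[0])), np.radians(float(view[1]))
    x = np.cos(lat) * np.sin(lon - lon0)
    y = np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(lon - lon0)
    cosc = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(lon - lon0)
    visible = cosc >= 0
    if np.isscalar(latitude) and np.isscalar(longitude):
        return float(x), float(y), bool(visible)
    return x, y, visible


def field_components(left_medial, left_lateral, right_medial, right_lateral):
    """Decompose the horizontal field at one elevation into its sectors.

    The left eye sees the azimuth interval ``[left_lateral, left_medial]``
    and the right eye ``[right_medial, right_lateral]``.  Returns monocular
    widths, the binocular overlap, the cyclopean (union) width and the blind
    sector, satisfying ``cyclopean = left + right - binocular`` and
    ``blind = 360 - cyclopean``.
    """
    lm, ll = float(left_medial), float(left_lateral)
    rm, rl = float(right_medial), float(right_lateral)
    if ll > lm or rm > rl:
        raise ValueError("margins must satisfy left_lateral <= left_medial and "
                         "right_medial <= right_lateral")
    left_mono = lm - ll
    right_mono = rl - rm
    binoc = max(0.0, min(lm, rl) - max(ll, rm))
    cyclopean = left_mono + right_mono - binoc
    if cyclopean > 360.0 + 1e-9:
        raise ValueError("cyclopean field exceeds 360 degrees")
    return {
        "left_monocular": left_mono,
        "right_monocular": right_mono,
        "binocular": binoc,
        "cyclopean": cyclopean,
        "blind": 360.0 - cyclopean,
    }


# ---------------------------------------------------------------------------
# record-table plumbing
# ---------------------------------------------------------------------------

def read_perimeter_csv(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf)
    missing = [c for c in PERIMETER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"perimeter CSV missing columns: {missing}")
    bad = set(df["eye"].unique()) - {"left", "right"}
    if bad:
        raise ValueError(f"unknown eye labels: {sorted(bad)}")
    bad = set(df["eye_state"].unique()) - {"converged", "diverged"}
    if bad:
        raise ValueError(f"unknown eye_state labels: {sorted(bad)}")
    if np.any(np.abs(df["margin_azimuth_deg"]) > 180 + 1e-9):
        raise ValueError("|margin_azimuth_deg| must be <= 180")
    if np.any(df["apparatus_radius_m"] <= 0):
        raise ValueError("apparatus_radius_m must be > 0")
    return df


def profiles_from_records(records: pd.DataFrame, grid_step: float = GRID_STEP) -> dict:
    """Build corrected per-individual profiles from converged margin records.

    Missing interior grid elevations (bill-holder blocked) become NaN-width
    rows; callers interpolate them with :func:`interpolate_blocked`.

    Returns ``{(species, individual): FieldProfile}``.
    """
    out = {}
    conv = records[records["eye_state"] == "converged"]
    for (sp, ind), g in conv.groupby(["species", "individual"], sort=True):
        piv = {}
        for _, row in g.iterrows():
            th = correct_to_infinity(
                row["margin_azimuth_deg"],
                row["eye"],
                row["apparatus_radius_m"],
                row["eye_separation_m"],
            )
            piv.setdefault(float(row["elevation_deg"]), {})[row["eye"]] = th
        elevs = np.sort(np.array(list(piv.keys())))
        full = np.arange(elevs.min(), elevs.max() + grid_step / 2, grid_step)
        lm = np.full(full.size, np.nan)
        rm = np.full(full.size, np.nan)
        for i, e in enumerate(full):
            rec = piv.get(float(e))
            if rec is not None and "left" in rec and "right" in rec:
                lm[i], rm[i] = rec["left"], rec["right"]
        width = np.where(
            np.isfinite(lm) & np.isfinite(rm), np.maximum(0.0, lm - rm), np.nan
        )
        out[(sp, str(ind))] = FieldProfile(sp, full, width, lm, rm)
    return out


def summaries_from_records(
    records: pd.DataFrame,
    bill_tips: Mapping | pd.Series,
    grid_step: float = GRID_STEP,
) -> pd.DataFrame:
    """Per-individual field summaries from raw perimeter records.

    ``bill_tips`` maps ``(species, individual)`` to the elevation of the
    eye--bill-tip projection (degrees).
    """
    rows = []
    for key, prof in profiles_from_records(records, grid_step).items():
        prof = interpolate_blocked(prof)
        summ = summarize_field(prof, float(bill_tips[key]))
        d = summ.to_dict()
        d["individual"] = key[1]
        rows.append(d)
    df = pd.DataFrame(rows)
    return df[
        ["species", "individual", "max_overlap_deg", "elevation_of_max_deg",
         "vertical_extent_deg", "bill_tip_elevation_deg", "offset_deg", "degenerate"]
    ].sort_values(["species", "individual"], ignore_index=True)


def species_outlines(records: pd.DataFrame, grid_step: float = GRID_STEP) -> dict:
    """One binocular outline per species: mean width over individuals.

    Individual profiles are interpolated, averaged per elevation over the
    individuals measured there, and turned into closed outlines.
    """
    by_species: dict[str, list[FieldProfile]] = {}
    for (sp, _), prof in profiles_from_records(records, grid_step).items():
        by_species.setdefault(sp, []).append(interpolate_blocked(prof))
    out = {}
    for sp, profs in by_species.items():
        elevs = np.unique(np.concatenate([p.elevation for p in profs]))
        acc = np.zeros(elevs.size)
        cnt = np.zeros(elevs.size)
        for p in profs:
            pos = np.searchsorted(elevs, p.elevation)
            acc[pos] += p.binocular_width
            cnt[pos] += 1
        mean_w = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
        out[sp] = outline_from_profile(FieldProfile(sp, elevs, mean_w))
    return out


def species_mean_summaries(individual_summaries: pd.DataFrame) -> pd.DataFrame:
    """Species values: arithmetic mean of the per-individual summaries."""
    num = ["max_overlap_deg", "elevation_of_max_deg", "vertical_extent_deg",
           "bill_tip_elevation_deg", "offset_deg"]
    g = individual_summaries.groupby("species", sort=True)
    out = g[num].mean()
    out["n_individuals"] = g.size()
    return out.reset_index()


# ---------------------------------------------------------------------------
# outline files: x,y per row, one blank-line-separated block per species
# ---------------------------------------------------------------------------

def write_outlines(path, outlines: Mapping[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for name in outlines:
            fh.write(f"# {name}\n")
            for x, y in np.asarray(outlines[name], dtype=float):
                fh.write(f"{x:.10g},{y:.10g}\n")
            fh.write("\n")


def read_outlines(path) -> dict:
    out: dict[str, np.ndarray] = {}
    name, pts = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                name = line[1:].strip()
                pts = []
            elif not line:
                if name is not None and pts:
                    out[name] = np.asarray(pts, dtype=float)
                name, pts = None, []
            else:
                x, y = line.split(",")
                pts.append((float(x), float(y)))
    if name is not None and pts:
        out[name] = np.asarray(pts, dtype=float)
    return out
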