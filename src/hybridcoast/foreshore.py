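"""Wave transformation over vegetated foreshores.

Extreme offshore waves are propagated along shore-normal transects toward the
dike toe. Two processes reduce the significant wave height on the way in:

* depth-induced breaking, which caps the height at a fixed fraction of the
  local water depth (``H <= gamma_br * h``), and
* bottom friction and vegetation drag, modelled as exponential decay whose
  rate scales inversely with the local depth.

A mangrove belt occupies the landward (innermost) part of the submerged
profile and dissipates far more strongly than bare bed.  The integrator below
is also used to populate a four-dimensional lookup table
(slope x depth-at-vegetation-front x incident Hs x vegetation width) that a
large transect set can query by multilinear interpolation instead of
re-marching every profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import ParameterError

logger = logging.getLogger(__name__)

#: breaker index: maximum Hs as a fraction of local still-water depth
GAMMA_BR = 0.78
#: decay coefficient inside the vegetated band [-]
CV = 0.007
#: decay coefficient over bare bed [-]
CB = 0.0002
#: marching step along the transect [m]
DX = 10.0
#: minimum depth used in the decay denominator [m]
DEPTH_FLOOR = 0.1

#: default lookup-table axes: gentle mangrove-foreshore slopes (log-spaced),
#: depths at the vegetation front that keep the belt submerged, incident Hs
#: (log-spaced around the breaking cap), and belt widths to 1 km
DEFAULT_SLOPES = tuple(np.exp(np.linspace(np.log(2e-4), np.log(1e-3), 6)))
DEFAULT_DEPTHS = tuple(np.exp(np.linspace(np.log(2.0), np.log(8.0), 14)))
DEFAULT_HS = tuple(np.exp(np.linspace(np.log(0.5), np.log(4.0), 16)))
DEFAULT_VEG_WIDTHS = tuple(np.linspace(0.0, 1000.0, 11))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HazardCurve:
    """Return-period curve of extreme still-water level and offshore Hs.

    Both series must be nondecreasing in the return period.  Queries at
    intermediate return periods interpolate linearly in ``ln T``.
    """

    return_periods: np.ndarray
    water_level: np.ndarray
    hs_offshore: np.ndarray

    def __post_init__(self):
        rp = np.asarray(self.return_periods, dtype=float)
        wl = np.asarray(self.water_level, dtype=float)
        hs = np.asarray(self.hs_offshore, dtype=float)
        if rp.size != wl.size or rp.size != hs.size:
            raise ParameterError("hazard curve series lengths do not match")
        if rp.size == 0 or np.any(rp < 1) or np.any(np.diff(rp) <= 0):
            raise ParameterError(
                "return_periods must be strictly increasing and >= 1")
        if np.any(np.diff(wl) < -1e-12) or np.any(np.diff(hs) < -1e-12):
            raise ParameterError(
                "water_level and hs_offshore must be nondecreasing in T")
        object.__setattr__(self, "return_periods", rp)
        object.__setattr__(self, "water_level", wl)
        object.__setattr__(self, "hs_offshore", hs)

    def wl(self, T: float) -> float:
        """Still-water level at return period ``T`` (interp in ln T)."""
        return float(np.interp(np.log(T), np.log(self.return_periods),
                               self.water_level))

    def hs(self, T: float) -> float:
        """Offshore significant wave height at return period ``T``."""
        return float(np.interp(np.log(T), np.log(self.return_periods),
                               self.hs_offshore))

    def shifted(self, offset: float) -> "HazardCurve":
        """Curve with all water levels raised by ``offset`` metres."""
        return HazardCurve(self.return_periods,
                           self.water_level + offset,
                           self.hs_offshore)


@dataclass
class Transect:
    """Shore-normal profile with mangrove state and offshore boundary forcing.

    ``profile_chainage`` runs from the offshore start (0 m) landward;
    ``profile_elevation`` is the bed level relative to mean sea level.
    Mangrove widths are belt widths measured along the transect; the restored
    band is assumed to abut the current band on its seaward side.
    """

    id: int
    anchor_x: float
    anchor_y: float
    bearing_deg: float
    profile_chainage: np.ndarray
    profile_elevation: np.ndarray
    mangrove_width_current: float
    mangrove_width_restorable: float
    region_id: int
    hazard: HazardCurve
    #: pre-buffering restorable width (input to :func:`assign_restorable_width`)
    restorable_raw: float = 0.0

    def __post_init__(self):
        ch = np.asarray(self.profile_chainage, dtype=float)
        el = np.asarray(self.profile_elevation, dtype=float)
        if ch.size != el.size or ch.size < 2:
            raise ParameterError("transect profile needs >= 2 matched points")
        if np.any(np.diff(ch) <= 0):
            raise ParameterError("profile chainage must be strictly increasing")
        if self.mangrove_width_current < 0 or self.mangrove_width_restorable < 0:
            raise ParameterError("mangrove widths must be >= 0")
        self.profile_chainage = ch
        self.profile_elevation = el

    @property
    def length(self) -> float:
        return float(self.profile_chainage[-1])

    def veg_width(self, state: str) -> float:
        """Total mangrove belt width for ``state`` in {'current','restored'}."""
        if state == "current":
            return self.mangrove_width_current
        if state == "restored":
            return self.mangrove_width_current + self.mangrove_width_restorable
        raise ParameterError(f"unknown mangrove state {state!r}")


@dataclass(frozen=True)
class AttenuationLookup:
    """Nearshore Hs at the dike toe on idealised planar foreshores.

    Axes: foreshore slope [-], still-water depth at the vegetation front [m],
    incident Hs [m], vegetation belt width [m]. Values are nonincreasing in
    width, nondecreasing in incident Hs, and never exceed the incident Hs.
    """

    slopes: np.ndarray
    depths: np.ndarray
    hs_values: np.ndarray
    veg_widths: np.ndarray
    values: np.ndarray
    _interp: RegularGridInterpolator = field(repr=False, compare=False,
                                             default=None)

    def __post_init__(self):
        # Interpolate log(value) on log-transformed slope/depth/hs axes and
        # linear width: exact for uncapped exponential decay (log H is then
        # linear in log hs and near-linear in width), and far better behaved
        # than linear interpolation where heights get small.
        axes = []
        transforms = []
        for a in (self.slopes, self.depths, self.hs_values):
            if np.all(a > 0):
                axes.append(np.log(a))
                transforms.append(True)
            else:
                axes.append(np.asarray(a, float))
                transforms.append(False)
        axes.append(np.asarray(self.veg_widths, float))
        transforms.append(False)
        logv = np.log(np.maximum(self.values, 1e-12))
        interp = RegularGridInterpolator(
            tuple(axes), logv, method="linear", bounds_error=False,
            fill_value=None)
        object.__setattr__(self, "_interp", interp)
        object.__setattr__(self, "_log_axes", tuple(transforms))


# ---------------------------------------------------------------------------
# wave physics
# ---------------------------------------------------------------------------

def depth_limited_breaking(hs_offshore: float, depth: float,
                           gamma_br: float = GAMMA_BR) -> float:
    """Cap an offshore Hs by depth-induced breaking: ``min(Hs, gamma*h)``."""
    if hs_offshore < 0 or depth < 0:
        raise ParameterError("hs_offshore and depth must be >= 0")
    return min(hs_offshore, gamma_br * depth)


def _march(x: np.ndarray, h: np.ndarray, hs0: float, veg_mask: np.ndarray,
           cv: float, cb: float, gamma_br: float) -> float:
    """Vectorised shoreward march of the capped exponential decay.

    ``x`` are node positions (uniform step), ``h`` still-water depths (> 0),
    ``veg_mask`` marks nodes inside the vegetated band. Equivalent to the
    sequential update  H <- min(H * exp(-c dx / max(h, floor)), gamma*h)
    but computed with prefix sums in log space.
    """
    dx = np.diff(x)
    c = np.where(veg_mask, cv, cb)
    # decay increment on each segment, evaluated at the segment midpoint
    # (second order: halving dx changes smooth-profile output well under 0.5%)
    h_mid = 0.5 * (h[:-1] + h[1:])
    d = c[:-1] * dx / np.maximum(h_mid, DEPTH_FLOOR)
    S = np.concatenate([[0.0], np.cumsum(d)])  # cumulative decay to node i
    caps = gamma_br * h
    # a cap activated at node j re-seeds the decayed height from gamma*h_j;
    # H_end = min over seeds j of seed_j * exp(-(S_end - S_j)), computed as a
    # running minimum in log space
    seeds = np.log(np.maximum(caps, 1e-300))
    seeds[0] = min(seeds[0], np.log(max(hs0, 1e-300)))
    running = np.minimum.accumulate(seeds + S)
    logH_end = running[-1] - S[-1]
    return float(np.exp(logH_end))


def integrate_wave_transect(transect: Transect, swl: float, hs0: float,
                            veg_width: float, *, cv: float = CV,
                            cb: float = CB, gamma_br: float = GAMMA_BR,
                            dx: float = DX) -> float:
    """March ``hs0`` shoreward along the submerged profile; return Hs at the
    landward end.

    The vegetated band occupies the innermost ``veg_width`` metres of the
    submerged transect. Each step applies exponential decay scaled by the
    inverse local depth, then caps the height by the breaking limit.  A fully
    dry transect returns 0 with a warning.
    """
    if hs0 < 0 or veg_width < 0:
        raise ParameterError("hs0 and veg_width must be >= 0")
    ch, el = transect.profile_chainage, transect.profile_elevation
    wet = el < swl
    if not wet.any() or not wet[0]:
        logger.warning("transect %s dry at swl=%.2f m", transect.id, swl)
        return 0.0
    # submerged span: from offshore start to the last wet crossing
    if wet.all():
        x_end = ch[-1]
    else:
        # first index where the profile emerges above swl
        idx = int(np.argmax(~wet))
        # linear interpolation of the waterline crossing
        x0, x1 = ch[idx - 1], ch[idx]
        e0, e1 = el[idx - 1], el[idx]
        x_end = x0 + (swl - e0) / (e1 - e0) * (x1 - x0)
    x_start = ch[0]
    n = max(int(np.ceil((x_end - x_start) / dx)), 1)
    x = np.linspace(x_start, x_end, n + 1)
    bed = np.interp(x, ch, el)
    h = np.clip(swl - bed, 0.0, None)
    veg_mask = x >= (x_end - veg_width)
    return _march(x, h, hs0, veg_mask, cv, cb, gamma_br)


def _planar_transect(slope: float, depth_front: float, width: float) -> Transect:
    """Idealised planar foreshore used for lookup-table cells: the bed starts
    ``depth_front`` below still water and rises at ``slope`` over the
    vegetated span, levelling off at the minimum toe depth (the dike toe is
    never at the exact waterline)."""
    length = max(width, DX)
    toe = min(DEPTH_FLOOR, depth_front)
    x_knee = (depth_front - toe) / slope if slope > 0 else np.inf
    if x_knee < length:
        ch = np.array([0.0, x_knee, length])
        el = np.array([-depth_front, -toe, -toe])
    else:
        ch = np.array([0.0, length])
        el = np.array([-depth_front, -depth_front + slope * length])
    dummy = HazardCurve(np.array([2.0, 100.0]), np.array([0.0, 0.0]),
                        np.array([1.0, 1.0]))
    return Transect(id=-1, anchor_x=0.0, anchor_y=0.0, bearing_deg=270.0,
                    profile_chainage=ch, profile_elevation=el,
                    mangrove_width_current=0.0, mangrove_width_restorable=0.0,
                    region_id=-1, hazard=dummy)


def integrate_planar(slope: float, depth_front: float, hs: float,
                     veg_width: float, *, cv: float = CV, cb: float = CB,
                     gamma_br: float = GAMMA_BR, dx: float = DX) -> float:
    """Direct integration on the idealised planar foreshore geometry used by
    the lookup table.  With ``veg_width = 0`` this reduces to the
    depth-limited incident height at the front."""
    if veg_width <= 0:
        return depth_limited_breaking(hs, depth_front, gamma_br)
    tr = _planar_transect(slope, depth_front, veg_width)
    return integrate_wave_transect(tr, 0.0, hs, veg_width,
                                   cv=cv, cb=cb, gamma_br=gamma_br, dx=dx)


def default_lookup(**kwargs) -> "AttenuationLookup":
    """Attenuation table on the default axes."""
    return build_lookup(DEFAULT_SLOPES, DEFAULT_DEPTHS, DEFAULT_HS,
                        DEFAULT_VEG_WIDTHS, **kwargs)


def build_lookup(slopes, depths, hs_values, veg_widths, *, cv: float = CV,
                 cb: float = CB, gamma_br: float = GAMMA_BR,
                 dx: float = DX) -> AttenuationLookup:
    """Populate the attenuation table by integrating every axis combination
    on an idealised planar transect."""
    axes = [np.asarray(a, dtype=float)
            for a in (slopes, depths, hs_values, veg_widths)]
    for name, a in zip(("slopes", "depths", "hs_values", "veg_widths"), axes):
        if a.size == 0:
            raise ParameterError(f"axis {name} is empty")
        if a.size > 1 and np.any(np.diff(a) <= 0):
            raise ParameterError(f"axis {name} must be strictly increasing")
    sl, de, hs, vw = axes
    values = np.empty((sl.size, de.size, hs.size, vw.size))
    for i, s in enumerate(sl):
        for j, d in enumerate(de):
            for k, H in enumerate(hs):
                for m, w in enumerate(vw):
                    values[i, j, k, m] = integrate_planar(
                        s, d, H, w, cv=cv, cb=cb, gamma_br=gamma_br, dx=dx)
    return AttenuationLookup(sl, de, hs, vw, values)


def lookup_attenuation(lut: AttenuationLookup, slope: float, depth: float,
                       hs: float, veg_width: float) -> float:
    """Multilinear interpolation of the table; queries outside the axis
    bounds are clamped to the edge (logged)."""
    q = np.array([slope, depth, hs, veg_width], dtype=float)
    lo = np.array([lut.slopes[0], lut.depths[0], lut.hs_values[0],
                   lut.veg_widths[0]])
    hi = np.array([lut.slopes[-1], lut.depths[-1], lut.hs_values[-1],
                   lut.veg_widths[-1]])
    clamped = np.clip(q, lo, hi)
    if np.any(clamped != q):
        logger.info("lookup query clamped to table bounds: %s -> %s", q, clamped)
    coords = np.array([np.log(v) if use_log else v
                       for v, use_log in zip(clamped, lut._log_axes)])
    return float(np.exp(np.asarray(lut._interp(coords)).ravel()[0]))


def lookup_to_netcdf(lut: AttenuationLookup, path) -> None:
    """Serialise the table (dims slope, depth, hs, veg_width) to NetCDF."""
    import xarray as xr
    ds = xr.Dataset(
        {"nearshore_hs": (("slope", "depth", "hs", "veg_width"), lut.values)},
        coords={"slope": lut.slopes, "depth": lut.depths, "hs": lut.hs_values,
                "veg_width": lut.veg_widths})
    ds.to_netcdf(path, engine="scipy")


def lookup_from_netcdf(path) -> AttenuationLookup:
    import xarray as xr
    with xr.open_dataset(path, engine="scipy") as ds:
        return AttenuationLookup(
            ds["slope"].values.copy(), ds["depth"].values.copy(),
            ds["hs"].values.copy(), ds["veg_width"].values.copy(),
            ds["nearshore_hs"].values.copy())


# ---------------------------------------------------------------------------
# restorable-width assignment
# ---------------------------------------------------------------------------

def assign_restorable_width(transects, radius: float = 1000.0,
                            at_risk_regions=frozenset()):
    """Smooth raw restorable widths over a neighbourhood buffer.

    Each transect receives the mean of the *raw* restorable widths of all
    transects whose anchors lie within ``radius`` metres and whose region is
    flagged at risk of flooding; a transect with no qualifying neighbour gets
    0. Returns new Transect objects; inputs are not mutated.
    """
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    at_risk = set(at_risk_regions)
    xs = np.array([t.anchor_x for t in transects])
    ys = np.array([t.anchor_y for t in transects])
    raw = np.array([t.restorable_raw for t in transects])
    risk = np.array([t.region_id in at_risk for t in transects])
    out = []
    for i, t in enumerate(transects):
        d2 = (xs - xs[i]) ** 2 + (ys - ys[i]) ** 2
        sel = (d2 <= radius ** 2) & risk
        width = float(raw[sel].mean()) if sel.any() else 0.0
        out.append(replace(t, mangrove_width_restorable=width))
    return out


def transect_nearshore_hs(transect: Transect, swl: float, hs_offshore: float,
                          veg_width: float, lut: AttenuationLookup | None = None,
                          **kwargs) -> float:
    """Nearshore Hs at the dike toe for one transect and sea state.

    Uses the full profile integrator by default.  With ``lut`` the bare
    approach up to the vegetation front is integrated directly (vegetation
    width 0) and the vegetated band is then reduced to its planar equivalent
    (band slope, depth at the vegetation front) and interpolated from the
    table.
    """
    if lut is None:
        return integrate_wave_transect(transect, swl, hs_offshore, veg_width,
                                       **kwargs)
    ch, el = transect.profile_chainage, transect.profile_elevation
    wet = el < swl
    if not wet.any() or not wet[0]:
        return 0.0
    if wet.all():
        x_end = ch[-1]
    else:
        idx = int(np.argmax(~wet))
        x0, x1 = ch[idx - 1], ch[idx]
        e0, e1 = el[idx - 1], el[idx]
        x_end = x0 + (swl - e0) / (e1 - e0) * (x1 - x0)
    x_front = max(x_end - veg_width, ch[0])
    depth_front = max(swl - float(np.interp(x_front, ch, el)), 0.0)
    if x_front > ch[0]:
        # march the unvegetated approach, then hand over to the table
        keep = ch < x_front
        sub_ch = np.concatenate([ch[keep], [x_front]])
        sub_el = np.concatenate([el[keep], [swl - depth_front]])
        approach = replace(transect, profile_chainage=sub_ch,
                           profile_elevation=sub_el)
        hs_front = integrate_wave_transect(approach, swl, hs_offshore, 0.0,
                                           **kwargs)
    else:
        hs_front = depth_limited_breaking(hs_offshore, depth_front)
    span = x_end - x_front
    depth_end = max(swl - float(np.interp(x_end, ch, el)), 0.0)
    slope = (depth_front - depth_end) / span if span > 0 else 0.0
    return lookup_attenuation(lut, slope, depth_front, hs_front, veg_width)
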