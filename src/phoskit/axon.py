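"""Simulated nerve-fiber-bundle map and axonal distance decomposition.

Retinal ganglion cell axons arc from the periphery toward the optic disc and
never cross the temporal raphe (the horizontal boundary temporal to the
fovea). The bundle trajectories follow a fundus-derived model expressed in
polar coordinates (r, φ) about the optic-disc center: a bundle seeded at
angular position φ0 on the disc follows

    φ(r) = φ0 + b · (r − r0)^c     for r ≥ r0,

with region-dependent coefficients (superior hemifield, 0 < φ0 ≤ 180:
ln b = −1.9 + 3.9·tanh(−(φ0 − 121)/14), c = 1.9 + 1.4·tanh((φ0 − 121)/14);
inferior hemifield, −180 ≤ φ0 < 0: ln(−b) = 0.7 + 1.5·tanh(−(−φ0 − 90)/25),
c = 1.0 + 0.5·tanh((−φ0 − 90)/25)), r0 = 4°. Coordinates use the canonical
right-eye retinal frame (fovea origin, +x toward the disc at (15°, 2°),
+y superior) with a constant 280 µm per degree of visual angle.

For an electrode pair, the inter-electrode separation is decomposed into two
nearly orthogonal components measured on the *temporal* electrode's closest
bundle: the **between-axon** distance (from the nasal electrode's center to
that bundle) and the **along-axon** distance (arc length along that bundle
between the two electrodes' foot points). The decomposition is defined for
pairs straddling the raphe as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from phoskit.errors import DomainError

UM_PER_DEG = 280.0

JANSONIUS_DEFAULTS = {
    "r0_deg": 4.0,
    "max_r_deg": 45.0,
    "disc_deg": (15.0, 2.0),
    "sup_b": (-1.9, 3.9, 121.0, 14.0),
    "sup_c": (1.9, 1.4, 121.0, 14.0),
    "inf_b": (0.7, 1.5, 90.0, 25.0),
    "inf_c": (1.0, 0.5, 90.0, 25.0),
}


@dataclass(frozen=True)
class PairDistances:
    """Axonal decomposition of one electrode pair's separation (µm)."""

    electrode_nasal: str
    electrode_temporal: str
    between_axon_um: float
    along_axon_um: float
    euclidean_um: float
    efd_nasal_um: float
    efd_temporal_um: float
    degenerate: bool = False


@dataclass
class AxonMap:
    """Family of nerve-fiber-bundle polylines in retinal µm, fovea origin."""

    bundles: list[np.ndarray]
    model_params: dict
    modeled_radius_um: float
    # cached concatenated segment arrays for nearest-bundle queries
    _seg: dict = field(default_factory=dict, repr=False)

    @property
    def n_bundles(self) -> int:
        return len(self.bundles)

    def _segments(self) -> dict:
        if not self._seg:
            starts, ends, bidx, s0 = [], [], [], []
            for i, poly in enumerate(self.bundles):
                seg_vec = np.diff(poly, axis=0)
                seg_len = np.hypot(seg_vec[:, 0], seg_vec[:, 1])
                cum = np.concatenate([[0.0], np.cumsum(seg_len)])
                starts.append(poly[:-1])
                ends.append(poly[1:])
                bidx.append(np.full(len(poly) - 1, i))
                s0.append(cum[:-1])
            self._seg = {
                "a": np.concatenate(starts),
                "b": np.concatenate(ends),
                "bundle": np.concatenate(bidx),
                "s0": np.concatenate(s0),
            }
        return self._seg


def _phi_of_r(phi0: float, r: np.ndarray, params: dict) -> np.ndarray:
    r0 = params["r0_deg"]
    if phi0 > 0:
        b0, b1, bc, bw = params["sup_b"]
        c0, c1, cc, cw = params["sup_c"]
        b = np.exp(b0 + b1 * np.tanh(-(phi0 - bc) / bw))
        c = c0 + c1 * np.tanh((phi0 - cc) / cw)
    else:
        b0, b1, bc, bw = params["inf_b"]
        c0, c1, cc, cw = params["inf_c"]
        b = -np.exp(b0 + b1 * np.tanh(-(-phi0 - bc) / bw))
        c = c0 + c1 * np.tanh((-phi0 - cc) / cw)
    dr = np.clip(r - r0, 0.0, None)
    return phi0 + b * dr**c


def _trace_bundle(phi0: float, params: dict, step_um: float, modeled_radius_um: float) -> np.ndarray:
    """Trace one bundle from the disc outward, clip at the raphe, resample."""
    r0 = params["r0_deg"]
    rmax = params["max_r_deg"]
    disc = np.asarray(params["disc_deg"], dtype=float)
    # quadratic spacing in r resolves the steep curvature just outside r0
    u = np.linspace(0.0, 1.0, 1600)
    r = np.concatenate([np.linspace(0.3, r0, 8, endpoint=False), r0 + (rmax - r0) * u**2])
    phi = _phi_of_r(phi0, r, params)
    # phi is measured counter-clockwise from the nasal horizontal at the disc;
    # phi0 = 180 deg is the nearly straight papillomacular bundle.
    phi_rad = np.deg2rad(phi)
    xy_deg = disc + np.column_stack([r * np.cos(phi_rad), r * np.sin(phi_rad)])
    xy = xy_deg * UM_PER_DEG
    # clip where the trajectory would cross the raphe (y = 0, temporal retina)
    hemi = 1.0 if phi0 > 0 else -1.0
    bad = (xy[:, 0] < 0) & (hemi * xy[:, 1] < 0)
    if bad.any():
        xy = xy[: int(np.argmax(bad))]
    # clip to the modeled disk about the fovea (keep one point beyond the rim)
    r_fov = np.hypot(xy[:, 0], xy[:, 1])
    outside = r_fov > modeled_radius_um
    if outside.any():
        first_out = int(np.argmax(outside))
        xy = xy[: max(first_out + 1, 2)]
    if len(xy) < 2:
        return xy
    # resample to uniform arc-length spacing
    seg = np.hypot(*np.diff(xy, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(np.ceil(cum[-1] / step_um)), 2)
    s = np.linspace(0.0, cum[-1], n + 1)
    return np.column_stack([np.interp(s, cum, xy[:, 0]), np.interp(s, cum, xy[:, 1])])


def build_axon_map(
    params: dict | None = None,
    n_bundles: int = 500,
    eye: str = "RE",
    *,
    step_um: float = 10.0,
    modeled_radius_deg: float = 30.0,
) -> AxonMap:
    """Build a deterministic axon map with ``n_bundles`` trajectories.

    Bundles are seeded at evenly spaced disc angles φ0 (excluding the raphe
    itself), traced outward at ``step_um`` arc resolution, and clipped at the
    raphe and at ``modeled_radius_deg`` from the fovea. ``eye="LE"`` mirrors
    the map about the vertical meridian.
    """
    if n_bundles < 100:
        raise ValueError("n_bundles must be at least 100")
    p = dict(JANSONIUS_DEFAULTS)
    if params:
        p.update(params)
    modeled_radius_um = modeled_radius_deg * UM_PER_DEG
    # offset by half a step so no seed lands exactly on the raphe (phi0 = 0)
    phi0s = -180.0 + (np.arange(n_bundles) + 0.5) * 360.0 / n_bundles
    bundles = []
    for phi0 in phi0s:
        if abs(phi0) < 1e-9 or abs(abs(phi0) - 180.0) < 1e-9:
            continue
        poly = _trace_bundle(float(phi0), p, step_um, modeled_radius_um)
        if len(poly) >= 2:
            bundles.append(poly)
    amap = AxonMap(bundles, {**p, "n_bundles": n_bundles, "step_um": step_um, "eye": eye},
                   modeled_radius_um)
    if eye == "LE":
        amap.bundles = [poly * np.array([-1.0, 1.0]) for poly in amap.bundles]
    _validate_raphe(amap)
    return amap


def _validate_raphe(amap: AxonMap) -> None:
    sign = -1.0 if amap.model_params.get("eye") == "LE" else 1.0
    for poly in amap.bundles:
        temporal = poly[:, 0] * sign < -1.0
        y = poly[temporal, 1]
        if len(y) and y.min() < -1.0 and y.max() > 1.0:
            raise DomainError("axon trajectory crosses the raphe; invalid model coefficients")


def _nearest_on_segments(point: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Distance, foot point, and in-segment offset of ``point`` vs segments."""
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.einsum("ij,ij->i", point - a, ab) / np.where(denom > 0, denom, 1.0)
    t = np.clip(t, 0.0, 1.0)
    foot = a + t[:, None] * ab
    d = np.hypot(foot[:, 0] - point[0], foot[:, 1] - point[1])
    return d, foot, t * np.sqrt(denom)


def closest_axon(amap: AxonMap, point) -> tuple[int, np.ndarray, float]:
    """Bundle index, foot point, and distance of the bundle closest to ``point``."""
    point = np.asarray(point, dtype=float)
    if np.hypot(point[0], point[1]) > amap.modeled_radius_um:
        raise DomainError(f"point {point} lies outside the modeled region")
    seg = amap._segments()
    d, foot, _ = _nearest_on_segments(point, seg["a"], seg["b"])
    i = int(np.argmin(d))
    return int(seg["bundle"][i]), foot[i], float(d[i])


def _project_on_bundle(amap: AxonMap, bundle_idx: int, point: np.ndarray):
    """Foot point, arc coordinate, and distance of ``point`` on one bundle."""
    seg = amap._segments()
    sel = seg["bundle"] == bundle_idx
    d, foot, offs = _nearest_on_segments(point, seg["a"][sel], seg["b"][sel])
    i = int(np.argmin(d))
    return foot[i], float(seg["s0"][sel][i] + offs[i]), float(d[i])


def electrode_fovea_distance(point) -> float:
    """Euclidean distance (µm) from a fovea-origin retinal position to the fovea."""
    point = np.asarray(point, dtype=float)
    return float(np.hypot(point[0], point[1]))


def pair_distances(
    amap: AxonMap,
    pos_a,
    pos_b,
    labels: tuple[str, str] = ("A", "B"),
    *,
    axon_of: str = "temporal",
) -> PairDistances:
    """Between-axon and along-axon distances for an electrode pair.

    Roles are assigned by the nasal-axis coordinate (larger x = more nasal in
    the canonical right-eye frame; ties broken by |y|, the more peripheral
    electrode counting as temporal). Both components are measured on the
    closest bundle of the electrode selected by ``axon_of`` ("temporal" by
    default; "nasal" retained as an alternative formulation).
    """
    if axon_of not in ("temporal", "nasal"):
        raise ValueError("axon_of must be 'temporal' or 'nasal'")
    pos_a = np.asarray(pos_a, dtype=float)
    pos_b = np.asarray(pos_b, dtype=float)
    euclid = float(np.hypot(*(pos_a - pos_b)))
    # nasal/temporal role assignment
    key_a = (pos_a[0], -abs(pos_a[1]))
    key_b = (pos_b[0], -abs(pos_b[1]))
    if key_a >= key_b:
        nasal_pos, nasal_lab, temp_pos, temp_lab = pos_a, labels[0], pos_b, labels[1]
    else:
        nasal_pos, nasal_lab, temp_pos, temp_lab = pos_b, labels[1], pos_a, labels[0]
    efd_n = electrode_fovea_distance(nasal_pos)
    efd_t = electrode_fovea_distance(temp_pos)
    if euclid == 0.0:
        return PairDistances(nasal_lab, temp_lab, 0.0, 0.0, 0.0, efd_n, efd_t, degenerate=True)
    anchor = temp_pos if axon_of == "temporal" else nasal_pos
    other = nasal_pos if axon_of == "temporal" else temp_pos
    bundle_idx, _, _ = closest_axon(amap, anchor)
    _, s_anchor, _ = _project_on_bundle(amap, bundle_idx, anchor)
    _, s_other, between = _project_on_bundle(amap, bundle_idx, other)
    along = abs(s_anchor - s_other)
    return PairDistances(
        electrode_nasal=nasal_lab,
        electrode_temporal=temp_lab,
        between_axon_um=between,
        along_axon_um=along,
        euclidean_um=euclid,
        efd_nasal_um=efd_n,
        efd_temporal_um=efd_t,
    )
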