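"""Trial manifests, drawing masks, and implant geometry.

Coordinate conventions
----------------------
* Rasters are row-major with the origin at the top-left pixel; ``x`` is the
  column index and ``y`` the row index. Centroids are reported in (x, y)
  pixel units before any scaling.
* Retinal coordinates use a canonical right-eye frame: fovea at the origin,
  +x toward the optic disc (nasal retina), +y superior, units µm. Left-eye
  implants are mirrored into this frame when positions are computed.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage as ndi

from phoskit.errors import DomainError, EmptyDrawingError, IntegrityError, SchemaError

MANIFEST_COLUMNS = [
    "participant",
    "electrode1",
    "electrode2",
    "amplitude_x_th",
    "frequency_hz",
    "trial",
    "mask_path",
    "viewing_distance_cm",
]

#: Visual angle subtended by one electrode disc (degrees); used as the
#: default "comparable location" tolerance (2 electrode radii) when deciding
#: whether a small spec recurs across trials.
ELECTRODE_DIAMETER_DEG = 0.7


@dataclass(frozen=True)
class TrialRecord:
    """One drawing trial: stimulus metadata plus a reference to its mask."""

    participant_id: str
    electrodes: tuple[str, ...]
    amplitude_x_threshold: float
    frequency_hz: float
    trial_index: int
    mask_path: str | None
    viewing_distance_cm: float

    def __post_init__(self) -> None:
        if not 1 <= len(self.electrodes) <= 2:
            raise ValueError(f"expected 1-2 electrodes, got {self.electrodes!r}")
        if len(set(self.electrodes)) != len(self.electrodes):
            raise ValueError(f"paired electrodes must be distinct: {self.electrodes!r}")
        if not self.amplitude_x_threshold > 1:
            raise ValueError("amplitude must exceed 1x threshold")
        if not self.frequency_hz > 0:
            raise ValueError("frequency must be positive")

    @property
    def electrode_key(self) -> str:
        """Canonical string key, e.g. ``"C7"`` or ``"C7+D7"``."""
        return "+".join(self.electrodes)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrodes)


@dataclass(frozen=True)
class ImplantSpec:
    """Geometry of a 6x10 epiretinal electrode array relative to the fovea.

    ``rotation_deg`` rotates the array about its own center
    (counter-clockwise in the canonical right-eye frame);
    ``center_offset_um`` places the array center relative to the fovea.
    ``per_electrode`` optionally maps electrode labels to
    ``{"erd_um": electrode-retina distance, "threshold_ua": current}``.
    """

    grid_shape: tuple[int, int] = (6, 10)
    pitch_um: float = 575.0
    electrode_diameter_um: float = 200.0
    rotation_deg: float = 0.0
    center_offset_um: tuple[float, float] = (0.0, 0.0)
    eye: str = "RE"
    per_electrode: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if not self.pitch_um > self.electrode_diameter_um > 0:
            raise ValueError("require pitch_um > electrode_diameter_um > 0")
        if self.eye not in ("RE", "LE"):
            raise ValueError(f"eye must be 'RE' or 'LE', got {self.eye!r}")

    @property
    def electrode_labels(self) -> list[str]:
        rows, cols = self.grid_shape
        return [f"{chr(ord('A') + r)}{c + 1}" for r in range(rows) for c in range(cols)]


@dataclass
class DrawingMask:
    """A binary phosphene drawing plus the screen geometry it was drawn on."""

    pixels: np.ndarray
    pixel_pitch_mm: float
    viewing_distance_cm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2 or 0 in self.pixels.shape:
            raise ValueError("mask raster must be 2-D and non-empty")

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())


# ---------------------------------------------------------------------------
# Manifest I/O


def _parse_row(row: Mapping[str, str]) -> TrialRecord:
    electrodes = [row["electrode1"].strip()]
    e2 = (row.get("electrode2") or "").strip()
    if e2:
        electrodes.append(e2)
    return TrialRecord(
        participant_id=row["participant"].strip(),
        electrodes=tuple(electrodes),
        amplitude_x_threshold=float(row["amplitude_x_th"]),
        frequency_hz=float(row["frequency_hz"]),
        trial_index=int(row["trial"]),
        mask_path=row["mask_path"].strip() or None,
        viewing_distance_cm=float(row["viewing_distance_cm"]),
    )


def load_manifest(path: str | Path) -> tuple[list[TrialRecord], list[dict]]:
    """Read a trial manifest CSV.

    Returns ``(records, rejected)`` where ``rejected`` holds one dict per
    unparseable row (``row_number``, ``reason``, ``row``). A missing column
    raises :class:`SchemaError`; a duplicate
    (participant, electrodes, amplitude, frequency, trial) combination raises
    :class:`IntegrityError`.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in MANIFEST_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"manifest {path} missing columns: {missing}")
        records: list[TrialRecord] = []
        rejected: list[dict] = []
        seen: set[tuple] = set()
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = _parse_row(row)
            except (ValueError, KeyError) as exc:
                rejected.append({"row_number": lineno, "reason": str(exc), "row": dict(row)})
                continue
            key = (
                rec.participant_id,
                rec.electrodes,
                rec.amplitude_x_threshold,
                rec.frequency_hz,
                rec.trial_index,
            )
            if key in seen:
                raise IntegrityError(f"duplicate trial at manifest line {lineno}: {key}")
            seen.add(key)
            records.append(rec)
    return records, rejected


def save_manifest(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Write records to a manifest CSV (inverse of :func:`load_manifest`)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for rec in records:
            e2 = rec.electrodes[1] if len(rec.electrodes) == 2 else ""
            writer.writerow(
                [
                    rec.participant_id,
                    rec.electrodes[0],
                    e2,
                    repr(rec.amplitude_x_threshold),
                    repr(rec.frequency_hz),
                    rec.trial_index,
                    rec.mask_path or "",
                    repr(rec.viewing_distance_cm),
                ]
            )


# ---------------------------------------------------------------------------
# Masks


def load_mask(path: str | Path, pixel_pitch_mm: float, viewing_distance_cm: float) -> DrawingMask:
    """Load a single-channel PNG mask; any nonzero pixel counts as drawn."""
    img = np.asarray(Image.open(path).convert("L"))
    return DrawingMask(img > 0, pixel_pitch_mm, viewing_distance_cm)


def save_mask(mask: DrawingMask, path: str | Path) -> None:
    Image.fromarray((mask.pixels * np.uint8(255))).save(path)


def pixels_to_degrees(mask: DrawingMask) -> float:
    """Degrees of visual angle subtended by one screen pixel.

    Uses the per-pixel arctangent at the mask's viewing distance, so the
    factor is exact for a pixel at the line of sight and accurate to the
    small-angle approximation elsewhere.
    """
    if mask.pixel_pitch_mm <= 0 or mask.viewing_distance_cm <= 0:
        raise DomainError("pixel pitch and viewing distance must be positive")
    return math.degrees(math.atan2(mask.pixel_pitch_mm, mask.viewing_distance_cm * 10.0))


# ---------------------------------------------------------------------------
# Implant geometry


def electrode_positions(spec: ImplantSpec) -> dict[str, np.ndarray]:
    """Retinal position (µm, fovea origin) of every electrode on the array.

    The ideal grid (rows A-F top to bottom, columns 1-10 left to right,
    spaced ``pitch_um``) is rotated about the array center, translated by
    ``center_offset_um``, and — for left eyes — mirrored about the vertical
    meridian into the canonical right-eye frame.
    """
    rows, cols = spec.grid_shape
    theta = math.radians(spec.rotation_deg)
    rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
    out: dict[str, np.ndarray] = {}
    for r in range(rows):
        for c in range(cols):
            local = np.array(
                [
                    (c - (cols - 1) / 2.0) * spec.pitch_um,
                    ((rows - 1) / 2.0 - r) * spec.pitch_um,
                ]
            )
            pos = rot @ local + np.asarray(spec.center_offset_um, dtype=float)
            if spec.eye == "LE":
                pos = pos * np.array([-1.0, 1.0])
            out[f"{chr(ord('A') + r)}{c + 1}"] = pos
    return out


def electrode_position(spec: ImplantSpec, label: str) -> np.ndarray:
    positions = electrode_positions(spec)
    try:
        return positions[label]
    except KeyError:
        raise KeyError(f"unknown electrode label {label!r} for grid {spec.grid_shape}") from None


def load_implant_spec(path: str | Path) -> ImplantSpec:
    """Read an implant geometry config (YAML or JSON)."""
    path = Path(path)
    with path.open() as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    return ImplantSpec(
        grid_shape=tuple(data.get("grid_shape", (6, 10))),
        pitch_um=float(data.get("pitch_um", 575.0)),
        electrode_diameter_um=float(data.get("electrode_diameter_um", 200.0)),
        rotation_deg=float(data.get("rotation_deg", 0.0)),
        center_offset_um=tuple(data.get("center_offset_um", (0.0, 0.0))),
        eye=data.get("eye", "RE"),
        per_electrode=data.get("per_electrode"),
    )


def save_implant_spec(spec: ImplantSpec, path: str | Path) -> None:
    data = {
        "grid_shape": list(spec.grid_shape),
        "pitch_um": spec.pitch_um,
        "electrode_diameter_um": spec.electrode_diameter_um,
        "rotation_deg": spec.rotation_deg,
        "center_offset_um": list(spec.center_offset_um),
        "eye": spec.eye,
    }
    if spec.per_electrode is not None:
        data["per_electrode"] = {k: dict(v) for k, v in spec.per_electrode.items()}
    path = Path(path)
    with path.open("w") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh)


# ---------------------------------------------------------------------------
# Drawing cleanup


def close_contours(mask: DrawingMask) -> DrawingMask:
    """Flood-fill the interior of closed contour lines (optional utility).

    Input drawings are normally assumed to arrive with closed, filled
    contours; this helper exists for raw stroke data and is not part of the
    default pipeline.
    """
    filled = ndi.binary_fill_holes(mask.pixels)
    return DrawingMask(filled, mask.pixel_pitch_mm, mask.viewing_distance_cm)


def _region_centroids(pixels: np.ndarray, max_area: float | None = None) -> list[tuple[float, float]]:
    labels, n = ndi.label(pixels, structure=np.ones((3, 3), dtype=int))
    cents = []
    for idx in range(1, n + 1):
        region = labels == idx
        area = int(region.sum())
        if max_area is not None and area >= max_area:
            continue
        ys, xs = np.nonzero(region)
        cents.append((float(xs.mean()), float(ys.mean())))
    return cents


def clean_drawing(
    mask: DrawingMask,
    sibling_trials: Sequence[DrawingMask] = (),
    *,
    min_area_px: int = 10,
    recurrence: float = 0.5,
    match_radius_px: float | None = None,
) -> DrawingMask:
    """Remove small non-recurring specs from a drawing.

    Connected regions (8-connected) smaller than ``min_area_px`` pixels are
    removed unless a region at a comparable location — centroid within
    ``match_radius_px`` — appears in at least ``recurrence`` of the sibling
    trials of the same electrode/stimulus combination. The default matching
    radius is two electrode radii (0.7 degrees of visual angle) converted to
    pixels via the mask's screen geometry.

    Raises :class:`EmptyDrawingError` if nothing survives, mirroring the
    removal of fully degenerate drawings from downstream analysis.
    """
    if match_radius_px is None:
        match_radius_px = ELECTRODE_DIAMETER_DEG / pixels_to_degrees(mask)
    structure = np.ones((3, 3), dtype=int)
    labels, n = ndi.label(mask.pixels, structure=structure)
    if n == 0:
        raise EmptyDrawingError("mask has no foreground pixels")
    sibling_cents = [_region_centroids(s.pixels) for s in sibling_trials]
    keep = np.zeros_like(mask.pixels)
    for idx in range(1, n + 1):
        region = labels == idx
        if int(region.sum()) >= min_area_px:
            keep |= region
            continue
        ys, xs = np.nonzero(region)
        cx, cy = float(xs.mean()), float(ys.mean())
        if sibling_cents:
            hits = sum(
                any(math.hypot(cx - sx, cy - sy) <= match_radius_px for sx, sy in cents)
                for cents in sibling_cents
            )
            if hits / len(sibling_cents) >= recurrence:
                keep |= region
    if not keep.any():
        raise EmptyDrawingError("no region survived spec cleaning")
    return DrawingMask(keep, mask.pixel_pitch_mm, mask.viewing_distance_cm)
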