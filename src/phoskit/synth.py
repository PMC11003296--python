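"""Seeded synthetic drawing cohorts with planted effect structure.

The generator emulates the statistical structure the analysis pipeline
assumes, so that every stage — descriptor extraction, normalization,
summation regression, and the axonal model comparison — can be verified
end-to-end against known ground truth:

* single-electrode percepts are elongated along the nerve-fiber bundle
  closest to the electrode, with radial width growing with stimulus
  amplitude and axial extent growing with pulse frequency and retinal
  eccentricity;
* paired-electrode percepts are the union of the two gain-scaled single
  percepts (total descriptor sums ≈ gain × sum of the singles), merging
  into one region with a probability that follows a logistic in the
  between-axon distance (or, optionally, the along-axon distance);
* trial-to-trial variability enters as multiplicative size jitter, percept
  position jitter, a per-participant scale bias, and occasional sub-10-pixel
  spec noise for the cleaning stage to remove.

This percept model is a deliberately simplified test harness — radial and
axial extents follow smooth power laws around a tapered axon segment — not a
re-implementation of published phosphene models. All randomness derives from
one master seed through counter-based seed sequences, so any individual
trial is regenerable in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from phoskit.axon import UM_PER_DEG, AxonMap, build_axon_map, closest_axon, pair_distances, _project_on_bundle
from phoskit.io import (
    DrawingMask,
    ImplantSpec,
    TrialRecord,
    electrode_positions,
    save_implant_spec,
    save_manifest,
    save_mask,
)


@dataclass
class GroundTruth:
    """Planted generative parameters for one synthetic cohort."""

    gain: float = 0.65                  # paired descriptor sum = gain x single sum
    count_mechanism: str = "between"    # which axonal distance drives the split
    # logistic midpoints sit near the median pair distance on a 575 µm-pitch
    # grid, so cohorts split into one vs two phosphenes at realistic rates
    split_midpoint_um: float = 2200.0   # logistic midpoint for P(two phosphenes)
    split_slope_um: float = 900.0
    along_midpoint_um: float = 1200.0   # used when count_mechanism == "along"
    along_slope_um: float = 600.0
    width_um: float = 28.0              # radial half-width at 1x threshold
    length_um: float = 140.0            # axial half-length at 20 Hz, reference ecc
    amp_width_exp: float = 0.5
    amp_length_exp: float = 0.15
    freq_length_exp: float = 0.35
    ecc_length_exp: float = 0.5
    ecc_width_exp: float = 0.2
    efd_ref_um: float = 2000.0
    freq_ref_hz: float = 20.0
    size_jitter_sd: float = 0.10        # SD of log size multiplier per trial
    position_jitter_um: float = 30.0
    spec_noise_prob: float = 0.10       # chance of a small non-recurring spec
    participant_scale_bias: dict = field(default_factory=dict)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError("gain must be positive")
        if self.split_midpoint_um <= 0 or self.along_midpoint_um <= 0:
            raise ValueError("logistic midpoints must be positive")
        if self.count_mechanism not in ("between", "along"):
            raise ValueError("count_mechanism must be 'between' or 'along'")

    def extents_um(self, amplitude: float, frequency: float, efd_um: float) -> tuple[float, float]:
        """Noise-free axial half-length and radial half-width (µm)."""
        ecc = max(efd_um, 200.0) / self.efd_ref_um
        length = (
            self.length_um
            * amplitude**self.amp_length_exp
            * (frequency / self.freq_ref_hz) ** self.freq_length_exp
            * ecc**self.ecc_length_exp
        )
        width = self.width_um * amplitude**self.amp_width_exp * ecc**self.ecc_width_exp
        return length, width


@dataclass
class ParticipantConfig:
    participant_id: str
    rotation_deg: float
    center_offset_um: tuple[float, float]
    viewing_distance_cm: float
    scale_bias: float = 1.0
    has_erd: bool = False


@dataclass
class CohortConfig:
    """Study design of a synthetic cohort (condition grid mirrors the
    single-amplitude/frequency sweeps plus 20 Hz-only paired conditions)."""

    participants: list[ParticipantConfig] = field(
        default_factory=lambda: [
            ParticipantConfig("P1", -32.0, (-1800.0, 400.0), 83.8, 1.15, has_erd=True),
            ParticipantConfig("P2", -44.0, (-1200.0, -300.0), 76.2, 0.85),
            ParticipantConfig("P3", -36.0, (-1500.0, 200.0), 77.5, 1.0),
        ]
    )
    n_electrodes: int = 10
    n_pairs: int = 12
    single_amps: tuple = (1.25, 1.5, 2.0, 3.0, 4.0, 7.5)
    single_freqs: tuple = (6.0, 40.0, 60.0, 120.0)  # at the fixed amplitude below
    freq_sweep_amp: float = 2.0
    paired_amps: tuple = (1.5, 2.0, 4.0)
    trials_per_condition: int = 5
    pixel_pitch_mm: float = 0.5
    min_pair_separation_um: float = 1150.0
    n_bundles: int = 500


@dataclass
class CohortTrial:
    record: TrialRecord
    mask: DrawingMask


@dataclass
class Cohort:
    trials: list[CohortTrial]
    implants: dict[str, ImplantSpec]
    positions: dict[str, dict[str, np.ndarray]]
    axon_map: AxonMap
    truth: GroundTruth
    config: CohortConfig

    @property
    def records(self) -> list[TrialRecord]:
        return [t.record for t in self.trials]


# ---------------------------------------------------------------------------
# Percept rendering


def _stamps_on_bundle(poly: np.ndarray, s0: float, half_len: float, width: float,
                      offset: np.ndarray) -> np.ndarray:
    """Tapered disk stamps (x_um, y_um, r_um) along one bundle polyline."""
    seg = np.hypot(*np.diff(poly, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    step = max(width / 3.0, 5.0)
    # slide the axial window along the bundle if it would overrun an end,
    # so the percept keeps its planted extent near the raphe or map rim
    lo, hi = s0 - half_len, s0 + half_len
    if lo < 0.0:
        hi, lo = min(hi - lo, cum[-1]), 0.0
    if hi > cum[-1]:
        lo, hi = max(lo - (hi - cum[-1]), 0.0), cum[-1]
    center, half = 0.5 * (lo + hi), max(0.5 * (hi - lo), step)
    s = np.arange(lo, hi + step, step)
    s = np.clip(s, 0.0, cum[-1])
    frac = np.clip(1.0 - ((s - center) / half) ** 2, 0.0, None)
    r = width * np.sqrt(frac)
    # truncate the taper so consecutive stamps always overlap (no bead-off tips)
    keep = r > max(0.4 * width, 2.0)
    if not keep.any():
        keep[np.argmin(np.abs(s - s0))] = True
        r = np.maximum(r, 2.0)
    x = np.interp(s[keep], cum, poly[:, 0]) + offset[0]
    y = np.interp(s[keep], cum, poly[:, 1]) + offset[1]
    return np.column_stack([x, y, r[keep]])


def stamp_bounds(stamp_sets: list[np.ndarray], pad_um: float = 0.0) -> tuple:
    """Bounding box (x0, y0, x1, y1) in µm around a set of stamp disks."""
    allstamps = np.vstack(stamp_sets)
    r = allstamps[:, 2].max()
    return (
        allstamps[:, 0].min() - r - pad_um,
        allstamps[:, 1].min() - r - pad_um,
        allstamps[:, 0].max() + r + pad_um,
        allstamps[:, 1].max() + r + pad_um,
    )


def _rasterize(stamp_sets: list[np.ndarray], pixel_pitch_mm: float,
               viewing_distance_cm: float, specs: np.ndarray | None = None,
               bounds_um: tuple | None = None) -> DrawingMask:
    """Render stamp disks (retinal µm) onto a screen-pixel canvas.

    ``bounds_um`` fixes the canvas frame; all trials of one stimulus
    condition share it so that region locations are comparable across
    trials (as on a real touchscreen). Stamps outside the frame are
    clipped. Without bounds the canvas tightly wraps the stamps.
    """
    deg_per_px = math.degrees(math.atan2(pixel_pitch_mm, viewing_distance_cm * 10.0))
    um_per_px = UM_PER_DEG * deg_per_px
    if bounds_um is None:
        bounds_um = stamp_bounds(stamp_sets, pad_um=6 * um_per_px)
    x0, y0, x1, y1 = bounds_um
    allstamps = np.vstack(stamp_sets)
    w = max(int(np.ceil((x1 - x0) / um_per_px)), 8)
    h = max(int(np.ceil((y1 - y0) / um_per_px)), 8)
    canvas = np.zeros((h, w), dtype=bool)
    for sx, sy, sr in allstamps:
        cx = (sx - x0) / um_per_px
        cy = (sy - y0) / um_per_px
        rpx = sr / um_per_px
        lo_x, hi_x = int(max(cx - rpx - 1, 0)), int(min(cx + rpx + 2, w))
        lo_y, hi_y = int(max(cy - rpx - 1, 0)), int(min(cy + rpx + 2, h))
        if lo_x >= hi_x or lo_y >= hi_y:
            continue
        yy, xx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
        canvas[lo_y:hi_y, lo_x:hi_x] |= (xx - cx) ** 2 + (yy - cy) ** 2 <= rpx**2
    if not canvas.any():
        canvas[h // 2, w // 2] = True
    if specs is not None and len(specs):
        # specs land in a band along the top edge of the shared frame; the
        # condition frame is padded enough that the percept never reaches it
        for px, py, n_px in specs:
            n_px = int(n_px)
            side = max(int(round(math.sqrt(n_px))), 1)
            x = 2 + int(px) % max(w - side - 4, 1)
            y = int(py) % 8
            canvas[y : y + side, x : x + max(n_px // side, 1)] = True
    return DrawingMask(canvas, pixel_pitch_mm, viewing_distance_cm)


def _site(amap: AxonMap, pos: np.ndarray):
    bundle_idx, _, _ = closest_axon(amap, pos)
    _, s0, _ = _project_on_bundle(amap, bundle_idx, pos)
    return amap.bundles[bundle_idx], s0


def _jittered_extents(length: float, width: float, truth: GroundTruth, bias: float,
                      rng: np.random.Generator | None, scale: float = 1.0):
    length *= bias * scale
    width *= bias * scale
    offset = np.zeros(2)
    if rng is not None and truth.size_jitter_sd > 0:
        length *= math.exp(rng.normal(0.0, truth.size_jitter_sd))
        width *= math.exp(rng.normal(0.0, truth.size_jitter_sd))
    if rng is not None and truth.position_jitter_um > 0:
        offset = rng.normal(0.0, truth.position_jitter_um, 2)
    return length, width, offset


def _maybe_specs(rng: np.random.Generator | None, truth: GroundTruth) -> np.ndarray | None:
    if rng is None or rng.random() >= truth.spec_noise_prob:
        return None
    return np.array([[rng.integers(0, 10_000), rng.integers(0, 10_000), rng.integers(2, 9)]])


def render_single_percept(
    electrode_pos_um,
    amplitude: float,
    frequency: float,
    amap: AxonMap,
    truth: GroundTruth,
    *,
    bias: float = 1.0,
    rng: np.random.Generator | None = None,
    scale: float = 1.0,
    pixel_pitch_mm: float = 0.5,
    viewing_distance_cm: float = 80.0,
    site=None,
    bounds_um: tuple | None = None,
) -> DrawingMask:
    """Render one single-electrode drawing as a binary mask.

    With ``rng=None`` the render is noise-free and deterministic. ``scale``
    multiplies both linear extents (used for gain-scaled paired renders).
    ``bounds_um`` fixes the canvas frame shared by all trials of a condition.
    """
    pos = np.asarray(electrode_pos_um, dtype=float)
    poly, s0 = site if site is not None else _site(amap, pos)
    length, width = truth.extents_um(amplitude, frequency, float(np.hypot(*pos)))
    length, width, offset = _jittered_extents(length, width, truth, bias, rng, scale)
    stamps = _stamps_on_bundle(poly, s0, length, width, offset)
    return _rasterize([stamps], pixel_pitch_mm, viewing_distance_cm,
                      specs=_maybe_specs(rng, truth), bounds_um=bounds_um)


def split_probability(truth: GroundTruth, between_um: float, along_um: float) -> float:
    """Planted probability that a pair is perceived as two phosphenes."""
    if truth.count_mechanism == "between":
        z = (between_um - truth.split_midpoint_um) / truth.split_slope_um
    else:
        z = (along_um - truth.along_midpoint_um) / truth.along_slope_um
    z = min(max(z, -500.0), 500.0)
    return 1.0 / (1.0 + math.exp(-z))


def render_paired_percept(
    pos1_um,
    pos2_um,
    amplitude: float,
    amap: AxonMap,
    truth: GroundTruth,
    *,
    bias: float = 1.0,
    rng: np.random.Generator | None = None,
    pixel_pitch_mm: float = 0.5,
    viewing_distance_cm: float = 80.0,
    sites=None,
    distances=None,
    bounds_um: tuple | None = None,
) -> DrawingMask:
    """Render one paired-electrode drawing (20 Hz conditions).

    Each constituent percept is scaled by sqrt(gain) so total descriptor
    sums approximate gain × (sum of the single percepts). With probability
    1 − P(two | axonal distance) the pair merges into a single compact
    percept whose area is calibrated to the same gain target.
    """
    pos1 = np.asarray(pos1_um, dtype=float)
    pos2 = np.asarray(pos2_um, dtype=float)
    freq = truth.freq_ref_hz
    dist = distances if distances is not None else pair_distances(amap, pos1, pos2)
    p_two = split_probability(truth, dist.between_axon_um, dist.along_axon_um)
    two = (rng.random() < p_two) if rng is not None else (p_two >= 0.5)
    if np.array_equal(pos1, pos2):
        two = False
    scale = math.sqrt(truth.gain)
    site1 = sites[0] if sites is not None else _site(amap, pos1)
    site2 = sites[1] if sites is not None else _site(amap, pos2)
    if two:
        stamp_sets = []
        for pos, site in [(pos1, site1), (pos2, site2)]:
            length, width = truth.extents_um(amplitude, freq, float(np.hypot(*pos)))
            length, width, offset = _jittered_extents(length, width, truth, bias, rng, scale)
            stamp_sets.append(_stamps_on_bundle(site[0], site[1], length, width, offset))
    else:
        # merged percept: the two gain-scaled percepts rendered end-to-end
        # (slightly overlapping) on the bundle under the pair midpoint, so
        # they fuse into one cohesive region while the descriptor sums keep
        # the planted gain
        mid = 0.5 * (pos1 + pos2)
        poly, s0 = _site(amap, mid)
        mu = 0.917  # truncated taper edge: the two halves abut end-to-end
        extents = []
        shared_offset = None
        for pos in (pos1, pos2):
            length, width = truth.extents_um(amplitude, freq, float(np.hypot(*pos)))
            length, width, offset = _jittered_extents(length, width, truth, bias, rng, scale)
            if shared_offset is None:
                shared_offset = offset  # one drawing: both halves move together
            extents.append((length, width))
        # clamp the junction so both halves fit on the bundle without
        # sliding back over each other (bundles are clipped at the raphe)
        seg = np.hypot(*np.diff(poly, axis=0).T)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        (l1, w1), (l2, w2) = extents
        lo_j, hi_j = (1.0 + mu) * l1, cum[-1] - (1.0 + mu) * l2
        junction = float(np.clip(s0, lo_j, min(hi_j, cum[-1]))) if lo_j <= hi_j else s0
        stamp_sets = [
            _stamps_on_bundle(poly, junction - mu * l1, l1, w1, shared_offset),
            _stamps_on_bundle(poly, junction + mu * l2, l2, w2, shared_offset),
        ]
        # a small waist stamp guarantees the two halves fuse into one region
        jx = np.interp(junction, cum, poly[:, 0]) + shared_offset[0]
        jy = np.interp(junction, cum, poly[:, 1]) + shared_offset[1]
        stamp_sets.append(np.array([[jx, jy, 0.5 * (w1 + w2) / 2.0]]))
    return _rasterize(stamp_sets, pixel_pitch_mm, viewing_distance_cm,
                      specs=_maybe_specs(rng, truth), bounds_um=bounds_um)


def _condition_bounds(kind, positions, sites, amap, truth, amp, freq, bias) -> tuple:
    """Shared canvas frame for all trials of one condition.

    The envelope inflates the noise-free extents by three size-jitter SDs
    and pads by four position-jitter SDs, so jittered trials virtually
    always fit inside the fixed frame.
    """
    inflate = math.exp(3.0 * truth.size_jitter_sd)
    # the margin also keeps the percept clear of the spec-noise band at the
    # frame's top edge (which sits within the spec-matching radius otherwise)
    pad = 4.0 * truth.position_jitter_um + 230.0
    zero = np.zeros(2)
    sets = []
    if kind == "single":
        (pos,), (site,) = positions, sites
        length, width = truth.extents_um(amp, freq, float(np.hypot(*pos)))
        sets.append(_stamps_on_bundle(site[0], site[1],
                                      length * inflate * bias, width * inflate * bias, zero))
    else:
        # cover both the split and the merged rendering variants
        for pos, site in zip(positions, sites):
            length, width = truth.extents_um(amp, freq, float(np.hypot(*pos)))
            sets.append(_stamps_on_bundle(site[0], site[1],
                                          length * inflate * bias, width * inflate * bias, zero))
        mid = 0.5 * (positions[0] + positions[1])
        poly, s0 = _site(amap, mid)
        seg = np.hypot(*np.diff(poly, axis=0).T)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        ext = [
            tuple(e * inflate * bias
                  for e in truth.extents_um(amp, freq, float(np.hypot(*pos))))
            for pos in positions
        ]
        lo_j, hi_j = 1.917 * ext[0][0], cum[-1] - 1.917 * ext[1][0]
        junction = float(np.clip(s0, lo_j, max(hi_j, lo_j))) if lo_j <= hi_j else s0
        for sign, (length, width) in zip((-1.0, 1.0), ext):
            sets.append(_stamps_on_bundle(poly, junction + sign * 0.917 * length,
                                          length, width, zero))
    return stamp_bounds(sets, pad_um=pad)


# ---------------------------------------------------------------------------
# Cohort generation


def _trial_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Counter-based per-trial generator: any trial is regenerable alone."""
    return np.random.default_rng(np.random.SeedSequence((int(master_seed),) + tuple(int(k) for k in key)))


def _sample_pairs(labels: list[str], positions: dict[str, np.ndarray], n_pairs: int,
                  min_sep_um: float, rng: np.random.Generator) -> list[tuple[str, str]]:
    eligible = [
        (a, b)
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
        if np.hypot(*(positions[a] - positions[b])) >= min_sep_um
    ]
    if len(eligible) < n_pairs:
        raise ValueError("not enough electrode pairs satisfy the separation constraint")
    idx = rng.choice(len(eligible), size=n_pairs, replace=False)
    return [eligible[i] for i in sorted(idx)]


def generate_cohort(config: CohortConfig | None = None, seed: int = 0,
                    truth: GroundTruth | None = None,
                    axon_map: AxonMap | None = None) -> Cohort:
    """Generate a full in-memory cohort from one master seed.

    The condition grid per participant: an amplitude sweep at 20 Hz and a
    frequency sweep at a fixed amplitude for every sampled electrode, plus
    paired conditions (20 Hz only) for sampled electrode pairs, each
    condition repeated ``trials_per_condition`` times.
    """
    config = config or CohortConfig()
    truth = truth or GroundTruth(master_seed=seed)
    truth.master_seed = seed
    amap = axon_map or build_axon_map(n_bundles=config.n_bundles)
    trials: list[CohortTrial] = []
    implants: dict[str, ImplantSpec] = {}
    all_positions: dict[str, dict[str, np.ndarray]] = {}
    for pidx, pconf in enumerate(config.participants):
        pid = pconf.participant_id
        bias = truth.participant_scale_bias.get(pid, pconf.scale_bias)
        truth.participant_scale_bias[pid] = bias
        setup_rng = _trial_rng(seed, pidx, 9_999)
        per_electrode = None
        spec = ImplantSpec(rotation_deg=pconf.rotation_deg,
                           center_offset_um=tuple(pconf.center_offset_um))
        positions = electrode_positions(spec)
        labels = sorted(setup_rng.choice(sorted(positions), size=config.n_electrodes,
                                         replace=False).tolist())
        if pconf.has_erd:
            erd_rng = _trial_rng(seed, pidx, 7_777)
            per_electrode = {lab: {"erd_um": float(erd_rng.uniform(30.0, 350.0))}
                             for lab in labels}
        else:
            per_electrode = {lab: {"erd_um": 0.0} for lab in labels}
        spec = dataclasses.replace(spec, per_electrode=per_electrode)
        implants[pid] = spec
        all_positions[pid] = positions
        sites = {lab: _site(amap, positions[lab]) for lab in labels}
        # enumerate conditions deterministically
        conditions: list[tuple] = []
        for lab in labels:
            for amp in config.single_amps:
                conditions.append(("single", lab, amp, truth.freq_ref_hz))
            for freq in config.single_freqs:
                conditions.append(("single", lab, config.freq_sweep_amp, freq))
        pair_rng = _trial_rng(seed, pidx, 8_888)
        pairs = _sample_pairs(labels, positions, config.n_pairs,
                              config.min_pair_separation_um, pair_rng)
        pair_dists = {
            (a, b): pair_distances(amap, positions[a], positions[b], labels=(a, b))
            for a, b in pairs
        }
        for a, b in pairs:
            for amp in config.paired_amps:
                conditions.append(("paired", (a, b), amp, truth.freq_ref_hz))
        for cidx, (kind, who, amp, freq) in enumerate(conditions):
            if kind == "single":
                bounds = _condition_bounds(
                    "single", (positions[who],), (sites[who],), amap, truth, amp, freq, bias)
            else:
                a, b = who
                bounds = _condition_bounds(
                    "paired", (positions[a], positions[b]), (sites[a], sites[b]),
                    amap, truth, amp, freq, bias)
            for trial in range(1, config.trials_per_condition + 1):
                rng = _trial_rng(seed, pidx, cidx, trial)
                if kind == "single":
                    mask = render_single_percept(
                        positions[who], amp, freq, amap, truth,
                        bias=bias, rng=rng,
                        pixel_pitch_mm=config.pixel_pitch_mm,
                        viewing_distance_cm=pconf.viewing_distance_cm,
                        site=sites[who], bounds_um=bounds,
                    )
                    electrodes = (who,)
                else:
                    a, b = who
                    mask = render_paired_percept(
                        positions[a], positions[b], amp, amap, truth,
                        bias=bias, rng=rng,
                        pixel_pitch_mm=config.pixel_pitch_mm,
                        viewing_distance_cm=pconf.viewing_distance_cm,
                        sites=(sites[a], sites[b]),
                        distances=pair_dists[(a, b)], bounds_um=bounds,
                    )
                    electrodes = (a, b)
                record = TrialRecord(
                    participant_id=pid,
                    electrodes=electrodes,
                    amplitude_x_threshold=float(amp),
                    frequency_hz=float(freq),
                    trial_index=trial,
                    mask_path=None,
                    viewing_distance_cm=pconf.viewing_distance_cm,
                )
                trials.append(CohortTrial(record, mask))
    return Cohort(trials, implants, all_positions, amap, truth, config)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort to disk: manifest CSV, PNG masks, geometry, ground truth."""
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    records = []
    for i, trial in enumerate(cohort.trials):
        rec = trial.record
        rel = f"masks/{rec.participant_id}_{rec.electrode_key.replace('+', '-')}_" \
              f"a{rec.amplitude_x_threshold}_f{rec.frequency_hz}_t{rec.trial_index}.png"
        save_mask(trial.mask, out / rel)
        records.append(dataclasses.replace(rec, mask_path=rel))
    save_manifest(records, out / "manifest.csv")
    for pid, spec in cohort.implants.items():
        save_implant_spec(spec, out / f"implant_{pid}.yaml")
    truth_dict = dataclasses.asdict(cohort.truth)
    with (out / "ground_truth.json").open("w") as fh:
        json.dump(truth_dict, fh, indent=2)
    with (out / "cohort_config.json").open("w") as fh:
        cfg = dataclasses.asdict(cohort.config)
        json.dump(cfg, fh, indent=2, default=str)
    return out
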