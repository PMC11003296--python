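"""Per-participant normalization and trial aggregation.

Raw per-region descriptor rows are converted into analysis-ready data points
through a fixed stage order:

1. aggregate regions within each drawing (sum for paired drawings, mean for
   single-electrode drawings by default);
2. normalize descriptors by each participant's standard-pulse reference
   (mean descriptor over all of that participant's single-electrode drawings
   at 2x threshold, 20 Hz), which cancels individual drawing bias and scale;
3. average across trials of the same electrode/stimulus combination;
4. remove data points any of whose normalized descriptors lies more than
   2.5 SD from the pooled mean (single- and paired-electrode sets filtered
   separately);
5. apply variance-stabilizing power transforms (cube root for area, square
   root for perimeter and axis lengths);
6. z-score the stimulus/neuroanatomical covariates across all participants.

The stage order is recorded in an audit log inside the returned
:class:`NormalizationContext`; permuting outlier removal and the power
transform would change the result, so the order is locked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phoskit.errors import DomainError, ReferencePulseError

DESCRIPTORS = ["area", "perimeter", "major", "minor"]
POWER_EXPONENTS = {"area": 1.0 / 3.0, "perimeter": 0.5, "major": 0.5, "minor": 0.5}
STANDARD_PULSE = {"amplitude": 2.0, "frequency": 20.0}
COVARIATES = ["amplitude", "frequency", "efd_um", "erd_um", "between_um", "along_um"]

GROUP_KEYS = ["participant", "electrode_key", "amplitude", "frequency"]
DRAWING_KEYS = GROUP_KEYS + ["trial"]


@dataclass
class NormalizationContext:
    """Reproducibility record of one pipeline run."""

    references: dict = field(default_factory=dict)
    covariate_stats: dict = field(default_factory=dict)
    dropped_covariates: dict = field(default_factory=dict)
    outlier_threshold_sd: float = 2.5
    power_exponents: dict = field(default_factory=lambda: dict(POWER_EXPONENTS))
    removal_log: list = field(default_factory=list)
    audit: list = field(default_factory=list)
    pre_transform: dict = field(default_factory=dict)

    def as_json(self) -> dict:
        return {
            "references": self.references,
            "covariate_stats": self.covariate_stats,
            "dropped_covariates": self.dropped_covariates,
            "outlier_threshold_sd": self.outlier_threshold_sd,
            "power_exponents": self.power_exponents,
            "removal_log": self.removal_log,
            "audit": self.audit,
        }


def aggregate_drawings(
    region_df: pd.DataFrame,
    *,
    single_mode: str = "mean",
    paired_mode: str = "sum",
) -> pd.DataFrame:
    """Collapse per-region rows into one descriptor vector per drawing.

    Paired-electrode drawings are summed descriptor-wise over their regions
    (accounting for the variable number of perceived phosphenes); single
    drawings default to the per-region mean. ``n_phosphenes`` records the
    region count of each drawing.
    """
    if single_mode not in ("mean", "sum") or paired_mode not in ("mean", "sum"):
        raise ValueError("aggregation modes must be 'mean' or 'sum'")
    df = region_df.copy()
    df["n_electrodes"] = df["electrode_key"].str.count(r"\+") + 1
    out = []
    for mode, sub in [(single_mode, df[df.n_electrodes == 1]), (paired_mode, df[df.n_electrodes == 2])]:
        if sub.empty:
            continue
        grouped = sub.groupby(DRAWING_KEYS, sort=False)
        agg = grouped[DESCRIPTORS].agg(mode)
        agg["n_phosphenes"] = grouped.size()
        agg["n_electrodes"] = grouped["n_electrodes"].first()
        out.append(agg.reset_index())
    return pd.concat(out, ignore_index=True)


def standard_pulse_reference(
    drawing_df: pd.DataFrame,
    *,
    amplitude: float = STANDARD_PULSE["amplitude"],
    frequency: float = STANDARD_PULSE["frequency"],
) -> dict[str, dict[str, float]]:
    """Per-participant mean descriptors over single-electrode standard-pulse drawings."""
    std = drawing_df[
        (drawing_df.n_electrodes == 1)
        & np.isclose(drawing_df.amplitude, amplitude)
        & np.isclose(drawing_df.frequency, frequency)
    ]
    refs: dict[str, dict[str, float]] = {}
    for pid in drawing_df.participant.unique():
        sub = std[std.participant == pid]
        if sub.empty:
            raise ReferencePulseError(
                f"participant {pid!r} has no standard-pulse "
                f"({amplitude}xTh, {frequency} Hz) single-electrode drawings"
            )
        refs[str(pid)] = {d: float(sub[d].mean()) for d in DESCRIPTORS}
    return refs


def normalize_by_reference(drawing_df: pd.DataFrame, references: dict) -> pd.DataFrame:
    df = drawing_df.copy()
    for d in DESCRIPTORS:
        ref = df.participant.astype(str).map(lambda p: references[p][d])
        df[d] = df[d] / ref
    return df


def average_over_trials(drawing_df: pd.DataFrame) -> pd.DataFrame:
    """One data point per (participant, electrode set, amplitude, frequency)."""
    grouped = drawing_df.groupby(GROUP_KEYS, sort=False)
    points = grouped[DESCRIPTORS].mean()
    points["n_phosphenes_mean"] = grouped["n_phosphenes"].mean()
    points["n_trials"] = grouped.size()
    points["n_electrodes"] = grouped["n_electrodes"].first()
    return points.reset_index()


def remove_outliers(
    points: pd.DataFrame,
    *,
    threshold_sd: float = 2.5,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop points whose descriptors deviate > ``threshold_sd`` SD from the mean.

    Means and SDs (n-1 estimator) are computed on the pooled set given; a
    zero-SD column removes nothing. Returns ``(kept, removed)``.
    """
    if threshold_sd <= 0:
        raise DomainError("outlier threshold must be positive")
    columns = columns or DESCRIPTORS
    mask = np.zeros(len(points), dtype=bool)
    for col in columns:
        vals = points[col].to_numpy(dtype=float)
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        if sd == 0 or not np.isfinite(sd):
            continue
        mask |= np.abs(vals - vals.mean()) > threshold_sd * sd
    return points[~mask].reset_index(drop=True), points[mask].reset_index(drop=True)


def power_transform(
    points: pd.DataFrame, exponents: dict[str, float] | None = None
) -> pd.DataFrame:
    """Apply 1/n power transforms (n=3 for area, n=2 otherwise)."""
    exponents = exponents or POWER_EXPONENTS
    df = points.copy()
    for col, e in exponents.items():
        if col not in df:
            continue
        vals = df[col].to_numpy(dtype=float)
        if (vals < 0).any():
            raise DomainError(f"negative {col} value cannot be power-transformed")
        df[col] = vals**e
    return df


def standardize_covariates(
    points: pd.DataFrame, covariates: list[str] | None = None
) -> tuple[pd.DataFrame, dict, dict]:
    """Add z-scored ``<name>_std`` columns for each covariate.

    Statistics are computed across the pooled set (ignoring missing values);
    the raw columns are kept so stimulus keys remain usable for matching.
    Zero-variance covariates get no ``_std`` column and are reported in the
    returned ``dropped`` dict. Returns ``(points, stats, dropped)`` with
    per-covariate (mean, sd).
    """
    covariates = [c for c in (covariates or COVARIATES) if c in points.columns]
    df = points.copy()
    stats: dict[str, tuple[float, float]] = {}
    dropped: dict[str, str] = {}
    for cov in covariates:
        vals = df[cov].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        mean = vals[ok].mean()
        sd = vals[ok].std(ddof=1) if ok.sum() > 1 else 0.0
        if sd == 0 or not np.isfinite(sd):
            dropped[cov] = "zero variance"
            continue
        df[cov + "_std"] = (vals - mean) / sd
        stats[cov] = (float(mean), float(sd))
    return df, stats, dropped


def build_datapoints(
    region_df: pd.DataFrame,
    covariate_df: pd.DataFrame | None = None,
    *,
    single_mode: str = "mean",
    paired_mode: str = "sum",
    outlier_sd: float = 2.5,
    standardize: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, NormalizationContext]:
    """Run the full normalization pipeline on a per-region descriptor table.

    ``region_df`` needs columns ``participant, electrode_key, amplitude,
    frequency, trial`` plus the four descriptors. ``covariate_df`` (optional)
    is keyed by (participant, electrode_key) and contributes anatomical
    covariates (efd_um, erd_um, between_um, along_um). Returns
    ``(single_points, paired_points, context)``.
    """
    ctx = NormalizationContext(outlier_threshold_sd=outlier_sd)
    drawings = aggregate_drawings(region_df, single_mode=single_mode, paired_mode=paired_mode)
    ctx.audit.append(f"aggregate(single={single_mode}, paired={paired_mode})")
    ctx.references = standard_pulse_reference(drawings)
    drawings = normalize_by_reference(drawings, ctx.references)
    ctx.audit.append("normalize_by_standard_pulse")
    points = average_over_trials(drawings)
    ctx.audit.append("average_over_trials")
    single = points[points.n_electrodes == 1].reset_index(drop=True)
    paired = points[points.n_electrodes == 2].reset_index(drop=True)
    kept_s, removed_s = remove_outliers(single, threshold_sd=outlier_sd)
    kept_p, removed_p = remove_outliers(paired, threshold_sd=outlier_sd)
    for tag, removed in [("single", removed_s), ("paired", removed_p)]:
        for _, row in removed.iterrows():
            ctx.removal_log.append(
                {"set": tag, **{k: row[k] for k in GROUP_KEYS}}
            )
    ctx.audit.append(f"remove_outliers(sd={outlier_sd}, removed="
                     f"{len(removed_s)}+{len(removed_p)})")
    ctx.pre_transform = {"single": kept_s.copy(), "paired": kept_p.copy()}
    kept_s = power_transform(kept_s)
    kept_p = power_transform(kept_p)
    ctx.audit.append("power_transform(area^1/3, others^1/2)")
    if covariate_df is not None:
        kept_s = kept_s.merge(covariate_df, on=["participant", "electrode_key"], how="left")
        kept_p = kept_p.merge(covariate_df, on=["participant", "electrode_key"], how="left")
        ctx.audit.append("merge_covariates")
    if standardize:
        n_single = len(kept_s)
        pooled = pd.concat([kept_s, kept_p], ignore_index=True)
        pooled, ctx.covariate_stats, ctx.dropped_covariates = standardize_covariates(pooled)
        kept_s = pooled.iloc[:n_single].reset_index(drop=True)
        kept_p = pooled.iloc[n_single:].reset_index(drop=True)
        ctx.audit.append("standardize_covariates")
    return kept_s, kept_p, ctx
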