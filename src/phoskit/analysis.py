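"""End-to-end cohort analysis: descriptors -> data points -> fitted tables.

Reproduces the structure of the study-style result tables on any cohort
(synthetic or loaded from disk):

* single-electrode shape regressions (per participant OLS + partial
  correlations; all-participant mixed model) against amplitude, frequency,
  electrode-fovea distance, and electrode-retina distance;
* paired-electrode shape regressions (amplitude, EFD, ERD; all paired
  conditions are 20 Hz, so frequency is excluded);
* intercept-free summation regressions of paired descriptors on the sum of
  their single-electrode counterparts, plus a raw-scale gain estimate;
* phosphene-count regressions with the between-/along-axon decomposition
  and the AIC/BIC comparison of the two model families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phoskit import normalize, stats
from phoskit.axon import electrode_fovea_distance, pair_distances
from phoskit.errors import EmptyDrawingError
from phoskit.io import clean_drawing
from phoskit.shapes import describe_drawing
from phoskit.synth import Cohort

SHAPE_PREDICTORS = ["amplitude_std", "frequency_std", "efd_um_std", "erd_um_std"]
PAIRED_SHAPE_PREDICTORS = ["amplitude_std", "efd_um_std", "erd_um_std"]
COUNT_PREDICTORS = ["amplitude_std", "efd_um_std", "erd_um_std"]


def descriptor_table(cohort: Cohort, *, clean: bool = True) -> pd.DataFrame:
    """Per-region descriptor rows for every drawing in a cohort.

    Cleaning uses all trials of the same electrode/stimulus combination as
    siblings; drawings left empty by cleaning are excluded (logged in the
    returned frame's ``attrs["excluded"]``).
    """
    groups: dict[tuple, list] = {}
    for trial in cohort.trials:
        rec = trial.record
        key = (rec.participant_id, rec.electrode_key, rec.amplitude_x_threshold, rec.frequency_hz)
        groups.setdefault(key, []).append(trial)
    rows, excluded = [], []
    for key, trials in groups.items():
        siblings = [t.mask for t in trials]
        for t in trials:
            mask = t.mask
            if clean:
                try:
                    mask = clean_drawing(mask, siblings)
                except EmptyDrawingError:
                    excluded.append({"key": key, "trial": t.record.trial_index})
                    continue
            desc = describe_drawing(mask)
            for region_id, shape in enumerate(desc.phosphenes):
                rows.append(
                    {
                        "participant": t.record.participant_id,
                        "electrode_key": t.record.electrode_key,
                        "amplitude": t.record.amplitude_x_threshold,
                        "frequency": t.record.frequency_hz,
                        "trial": t.record.trial_index,
                        "region_id": region_id,
                        **shape.as_dict(),
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["excluded"] = excluded
    return df


def covariate_table(cohort: Cohort) -> pd.DataFrame:
    """Anatomical covariates per (participant, electrode set).

    Pairs get the mean EFD/ERD of their two electrodes plus the
    between-/along-axon decomposition of their separation.
    """
    keys = sorted({(t.record.participant_id, t.record.electrode_key) for t in cohort.trials})
    rows = []
    for pid, ekey in keys:
        positions = cohort.positions[pid]
        per_el = cohort.implants[pid].per_electrode or {}
        electrodes = ekey.split("+")
        efd = float(np.mean([electrode_fovea_distance(positions[e]) for e in electrodes]))
        erd = float(np.mean([per_el.get(e, {}).get("erd_um", 0.0) for e in electrodes]))
        row = {"participant": pid, "electrode_key": ekey, "efd_um": efd, "erd_um": erd,
               "between_um": np.nan, "along_um": np.nan}
        if len(electrodes) == 2:
            pdist = pair_distances(cohort.axon_map, positions[electrodes[0]],
                                   positions[electrodes[1]], labels=tuple(electrodes))
            row["between_um"] = pdist.between_axon_um
            row["along_um"] = pdist.along_axon_um
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortResults:
    """All fitted tables for one cohort run."""

    single_points: pd.DataFrame
    paired_points: pd.DataFrame
    context: normalize.NormalizationContext
    single_shape_fits: dict = field(default_factory=dict)
    paired_shape_fits: dict = field(default_factory=dict)
    summation_fits: dict = field(default_factory=dict)
    summation_matched: pd.DataFrame | None = None
    summation_gain: dict = field(default_factory=dict)
    count_fits: dict = field(default_factory=dict)
    model_comparisons: dict = field(default_factory=dict)


def _available(df: pd.DataFrame, names: list[str]) -> list[str]:
    return [n for n in names if n in df.columns and df[n].notna().all() and df[n].nunique() > 1]


def _shape_fit_block(points: pd.DataFrame, predictors: list[str]) -> dict:
    """Per-participant OLS + all-participant mixed fits for each descriptor."""
    out: dict = {}
    for pid, sub in points.groupby("participant"):
        preds = _available(sub, predictors)
        fits = {}
        for desc in normalize.DESCRIPTORS:
            try:
                fits[desc] = stats.ols_standardized(sub[desc], sub[preds],
                                                    response=desc, model=str(pid))
            except Exception as exc:  # under-determined sub-designs stay absent
                fits[desc] = exc
        m = len(preds) * len(normalize.DESCRIPTORS)
        _adjust_block(fits, m)
        out[str(pid)] = fits
    preds = _available(points, predictors)
    fits = {}
    for desc in normalize.DESCRIPTORS:
        fits[desc] = stats.mixed_effects(points[desc], points[preds],
                                         points["participant"], response=desc,
                                         model="all")
    _adjust_block(fits, len(preds) * len(normalize.DESCRIPTORS))
    out["all"] = fits
    return out


def _adjust_block(fits: dict, m: int) -> None:
    """Bonferroni-adjust p-values within one table block (family size m)."""
    for fit in fits.values():
        if not isinstance(fit, stats.FitResult):
            continue
        pvals = [p.p for p in fit.predictors]
        adj, star = stats.bonferroni(pvals, m=max(m, len(pvals)))
        for pred, a, s in zip(fit.predictors, adj, star):
            pred.p_adj = float(a)
            pred.stars = s


def estimate_summation_gain(context: normalize.NormalizationContext) -> dict[str, float]:
    """Raw-scale gain per descriptor from intercept-free regression.

    Uses the trial-averaged, normalized but *untransformed* descriptor
    values, so the fitted slope sits on the scale on which the generative
    gain is planted (paired sum ≈ gain × single sum).
    """
    single = context.pre_transform["single"]
    paired = context.pre_transform["paired"]
    fits, matched, _ = stats.summation_regression(paired, single)
    return {d: fit.predictors[0].beta for d, fit in fits.items()}


def run_analysis(cohort: Cohort, *, clean: bool = True) -> CohortResults:
    """Full pipeline: descriptors, data points, and every fitted table."""
    regions = descriptor_table(cohort, clean=clean)
    covariates = covariate_table(cohort)
    single, paired, ctx = normalize.build_datapoints(regions, covariates)
    res = CohortResults(single_points=single, paired_points=paired, context=ctx)

    res.single_shape_fits = _shape_fit_block(single, SHAPE_PREDICTORS)
    if len(paired) >= 8:
        res.paired_shape_fits = _shape_fit_block(paired, PAIRED_SHAPE_PREDICTORS)

        fits, matched, excluded = stats.summation_regression(paired, single)
        _adjust_block(fits, len(fits))
        res.summation_fits = fits
        res.summation_matched = matched
        res.summation_gain = estimate_summation_gain(ctx)

        res.count_fits, res.model_comparisons = count_analysis(paired)
    return res


def count_analysis(paired_points: pd.DataFrame) -> tuple[dict, dict]:
    """Phosphene-count regressions and the axonal model comparison.

    Model A predicts the mean number of perceived phosphenes from the
    along-axon distance plus stimulus/anatomical factors; Model B swaps in
    the between-axon distance. Lower AIC/BIC wins.
    """
    fits: dict = {}
    comparisons: dict = {}
    response = "n_phosphenes_mean"
    for pid, sub in paired_points.groupby("participant"):
        base = _available(sub, COUNT_PREDICTORS)
        full = base + [c for c in ("between_um_std", "along_um_std") if c in sub.columns]
        try:
            fit = stats.ols_standardized(sub[response], sub[full], response=response,
                                         model=str(pid))
            _adjust_block({response: fit}, len(full))
            fits[str(pid)] = fit
            comparisons[str(pid)] = stats.compare_models(
                sub, response, base + ["along_um_std"], base + ["between_um_std"])
        except Exception as exc:
            fits[str(pid)] = exc
    base = _available(paired_points, COUNT_PREDICTORS)
    full = base + ["between_um_std", "along_um_std"]
    fit = stats.mixed_effects(paired_points[response], paired_points[full],
                              paired_points["participant"], response=response, model="all")
    _adjust_block({response: fit}, len(full))
    fits["all"] = fit
    comparisons["all"] = stats.compare_models(
        paired_points, response, base + ["along_um_std"], base + ["between_um_std"],
        groups="participant")
    return fits, comparisons


# ---------------------------------------------------------------------------
# Report rendering


def fits_to_frame(block: dict) -> pd.DataFrame:
    """Flatten a {section: {response: FitResult}} block into a tidy table."""
    rows = []
    for section, fits in block.items():
        items = fits.items() if isinstance(fits, dict) else [(getattr(fits, "response", "?"), fits)]
        for response, fit in items:
            if not isinstance(fit, stats.FitResult):
                continue
            for pred in fit.predictors:
                rows.append(
                    {"section": section, "response": response, "n": fit.n,
                     "predictor": pred.name, "beta": pred.beta, "partial_r": pred.partial_r,
                     "p": pred.p, "p_adj": pred.p_adj, "stars": pred.stars}
                )
    return pd.DataFrame(rows)


def comparisons_to_frame(comparisons: dict) -> pd.DataFrame:
    rows = []
    for section, cmp_ in comparisons.items():
        rows.append(
            {"section": section, "n": cmp_.model_a.n,
             "aic_along": cmp_.model_a.aic, "aic_between": cmp_.model_b.aic,
             "bic_along": cmp_.model_a.bic, "bic_between": cmp_.model_b.bic,
             "delta_aic": cmp_.delta_aic, "delta_bic": cmp_.delta_bic,
             "verdict_aic": cmp_.verdict_aic, "verdict_bic": cmp_.verdict_bic}
        )
    return pd.DataFrame(rows)
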