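"""Out-of-sample bootstrap model assessment.

Individuals (with all their visits) are resampled with replacement to the
original count; the ~36.8% never drawn form the out-of-bag test set. Each
candidate model form is fitted on the in-bag cohort and scored by one-step
prediction RMSE/MAE on both sets, combined with the .632 estimator

    RMSE_632 = 0.632 * RMSE_test + 0.368 * RMSE_train

(0.632 being the expected unique fraction in a bootstrap resample).
Parameter standard errors are the across-replicate standard deviations.
All model forms see identical splits, so comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AGE_COL, ID_COL, LongitudinalCohort
from .estimation import FitConfig, FitResult, _cohort_pair_arrays, fit

__all__ = [
    "bootstrap_resample",
    "prediction_error",
    "assess",
    "compare_models",
    "AssessmentResult",
]

W632, W368 = 0.632, 0.368


def bootstrap_resample(
    cohort: LongitudinalCohort, seed: int | np.random.Generator
) -> tuple[LongitudinalCohort, LongitudinalCohort]:
    """Resample individuals with replacement; out-of-bag = never drawn.

    Duplicated individuals get suffixed ids so the in-bag cohort remains a
    valid cohort (distinct individuals with strictly increasing visit ages).
    """
    if cohort.n_individuals < 1:
        raise ValueError("empty cohort")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    id_arr = cohort.data[ID_COL].to_numpy()
    ids = pd.unique(id_arr)
    n = len(ids)
    draw_idx = rng.integers(0, n, size=n)
    in_mask = np.zeros(n, dtype=bool)
    in_mask[draw_idx] = True
    oob_ids = ids[~in_mask]

    # row slices per individual (data is sorted by id)
    change = np.flatnonzero(id_arr[1:] != id_arr[:-1]) + 1
    bounds = np.concatenate([[0], change, [len(id_arr)]])
    starts, stops = bounds[:-1], bounds[1:]
    row_idx = np.concatenate([np.arange(starts[g], stops[g]) for g in draw_idx])
    sizes = (stops - starts)[draw_idx]
    new_ids = np.array([f"{ids[g]}~{k}" for k, g in enumerate(draw_idx)], dtype=object)
    in_data = cohort.data.iloc[row_idx].reset_index(drop=True)
    in_data[ID_COL] = np.repeat(new_ids, sizes)
    in_events = None
    if cohort.events is not None:
        in_events = cohort.events.loc[ids[draw_idx]].set_axis(new_ids, axis=0)
        in_events.index.name = ID_COL
    in_bag = LongitudinalCohort(
        in_data, list(cohort.biomarker_names), list(cohort.covariate_names),
        in_events, cohort.time_unit,
    )

    oob_data = cohort.data[cohort.data[ID_COL].isin(oob_ids)].reset_index(drop=True)
    oob_events = None if cohort.events is None else cohort.events.loc[
        [i for i in oob_ids if i in cohort.events.index]
    ]
    out_of_bag = LongitudinalCohort(
        oob_data, list(cohort.biomarker_names), list(cohort.covariate_names),
        oob_events, cohort.time_unit,
    )
    return in_bag, out_of_bag


def prediction_error(fit_result: FitResult, cohort: LongitudinalCohort) -> tuple[float, float]:
    """One-step-ahead (RMSE, MAE) over observed biomarker entries.

    Predictors with missing entries are carry-imputed; target entries that
    were missing in the data are excluded (never imputed), so the test score
    cannot leak model-mean imputations.
    """
    from .estimation import impute_carry

    target_mask = cohort.missing_mask()
    work = impute_carry(cohort) if target_mask.any() else cohort
    y = work.biomarker_matrix()
    if np.isnan(y).any():
        y = np.where(np.isnan(y), 0.0, y)
    arr = _cohort_pair_arrays(y, work)
    if len(arr["dt"]) == 0:
        raise ValueError("cohort has no transition pairs")
    p = fit_result.params_observed
    from .estimation import _augment_x

    xa = _augment_x(arr, p.covariate_names)
    mu = xa @ p.Lambda.T
    pred = arr["y_from"] + ((arr["y_from"] - mu) @ p.W.T) * arr["dt"][:, None]
    resid = arr["y_to"] - pred
    keep = ~target_mask[arr["i_to"]]
    r = resid[keep]
    if r.size == 0:
        raise ValueError("no observed target entries")
    return float(np.sqrt(np.mean(r**2))), float(np.mean(np.abs(r)))


@dataclass
class AssessmentResult:
    """Aggregate errors per model form plus per-replicate records."""

    summary: pd.DataFrame  # one row per form: RMSE/MAE train, test, 632
    replicates: pd.DataFrame  # one row per (form, replicate)
    param_se: dict[str, dict[str, np.ndarray]]  # form -> {"W": SE matrix, "Lambda": ...}
    n_boot: int
    n_skipped: int
    seed: int

    def to_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


def _form_label(config: FitConfig) -> str:
    return config.model_form


def assess(
    cohort: LongitudinalCohort,
    configs: list[FitConfig],
    n_boot: int = 100,
    seed: int = 0,
) -> AssessmentResult:
    """Paired bootstrap assessment of one or more model forms."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    labels = [_form_label(c) for c in configs]
    if len(set(labels)) != len(labels):
        labels = [f"{l}#{k}" for k, l in enumerate(labels)]
    rng = np.random.default_rng(seed)
    rec = []
    params_acc: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {l: [] for l in labels}
    n_skipped = 0
    for b in range(n_boot):
        in_bag, oob = bootstrap_resample(cohort, rng)
        if oob.n_individuals == 0:
            n_skipped += 1
            continue
        for label, cfg in zip(labels, configs):
            fr = fit(in_bag, cfg)
            rmse_tr, mae_tr = prediction_error(fr, in_bag)
            rmse_te, mae_te = prediction_error(fr, oob)
            params_acc[label].append((fr.params_observed.W, fr.params_observed.Lambda))
            rec.append(
                {
                    "form": label, "replicate": b,
                    "rmse_train": rmse_tr, "rmse_test": rmse_te,
                    "rmse_632": W632 * rmse_te + W368 * rmse_tr,
                    "mae_train": mae_tr, "mae_test": mae_te,
                    "mae_632": W632 * mae_te + W368 * mae_tr,
                }
            )
    replicates = pd.DataFrame(rec)
    summary = (
        replicates.groupby("form", sort=False)
        .mean(numeric_only=True)
        .drop(columns="replicate")
        .reset_index()
    )
    param_se = {}
    for label in labels:
        Ws = np.array([w for w, _ in params_acc[label]])
        Ls = np.array([l for _, l in params_acc[label]])
        param_se[label] = {"W": Ws.std(axis=0, ddof=1), "Lambda": Ls.std(axis=0, ddof=1)}
    return AssessmentResult(
        summary=summary, replicates=replicates, param_se=param_se,
        n_boot=n_boot, n_skipped=n_skipped, seed=seed,
    )


def compare_models(result: AssessmentResult, metric: str = "rmse_632") -> pd.DataFrame:
    """Rank forms by the .632 error; paired differences with bootstrap SEs.

    A difference is flagged significant when |mean difference| > 2 SE, with
    the SE taken over the paired per-replicate differences.
    """
    reps = result.replicates
    forms = list(reps["form"].unique())
    wide = reps.pivot(index="replicate", columns="form", values=metric)
    if wide.isna().any().any():
        raise ValueError("unpaired replicates between model forms")
    ranking = wide.mean().sort_values()
    rows = []
    for a_i in range(len(forms)):
        for b_i in range(a_i + 1, len(forms)):
            a, b = forms[a_i], forms[b_i]
            d = wide[a] - wide[b]
            se = d.std(ddof=1) / np.sqrt(len(d))
            rows.append(
                {
                    "form_a": a, "form_b": b,
                    "mean_diff": float(d.mean()), "se": float(se),
                    "significant": bool(abs(d.mean()) > 2 * se) if se > 0 else d.mean() != 0,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["ranking"] = list(ranking.index)
    return out
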