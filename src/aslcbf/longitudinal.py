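"""Mixed-model analysis of baseline perfusion and cognitive decline.

The analysis follows the standard longitudinal design for memory-clinic
cohorts: subjects enter if they have at least two MMSE scores spanning at
least one year; the chosen baseline CBF measure is standardized over the
analysis sample and inverted (so positive z means lower perfusion, "per SD
decrease"); and a linear mixed model with random intercept and random slope
on time is fitted:

    MMSE ~ z + time + z:time + covariates,   random: ~ time | subject

Two covariate sets are predefined: "model1" adjusts for age, sex and
education; "model2" additionally for normalized gray-matter volume, medial
temporal atrophy, white-matter hyperintensities, microbleeds and lacunes
(NGMV is dropped when the predictor is already partial-volume corrected).

The z:time interaction is the quantity of interest: the extra annual MMSE
change associated with one SD lower baseline perfusion.  Estimation is
restricted maximum likelihood by default with an unstructured 2x2
random-effects covariance; inference is Wald against a normal reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "MODEL1_COVARIATES",
    "MODEL2_COVARIATES",
    "LMMSpec",
    "apply_inclusion",
    "standardize_invert",
    "CBFDeclineModel",
    "DeclineResults",
    "annual_change",
    "report_tables",
    "cohort_summary",
]

logger = logging.getLogger(__name__)

MODEL1_COVARIATES = ("age_years", "sex", "education")
MODEL2_COVARIATES = MODEL1_COVARIATES + (
    "ngmv_ml",
    "mta",
    "wmh_fazekas",
    "n_microbleeds",
    "n_lacunes",
)


@dataclass(frozen=True)
class LMMSpec:
    """Specification of one mixed-model fit.

    ``measure`` names a baseline CBF column of the cohort table;
    ``covariates`` is "model1", "model2", an explicit sequence of column
    names, or None for the unadjusted model.  ``invert`` flips the
    standardized predictor so higher z means lower perfusion.
    """

    measure: str = "cbf_whole_brain"
    covariates: str | tuple[str, ...] | None = "model1"
    invert: bool = True
    reml: bool = True

    def covariate_columns(self) -> tuple[str, ...]:
        if self.covariates is None:
            return ()
        if self.covariates == "model1":
            return MODEL1_COVARIATES
        if self.covariates == "model2":
            cols = MODEL2_COVARIATES
            if "pvc" in self.measure:
                # volume adjustment is redundant once the predictor is PVC
                cols = tuple(c for c in cols if c != "ngmv_ml")
            return cols
        return tuple(self.covariates)


def apply_inclusion(
    cohort: pd.DataFrame, min_scores: int = 2, min_span_years: float = 1.0
) -> pd.DataFrame:
    """Retain subjects with enough MMSE follow-up for a slope estimate.

    A subject stays if at least ``min_scores`` non-missing MMSE values exist
    and the last visit is at least ``min_span_years`` after the first.
    """
    scored = cohort.dropna(subset=["mmse"])
    g = scored.groupby("subject_id")["visit_time_years"]
    ok = (g.count() >= min_scores) & ((g.max() - g.min()) >= min_span_years)
    keep = ok[ok].index
    out = cohort[cohort["subject_id"].isin(keep)].copy()
    n_in, n_all = len(keep), cohort["subject_id"].nunique()
    logger.info(
        "inclusion filter (>=%d MMSE over >=%g y): %d of %d subjects retained",
        min_scores, min_span_years, n_in, n_all,
    )
    if out.empty:
        raise ValueError(
            f"inclusion filter (>= {min_scores} MMSE scores over >= "
            f"{min_span_years} years) excluded every subject"
        )
    return out


def standardize_invert(values, invert: bool = True) -> np.ndarray:
    """Standardize baseline values to z-scores, optionally sign-inverted.

    With ``invert`` (the default) z = (mean - x) / SD with the sample SD
    (n-1 denominator), so one unit of z is one SD *decrease*: higher z means
    lower perfusion.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("standardization needs at least two distinct values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation: cannot standardize")
    z = (x - x.mean()) / sd
    return -z if invert else z


@dataclass
class DeclineResults:
    """Fitted fixed effects, variance components and fit diagnostics.

    ``params``/``bse``/``pvalues`` are indexed by term name; the predictor
    main effect is ``cbf_z`` and the decline effect ``cbf_z:time``.
    ``varcomp`` holds the random-intercept variance, random-slope variance,
    their covariance and the residual variance.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    varcomp: dict[str, float]
    n_subjects: int
    n_observations: int
    converged: bool
    spec: LMMSpec | None = None
    dropped_subjects: int = 0

    def summary(self) -> str:
        lines = []
        title = "Mixed model: MMSE decline"
        if self.spec is not None:
            title += f" ~ {self.spec.measure} (covariates: {self.spec.covariates})"
        lines.append(title)
        lines.append(
            f"subjects: {self.n_subjects}   observations: {self.n_observations}"
            f"   converged: {self.converged}"
        )
        lines.append(f"{'term':<22}{'beta':>10}{'SE':>9}{'p':>9}")
        for term in self.params.index:
            lines.append(
                f"{term:<22}{self.params[term]:>10.3f}{self.bse[term]:>9.3f}"
                f"{self.pvalues[term]:>9.3g}"
            )
        lines.append(
            "variance components: intercept {var_intercept:.3f}, slope "
            "{var_slope:.3f}, covariance {cov_intercept_slope:.3f}, residual "
            "{var_residual:.3f}".format(**self.varcomp)
        )
        return "\n".join(lines)


def _fit_mixedlm(frame: pd.DataFrame, fixed_terms: list[str], reml: bool):
    """Fit the random-intercept/random-slope model, trying several optimizers."""
    formula = "mmse ~ " + " + ".join(fixed_terms)
    model = smf.mixedlm(formula, frame, groups="subject_id", re_formula="~time")
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = None
        for method in ("lbfgs", "cg", "powell"):
            try:
                fit = model.fit(reml=reml, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if fit.converged:
                break
        if fit is None:
            raise RuntimeError("mixed-model estimation failed for every optimizer")
        converged = bool(fit.converged) and not any(
            issubclass(c.category, ConvergenceWarning) for c in caught
        )
    return fit, converged


def _results_from_fit(fit, converged: bool, frame: pd.DataFrame,
                      spec: LMMSpec | None, dropped: int) -> DeclineResults:
    k = len(fit.fe_params)
    cov_re = np.asarray(fit.cov_re)
    varcomp = {
        "var_intercept": float(cov_re[0, 0]),
        "var_slope": float(cov_re[1, 1]) if cov_re.shape[0] > 1 else 0.0,
        "cov_intercept_slope": float(cov_re[0, 1]) if cov_re.shape[0] > 1 else 0.0,
        "var_residual": float(fit.scale),
    }
    return DeclineResults(
        params=fit.params[:k].copy(),
        bse=fit.bse[:k].copy(),
        pvalues=fit.pvalues[:k].copy(),
        varcomp=varcomp,
        n_subjects=frame["subject_id"].nunique(),
        n_observations=len(frame),
        converged=converged,
        spec=spec,
        dropped_subjects=dropped,
    )


class CBFDeclineModel:
    """Random-intercept/random-slope model of MMSE decline versus baseline CBF.

    Parameters
    ----------
    cohort : DataFrame
        Long-format visit table (one row per visit) that already passed the
        inclusion filter; see :func:`apply_inclusion`.
    spec : LMMSpec
        Which CBF measure, covariate set and estimation mode to use.

    The predictor is the subject's baseline value of ``spec.measure``,
    standardized over the analysis sample after complete-case filtering and
    inverted per SD decrease.  ``fit`` returns :class:`DeclineResults`.
    """

    def __init__(self, cohort: pd.DataFrame, spec: LMMSpec = LMMSpec()):
        self.spec = spec
        covars = spec.covariate_columns()
        needed = ["subject_id", "visit_time_years", "mmse", spec.measure, *covars]
        missing = [c for c in needed if c not in cohort.columns]
        if missing:
            raise ValueError(f"cohort table lacks required columns: {missing}")

        data = cohort[needed].copy()
        n_before = data["subject_id"].nunique()
        # complete-case per model: drop subjects with any missing modeled value
        bad = data[data[needed].isna().any(axis=1)]["subject_id"].unique()
        data = data[~data["subject_id"].isin(bad)]
        self.dropped_subjects = n_before - data["subject_id"].nunique()
        if self.dropped_subjects:
            logger.info(
                "dropped %d subject(s) with missing modeled values (%d remain)",
                self.dropped_subjects, data["subject_id"].nunique(),
            )
        if data.empty:
            raise ValueError("no complete cases left for the requested model")

        # A covariate that is constant across subjects (e.g. a count that is
        # all zero in a small sample) makes the design singular; drop it.
        kept_covars = []
        for col in covars:
            if data[col].nunique() > 1:
                kept_covars.append(col)
            else:
                logger.info("covariate %r is constant in this sample; dropped", col)
        covars = tuple(kept_covars)

        # Subject-level identifiability guard: with few subjects the baseline
        # covariate design can be rank-deficient (covariates are constant
        # within subject, so their joint rank is capped by the subject count).
        # Drop trailing covariates until the subject-level design has full
        # column rank.
        base_rows = data.groupby("subject_id").first()
        while covars:
            design = np.column_stack([
                np.ones(len(base_rows)),
                base_rows[spec.measure].to_numpy(float),
                base_rows[list(covars)].to_numpy(float),
            ])
            if np.linalg.matrix_rank(design) == design.shape[1]:
                break
            logger.info(
                "covariate %r dropped: subject-level design rank-deficient "
                "with %d subjects", covars[-1], len(base_rows),
            )
            covars = covars[:-1]

        baseline = (
            data.sort_values("visit_time_years").groupby("subject_id")[spec.measure].first()
        )
        z = pd.Series(
            standardize_invert(baseline.to_numpy(), invert=spec.invert),
            index=baseline.index,
        )
        frame = data.rename(columns={"visit_time_years": "time"})
        frame["cbf_z"] = frame["subject_id"].map(z)
        self.frame = frame
        self.fixed_terms = ["cbf_z", "time", "cbf_z:time", *covars]

    @classmethod
    def from_dataframe(
        cls,
        cohort: pd.DataFrame,
        measure: str = "cbf_whole_brain",
        covariates: str | tuple[str, ...] | None = "model1",
        invert: bool = True,
        reml: bool = True,
    ) -> "CBFDeclineModel":
        return cls(cohort, LMMSpec(measure, covariates, invert, reml))

    def fit(self) -> DeclineResults:
        fit, converged = _fit_mixedlm(self.frame, self.fixed_terms, self.spec.reml)
        return _results_from_fit(
            fit, converged, self.frame, self.spec, self.dropped_subjects
        )


def annual_change(cohort: pd.DataFrame, reml: bool = True) -> DeclineResults:
    """Unadjusted mean annual MMSE change (fixed effect of time only)."""
    frame = cohort.rename(columns={"visit_time_years": "time"})[
        ["subject_id", "time", "mmse"]
    ].dropna()
    fit, converged = _fit_mixedlm(frame, ["time"], reml)
    return _results_from_fit(fit, converged, frame, None, 0)


def report_tables(
    results: dict[tuple[str, str], DeclineResults],
    strong_p: float = 0.05,
    trend_p: float = 0.06,
) -> pd.DataFrame:
    """Arrange fitted models into a grid of baseline and annual-change effects.

    ``results`` maps (measure, covariate-set label) to a fitted result.  The
    returned frame has one row per measure and, per covariate set, formatted
    ``beta ± SE`` cells for the predictor main effect (estimated baseline
    MMSE difference per SD decrease) and the predictor-by-time interaction
    (estimated extra annual change).  Cells get ``*`` at p <= ``strong_p``
    and a trend dagger at p <= ``trend_p``; missing fits stay empty.
    """
    measures = sorted({m for m, _ in results})
    models = sorted({g for _, g in results})
    rows = {}
    for measure in measures:
        row = {}
        for grp in models:
            res = results.get((measure, grp))
            for term, label in (("cbf_z", "baseline"), ("cbf_z:time", "annual change")):
                col = f"{grp}: {label}"
                if res is None or term not in res.params.index:
                    row[col] = ""
                    continue
                p = res.pvalues[term]
                mark = "*" if p <= strong_p else ("†" if p <= trend_p else "")
                row[col] = f"{res.params[term]:.2f} ± {res.bse[term]:.2f}{mark}"
        rows[measure] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=[
        f"{g}: {lab}" for g in models for lab in ("baseline", "annual change")
    ])


def cohort_summary(cohort: pd.DataFrame) -> pd.Series:
    """Demographics-style summary of a long-format cohort table."""
    base = cohort.sort_values("visit_time_years").groupby("subject_id").first()
    visits = cohort.groupby("subject_id")["visit_time_years"]
    counts = visits.count()
    span = visits.max() - visits.min()
    out = {
        "n_subjects": len(base),
        "n_mmse": int(cohort["mmse"].notna().sum()),
        "age_mean": base["age_years"].mean(),
        "age_sd": base["age_years"].std(),
        "female_pct": 100.0 * (base["sex"] == 1).mean(),
        "education_mean": base["education"].mean(),
        "followup_years_mean": span.mean(),
        "followup_years_sd": span.std(),
        "baseline_mmse_mean": base["mmse"].mean(),
        "baseline_mmse_sd": base["mmse"].std(),
        "visits_median": counts.median(),
        "visits_min": counts.min(),
        "visits_max": counts.max(),
    }
    for col in cohort.columns:
        if col.startswith("cbf_"):
            out[f"{col}_mean"] = base[col].mean()
            out[f"{col}_sd"] = base[col].std()
    return pd.Series(out)
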