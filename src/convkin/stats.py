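"""Mixed-model comparison and Tukey-adjusted contrasts per articulator x feature.

For every articulator (torso, head, hands) and kinematic feature, a null
linear mixed model

    feature ~ time_bin + utterance_duration + (random terms)

is compared against a model of interest that adds the six-level social action
category, both fitted by maximum likelihood (so the likelihood-ratio test is
valid), with a chi-squared test on 2 * (LL_interest - LL_null). The random
structure is chosen by a fallback ladder: nested dyad/participant intercepts
with a per-participant category slope, then dropping the slope, then a
participant-only intercept with and without the slope — the first rung that
converges without a singular fit wins, and the same structure is used for
both models of a comparison. When the omnibus test is significant, all 15
pairwise category contrasts of the estimated marginal means are computed with
covariates held at their observed means, with p-values adjusted by the Tukey
method (studentized range, family of six).

Numerical notes: the random "slope" rung is parameterized as a
single-variance participant x category variance component (the economical
``(1 | participant:category)`` form) rather than a full 6x6 random-slope
covariance. Variance-parameter optimization is warm-started from a simpler
model's estimates, and a null/interest likelihood inversion (which a local
optimizer can produce for nested models) is repaired by refitting the
interest model from the null model's solution; see docs/methods.md.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLMParams

from .datamodel import (
    ANALYSIS_ARTICULATORS,
    ANALYZED_LABELS,
    FEATURES,
    ValidationError,
)

logger = logging.getLogger("convkin")

#: Relative threshold below which a random-effect variance marks a singular fit.
SINGULAR_VARIANCE_RATIO = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """One mixed-model specification (always ML estimation)."""

    dependent: str
    include_category: bool
    random_structure: str  # "dyad_nested" | "participant"
    random_slope: bool

    def __post_init__(self) -> None:
        if self.dependent not in FEATURES:
            raise ValidationError(f"unknown dependent feature {self.dependent!r}")
        if self.random_structure not in ("dyad_nested", "participant"):
            raise ValidationError(f"unknown random structure {self.random_structure!r}")


#: The random-structure fallback ladder, most to least complex.
LADDER: tuple[tuple[str, bool], ...] = (
    ("dyad_nested", True),
    ("dyad_nested", False),
    ("participant", True),
    ("participant", False),
)


@dataclass
class FitResult:
    spec: ModelSpec
    result: object  # MixedLMResults, or None on hard failure
    converged: bool
    singular: bool
    llf: float
    n_fixed: int
    n_obs: int
    category_levels: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return self.converged and not self.singular


@dataclass
class ModelComparison:
    articulator: str
    feature: str
    chi2: float
    df: int
    p_value: float
    random_structure_used: str
    slope_retained: bool
    converged: bool
    n_obs: int = 0


@dataclass
class ContrastResult:
    category_a: str
    category_b: str
    estimate: float
    se: float
    z_ratio: float
    p_unadjusted: float
    p_adjusted: float
    significant: bool


@dataclass
class AnalysisResults:
    comparisons: pd.DataFrame
    contrasts: dict[tuple[str, str], list[ContrastResult]]
    ladder_log: list[dict] = field(default_factory=list)
    alpha: float = 0.05


# -- data preparation ---------------------------------------------------------


def prepare_rows(table: pd.DataFrame, dependent: str) -> pd.DataFrame:
    """Restrict a feature table to analyzable rows for one dependent feature.

    Keeps the six analyzed categories, usable bins, and rows with finite
    dependent and duration values; adds the standardized duration covariate
    and a within-dyad participant label used for nested variance components.
    """
    if dependent not in FEATURES:
        raise ValidationError(f"unknown dependent feature {dependent!r}")
    df = table.loc[
        (~table["excluded"].astype(bool))
        & table["usable"].astype(bool)
        & np.isfinite(table[dependent].astype(float))
        & np.isfinite(table["utterance_duration_ms"].astype(float))
    ].copy()
    if len(df) == 0:
        raise ValidationError(f"no analyzable rows for {dependent!r}")
    levels = [c for c in ANALYZED_LABELS if c in set(df["category"])]
    df["category"] = pd.Categorical(df["category"], categories=levels)
    dur = df["utterance_duration_ms"].astype(float)
    sd = dur.std(ddof=1)
    df["dur_z"] = (dur - dur.mean()) / (sd if sd > 0 else 1.0)
    df["bin_index"] = df["bin_index"].astype(int)
    # participant position within dyad: reusable 2-level label, so nested
    # variance components stay 2 (or 12) columns wide regardless of corpus size
    first = df.groupby("dyad_id")["participant_id"].transform("min")
    df["part_local"] = np.where(df["participant_id"] == first, "p0", "p1")
    return df


def _formulas(spec: ModelSpec) -> tuple[str, str, dict | None]:
    fixed = f"{spec.dependent} ~ C(bin_index) + dur_z"
    if spec.include_category:
        fixed += " + C(category)"
    if spec.random_structure == "dyad_nested":
        groups = "dyad_id"
        vc = {"participant": "0 + C(part_local)"}
        if spec.random_slope:
            vc["slope"] = "0 + C(part_local):C(category)"
    else:
        groups = "participant_id"
        vc = {"slope": "0 + C(category)"} if spec.random_slope else None
    return fixed, groups, vc


# -- fitting ------------------------------------------------------------------


def _vc_names(spec: ModelSpec) -> list[str]:
    _, _, vc = _formulas(spec)
    return list(vc) if vc else []


def _derive_start(source: FitResult, target_spec: ModelSpec) -> MixedLMParams | None:
    """Variance-parameter starting values for one model from another's fit.

    Values are mapped by component name where possible; a component absent
    from the source starts at a small positive fraction of its nearest
    analogue. All values are on the residual-scale-relative scale statsmodels
    optimizes over.
    """
    if source.result is None or not np.isfinite(source.llf):
        return None
    res = source.result
    scale = float(res.scale)
    if not np.isfinite(scale) or scale <= 0:
        return None
    src_re = float(np.atleast_2d(res.cov_re)[0, 0]) / scale
    src_vc = {
        name: float(v) / scale
        for name, v in zip(_vc_names(source.spec), np.atleast_1d(res.vcomp))
    }
    same_groups = source.spec.random_structure == target_spec.random_structure
    re_start = max(src_re if same_groups else src_re / 2.0, 1e-3)
    vcomp = []
    for name in _vc_names(target_spec):
        if name in src_vc:
            vcomp.append(max(src_vc[name], 1e-4))
        elif name == "participant":
            vcomp.append(max(src_re / 2.0, 1e-3))
        else:  # slope component: start near the boundary
            vcomp.append(1e-2)
    return MixedLMParams.from_components(
        cov_re=np.array([[re_start]]), vcomp=np.array(vcomp)
    )


def fit_model(
    rows: pd.DataFrame,
    spec: ModelSpec,
    *,
    start_base: FitResult | None = None,
    retry: bool = True,
) -> FitResult:
    """Fit one mixed model by ML; convergence problems flag, never raise.

    Optimization runs over the variance parameters (fixed effects are
    profiled out). When ``start_base`` is given, its variance estimates seed
    the optimizer; a cold start (and, with ``retry``, a derivative-free
    Powell pass) is attempted as fallback. Among converged attempts the best
    log-likelihood wins.
    """
    df = rows if "dur_z" in rows.columns else prepare_rows(rows, spec.dependent)
    levels = tuple(df["category"].cat.categories)
    formula, groups, vc = _formulas(spec)
    best = None
    best_converged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                formula, data=df, groups=df[groups], re_formula="1", vc_formula=vc
            )
            start = _derive_start(start_base, spec) if start_base is not None else None
            # Powell first: on these profiled-variance surfaces the
            # quasi-Newton methods stall on near-boundary plateaus, while
            # Powell reliably reaches the optimum at comparable cost.
            attempts = []
            if start is not None:
                attempts.append(("powell", start))
            attempts.append(("powell", None))
            if retry:
                attempts.append(("lbfgs", None))
            for method, start_params in attempts:
                try:
                    result = model.fit(
                        reml=False,
                        method=method,
                        maxiter=300,
                        disp=False,
                        start_params=start_params,
                    )
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if not np.isfinite(result.llf):
                    continue
                if best is None or result.llf > best.llf:
                    best = result
                    best_converged = bool(result.converged)
                if bool(result.converged):
                    break  # accept the first successful converged attempt
            if best is not None:
                # quasi-Newton polish from the Powell solution: gradient
                # methods are reliable locally, and the extra digits keep
                # nested-model likelihood differences consistent
                polish_start = MixedLMParams.from_components(
                    cov_re=np.atleast_2d(best.cov_re) / best.scale,
                    vcomp=np.atleast_1d(best.vcomp) / best.scale,
                )
                try:
                    polished = model.fit(
                        reml=False,
                        method="lbfgs",
                        maxiter=100,
                        disp=False,
                        start_params=polish_start,
                    )
                    if np.isfinite(polished.llf) and polished.llf > best.llf:
                        best = polished
                        best_converged = best_converged or bool(polished.converged)
                except (np.linalg.LinAlgError, ValueError):
                    pass
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("fit failed for %s: %s", spec, exc)

    if best is None:
        return FitResult(spec, None, False, False, np.nan, 0, len(df), levels)
    variances = list(np.atleast_1d(np.diag(np.atleast_2d(best.cov_re))))
    variances += list(np.atleast_1d(best.vcomp))
    floor = SINGULAR_VARIANCE_RATIO * float(best.scale)
    singular = any(v < floor for v in variances)
    return FitResult(
        spec=spec,
        result=best,
        converged=best_converged,
        singular=singular,
        llf=float(best.llf),
        n_fixed=int(len(best.fe_params)),
        n_obs=len(df),
        category_levels=levels,
    )


def random_structure_ladder(
    rows: pd.DataFrame, dependent: str
) -> tuple[FitResult | None, int, list[dict]]:
    """Walk the fallback ladder on the model of interest.

    Returns the first rung's fit that converges without a singular fit, the
    rung index (0-based), and a log of rungs tried. Rungs requiring nesting
    are skipped when dyads do not contain two participants. Returns
    (None, -1, log) if every rung fails.
    """
    df = rows if "dur_z" in rows.columns else prepare_rows(rows, dependent)
    nested_possible = df.groupby("dyad_id")["participant_id"].nunique().max() >= 2
    log: list[dict] = []
    for rung, (structure, slope) in enumerate(LADDER):
        if structure == "dyad_nested" and not nested_possible:
            log.append(dict(rung=rung, structure=structure, slope=slope, outcome="skipped"))
            continue
        spec = ModelSpec(dependent, True, structure, slope)
        fit = fit_model(df, spec)
        outcome = (
            "retained" if fit.ok else ("singular" if fit.singular else "not_converged")
        )
        log.append(dict(rung=rung, structure=structure, slope=slope, outcome=outcome))
        if fit.ok:
            return fit, rung, log
    return None, -1, log


# -- model comparison ---------------------------------------------------------


def compare_models(
    null_fit: FitResult,
    interest_fit: FitResult,
    *,
    articulator: str = "",
) -> ModelComparison:
    """Chi-squared likelihood-ratio test of the nested ML fits.

    The two fits must use the same rows and the same random structure; the
    degrees of freedom are the fixed-parameter count difference (5 when only
    the six-level category predictor is added).
    """
    if null_fit.n_obs != interest_fit.n_obs:
        raise ValidationError(
            f"model comparison on mismatched rows: {null_fit.n_obs} vs "
            f"{interest_fit.n_obs}"
        )
    sn, si = null_fit.spec, interest_fit.spec
    if (sn.random_structure, sn.random_slope) != (si.random_structure, si.random_slope):
        raise ValidationError("model comparison across different random structures")
    if sn.dependent != si.dependent:
        raise ValidationError("model comparison across different dependents")
    df_diff = interest_fit.n_fixed - null_fit.n_fixed
    chi2 = max(0.0, 2.0 * (interest_fit.llf - null_fit.llf))
    p = float(sps.chi2.sf(chi2, df_diff)) if df_diff > 0 else 1.0
    if df_diff == 0:
        chi2, p = 0.0, 1.0
    return ModelComparison(
        articulator=articulator,
        feature=si.dependent,
        chi2=chi2,
        df=df_diff,
        p_value=p,
        random_structure_used=si.random_structure,
        slope_retained=si.random_slope,
        converged=null_fit.converged and interest_fit.converged,
        n_obs=interest_fit.n_obs,
    )


def lrt_cell(
    rows: pd.DataFrame, dependent: str, *, articulator: str = ""
) -> tuple[ModelComparison, FitResult | None, list[dict]]:
    """Resolve the random structure and run one null-vs-interest LRT.

    The null model is warm-started from the interest fit's variance
    estimates; if a local optimum still leaves the null above the interest
    model (impossible at the true optima of nested models), the interest
    model is refit from the null solution and the better fit kept.
    """
    df = rows if "dur_z" in rows.columns else prepare_rows(rows, dependent)
    interest_fit, rung, log = random_structure_ladder(df, dependent)
    if interest_fit is None:
        comparison = ModelComparison(
            articulator=articulator,
            feature=dependent,
            chi2=np.nan,
            df=0,
            p_value=np.nan,
            random_structure_used="none",
            slope_retained=False,
            converged=False,
            n_obs=len(df),
        )
        return comparison, None, log
    null_spec = ModelSpec(
        dependent,
        include_category=False,
        random_structure=interest_fit.spec.random_structure,
        random_slope=interest_fit.spec.random_slope,
    )
    null_fit = fit_model(df, null_spec, start_base=interest_fit)
    if null_fit.converged and null_fit.llf > interest_fit.llf + 1e-9:
        repaired = fit_model(df, interest_fit.spec, start_base=null_fit)
        if repaired.converged and repaired.llf > interest_fit.llf:
            interest_fit = repaired
    comparison = compare_models(null_fit, interest_fit, articulator=articulator)
    return comparison, interest_fit, log


# -- post-hoc contrasts -------------------------------------------------------


def _fe_cov(fit: FitResult) -> pd.DataFrame:
    res = fit.result
    cov = res.cov_params()
    names = list(res.fe_params.index)
    return cov.loc[names, names]


def marginal_means(fit: FitResult) -> dict[str, float]:
    """Estimated marginal mean per category, covariates at observed means."""
    if not fit.converged or fit.result is None:
        raise ValidationError("cannot compute marginal means from a failed fit")
    res = fit.result
    names = list(res.fe_params.index)
    exog_mean = np.asarray(res.model.exog).mean(axis=0)
    cat_cols = {i: n for i, n in enumerate(names) if n.startswith("C(category)")}
    base = exog_mean.copy()
    for i in cat_cols:
        base[i] = 0.0
    beta = res.fe_params.to_numpy()
    means = {}
    for level in fit.category_levels:
        x = base.copy()
        col = f"C(category)[T.{level}]"
        if col in names:  # reference level has no column
            x[names.index(col)] = 1.0
        means[level] = float(x @ beta)
    return means


def posthoc_contrasts(
    interest_fit: FitResult, alpha: float = 0.05
) -> list[ContrastResult]:
    """All pairwise category contrasts with Tukey-adjusted p-values.

    Estimates are differences of estimated marginal means (equivalently, of
    the category coefficients, since covariate terms cancel); z-ratios use
    the asymptotic normal fixed-effect covariance, and the familywise
    adjustment uses the studentized range with k groups and infinite df.
    """
    if not interest_fit.converged or interest_fit.result is None:
        raise ValidationError("post-hoc contrasts require a converged interest fit")
    if not interest_fit.spec.include_category:
        raise ValidationError("post-hoc contrasts require the category predictor")
    res = interest_fit.result
    names = list(res.fe_params.index)
    beta = res.fe_params.to_numpy()
    cov = _fe_cov(interest_fit).to_numpy()
    levels = interest_fit.category_levels
    k = len(levels)

    def coef_vector(level: str) -> np.ndarray:
        c = np.zeros(len(names))
        col = f"C(category)[T.{level}]"
        if col in names:
            c[names.index(col)] = 1.0
        return c

    out: list[ContrastResult] = []
    for a, b in itertools.combinations(levels, 2):
        c = coef_vector(a) - coef_vector(b)
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        z = est / se if se > 0 else np.nan
        p_unadj = float(2.0 * sps.norm.sf(abs(z)))
        p_adj = float(
            np.clip(sps.studentized_range.sf(np.sqrt(2.0) * abs(z), k, np.inf), 0.0, 1.0)
        )
        out.append(
            ContrastResult(
                category_a=a,
                category_b=b,
                estimate=est,
                se=se,
                z_ratio=z,
                p_unadjusted=p_unadj,
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    return out


def contrasts_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in contrasts])


# -- full grid ----------------------------------------------------------------


def run_full_analysis(
    table: pd.DataFrame,
    alpha: float = 0.05,
    features: tuple[str, ...] = FEATURES,
) -> AnalysisResults:
    """Run the articulator x feature analysis grid on a feature table.

    For each of the articulators present and each feature: resolve the random
    structure on the model of interest, fit the null model with the same
    structure, compare by LRT, and compute Tukey-adjusted pairwise contrasts
    when the omnibus test is significant at ``alpha``. Cells whose every
    ladder rung fails are reported with ``converged=False``.
    """
    comparisons: list[ModelComparison] = []
    contrasts: dict[tuple[str, str], list[ContrastResult]] = {}
    ladder_log: list[dict] = []
    present = [a for a in ANALYSIS_ARTICULATORS if a in set(table["articulator"])]
    for articulator in ANALYSIS_ARTICULATORS:
        if articulator not in present:
            logger.warning(
                "articulator %r missing from feature table; skipped", articulator
            )
    for articulator in present:
        sub = table[table["articulator"] == articulator]
        for feature in features:
            try:
                rows = prepare_rows(sub, feature)
            except ValidationError as exc:
                logger.warning("%s/%s: %s", articulator, feature, exc)
                continue
            comparison, interest_fit, log = lrt_cell(
                rows, feature, articulator=articulator
            )
            for entry in log:
                ladder_log.append(dict(articulator=articulator, feature=feature, **entry))
            comparisons.append(comparison)
            if (
                interest_fit is not None
                and comparison.converged
                and comparison.p_value < alpha
            ):
                contrasts[(articulator, feature)] = posthoc_contrasts(
                    interest_fit, alpha=alpha
                )
    frame = pd.DataFrame([vars(c) for c in comparisons])
    return AnalysisResults(
        comparisons=frame, contrasts=contrasts, ladder_log=ladder_log, alpha=alpha
    )
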