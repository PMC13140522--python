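"""Statistical stage: paired hemisphere comparisons, FDR adjustment and
linear mixed-effects models of band-averaged phase shift.

The mixed models have a subject random intercept and fixed effects built
from hemisphere, patient covariates, time segment and their interactions,
optionally including the short-separation-channel TFA phase as a nuisance
regressor for extracerebral contamination.  Estimation is REML via
statsmodels; inference uses Wald t/F statistics with a between-within
denominator degrees-of-freedom approximation (documented in the methods
note): terms varying within subject use n_obs − n_subjects − q_within,
terms constant within subject use n_subjects − q_between.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class PairedTestResult:
    test: str  # "paired-t" or "wilcoxon"
    statistic: float
    pvalue: float
    estimate: float  # mean (t) or median (wilcoxon) paired difference
    n_pairs: int
    normality_p: float


class SmallSampleError(ValueError):
    """A categorical fixed effect has a level with too few observations."""


def paired_side_test(
    table: pd.DataFrame,
    measure: str = "phase_deg",
    segment: str | None = None,
    band: str | None = None,
    normality_alpha: float = 0.05,
) -> PairedTestResult:
    """Side-to-side (ischaemic − contralateral) paired comparison.

    Per-subject differences are screened for normality (Shapiro–Wilk at
    ``normality_alpha``); a paired t-test is used when the screen passes,
    otherwise the Wilcoxon signed-rank test.
    """
    df = table
    if segment is not None:
        df = df[df["segment"] == segment]
    if band is not None and "band" in df.columns:
        df = df[df["band"] == band]
    wide = df.pivot_table(index="subject_id", columns="hemisphere", values=measure)
    if "ischaemic" not in wide.columns or "contralateral" not in wide.columns:
        raise ValueError("both hemispheres required for a paired test")
    wide = wide.dropna()
    diffs = (wide["ischaemic"] - wide["contralateral"]).to_numpy()
    if len(diffs) < 3:
        raise ValueError("fewer than 3 complete pairs")
    if np.ptp(diffs) == 0:
        # degenerate: identical difference in every subject; a nonzero
        # constant shift is evidence at machine precision
        est = float(diffs[0])
        p = 1.0 if est == 0 else 0.0
        return PairedTestResult("paired-t", np.inf if est else 0.0, p, est, len(diffs), 1.0)
    norm_p = float(sps.shapiro(diffs).pvalue)
    if norm_p >= normality_alpha:
        res = sps.ttest_rel(wide["ischaemic"], wide["contralateral"])
        return PairedTestResult(
            "paired-t", float(res.statistic), float(res.pvalue),
            float(np.mean(diffs)), len(diffs), norm_p,
        )
    res = sps.wilcoxon(diffs)
    return PairedTestResult(
        "wilcoxon", float(res.statistic), float(res.pvalue),
        float(np.median(diffs)), len(diffs), norm_p,
    )


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class FixedEffect:
    name: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    tvalue: float
    df: float
    pvalue: float


@dataclass
class InteractionTest:
    terms: list[str]
    fvalue: float
    df_num: int
    df_den: float
    pvalue: float


@dataclass
class LmmFit:
    formula: str
    fixed_effects: dict[str, FixedEffect]
    interaction_tests: dict[str, InteractionTest]
    var_subject: float
    var_residual: float
    marginal_r2: float
    conditional_r2: float
    aic: float
    n_obs: int
    n_subjects: int
    converged: bool
    warnings: list[str] = field(default_factory=list)


class ConvergenceError(RuntimeError):
    pass


def _check_level_counts(table: pd.DataFrame, columns: list[str], min_count: int) -> None:
    for col in columns:
        if col not in table.columns:
            continue
        s = table[col]
        if s.dtype == object or s.dtype == bool or str(s.dtype) == "category":
            counts = s.value_counts()
            bad = counts[counts < min_count]
            if len(bad):
                raise SmallSampleError(
                    f"fixed effect {col!r} has levels below {min_count} "
                    f"observations: {dict(bad)}"
                )


def fit_phase_lmm(
    table: pd.DataFrame,
    fixed: str,
    outcome: str = "phase_deg",
    group: str = "subject_id",
    include_ss: bool = True,
    min_level_count: int = 3,
    on_nonconvergence: str = "warn",
) -> LmmFit:
    """REML linear mixed model of ``outcome`` with a subject random intercept.

    Parameters
    ----------
    fixed : patsy formula right-hand side, e.g. ``"hemisphere * etco2"`` or
        ``"hemisphere + segment * independence"``.
    include_ss : append the short-separation phase regressor
        (``ss_phase_deg``) to the fixed effects if present in the table.
    min_level_count : refuse categorical fixed effects with any level below
        this many observations (guardrail for tiny clinical strata).
    on_nonconvergence : ``"warn"`` records a warning in the fit, ``"raise"``
        raises :class:`ConvergenceError`.
    """
    table = table.reset_index(drop=True)
    if table[group].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if table.groupby(group).size().max() < 2:
        raise ValueError(
            "no repeated measures: at most one row per subject, the subject "
            "random intercept is unidentifiable"
        )
    rhs = fixed
    if include_ss and "ss_phase_deg" in table.columns and "ss_phase_deg" not in fixed:
        rhs = f"{fixed} + ss_phase_deg"
    term_cols = [c for c in table.columns if c in rhs]
    _check_level_counts(table, term_cols, min_level_count)

    formula = f"{outcome} ~ {rhs}"
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(formula, data=table, groups=table[group])
        result = model.fit(reml=True)
    conv_msgs = [str(w.message) for w in caught if issubclass(w.category, ConvergenceWarning)]
    converged = bool(getattr(result, "converged", True)) and not any(
        "did not converge" in m.lower() for m in conv_msgs
    )
    if not converged and on_nonconvergence == "raise":
        raise ConvergenceError("mixed model did not converge: " + "; ".join(conv_msgs))

    exog = model.exog
    names = model.exog_names
    groups_arr = table[group].to_numpy()
    n_obs = len(table)
    n_subj = table[group].nunique()

    # between-within df: a column is "between" if constant within every subject
    is_between = {}
    gb = pd.DataFrame(exog, columns=names).groupby(groups_arr)
    within_var = gb.var(ddof=0).max()
    for nm in names:
        is_between[nm] = bool(within_var[nm] < 1e-12)
    q_between = sum(is_between.values())  # includes intercept
    q_within = len(names) - q_between
    df_between = max(n_subj - q_between, 1)
    df_within = max(n_obs - n_subj - q_within, 1)

    fe_params = result.fe_params
    cov = result.cov_params().iloc[: len(names), : len(names)]
    fixed_effects: dict[str, FixedEffect] = {}
    for nm in names:
        est = float(fe_params[nm])
        se = float(np.sqrt(cov.loc[nm, nm]))
        ddf = df_between if is_between[nm] else df_within
        tval = est / se if se > 0 else np.inf
        pval = float(2 * sps.t.sf(abs(tval), ddf))
        fixed_effects[nm] = FixedEffect(
            name=nm,
            estimate=est,
            se=se,
            ci_low=est - 1.96 * se,
            ci_high=est + 1.96 * se,
            tvalue=float(tval),
            df=float(ddf),
            pvalue=pval,
        )

    # joint Wald F-test per interaction family (terms sharing a ':' stem)
    interaction_tests: dict[str, InteractionTest] = {}
    stems: dict[str, list[str]] = {}
    for nm in names:
        if ":" in nm:
            stem = ":".join(
                part.split("[")[0] for part in nm.split(":")
            )
            stems.setdefault(stem, []).append(nm)
    beta = fe_params.to_numpy()
    for stem, terms in stems.items():
        idx = [names.index(t) for t in terms]
        b = beta[idx]
        v = cov.to_numpy()[np.ix_(idx, idx)]
        try:
            stat = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError:
            continue
        q = len(idx)
        fval = stat / q
        ddf = df_within if any(not is_between[t] for t in terms) else df_between
        interaction_tests[stem] = InteractionTest(
            terms=terms,
            fvalue=fval,
            df_num=q,
            df_den=float(ddf),
            pvalue=float(sps.f.sf(fval, q, ddf)),
        )

    var_subj = float(result.cov_re.iloc[0, 0])
    var_resid = float(result.scale)
    fitted_fixed = exog @ beta
    var_fixed = float(np.var(fitted_fixed))
    denom = var_fixed + var_subj + var_resid
    marg_r2 = var_fixed / denom if denom > 0 else np.nan
    cond_r2 = (var_fixed + var_subj) / denom if denom > 0 else np.nan

    return LmmFit(
        formula=formula,
        fixed_effects=fixed_effects,
        interaction_tests=interaction_tests,
        var_subject=var_subj,
        var_residual=var_resid,
        marginal_r2=marg_r2,
        conditional_r2=cond_r2,
        aic=float(result.aic) if result.aic is not None else np.nan,
        n_obs=n_obs,
        n_subjects=n_subj,
        converged=converged,
        warnings=conv_msgs,
    )
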