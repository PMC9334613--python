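"""Statistical analyses on coherence tables.

Two preset beta-GLMM analyses mirror the study design:

* control analysis — ``wtc ~ pairing * condition * region`` with dyad-level
  random effects, comparing original against random (pseudo-dyad) pairings;
* main analysis — ``wtc ~ condition * region`` on original pairs only
  (HbR by default, which is the chromophore the control analysis validates).

Random-effect structure starts from slopes for the fixed terms and is
reduced in a fixed order (interaction slopes first, then main-effect slopes,
then intercept-only) until the fit converges, recording the trail.  Effects
are tested with likelihood-ratio tests of nested fits; post-hoc pairwise
contrasts use estimated marginal means (equal-weight averaging on the link
scale) with Tukey studentized-range adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats

from .glmm import BetaMixedModel, BetaMixedResults, FitError, lr_test


@dataclass
class ModelSpec:
    """A fixed-effects formula plus the random-structure reduction trail."""

    formula: str
    re_trail: list[str] = field(default_factory=lambda: ["1"])
    groups: str = "dyad"


def control_spec(include_region: bool = True, random_slopes: bool = False) -> ModelSpec:
    """Original-vs-random pairing analysis specification."""
    if include_region:
        formula = "wtc_value ~ pairing * condition * region"
        trail = (
            [
                "1 + pairing * condition * region",
                "1 + (pairing + condition + region) ** 2",
                "1 + pairing + condition + region",
                "1",
            ]
            if random_slopes
            else ["1"]
        )
    else:
        formula = "wtc_value ~ pairing * condition"
        trail = (
            ["1 + pairing * condition", "1 + pairing + condition", "1"]
            if random_slopes
            else ["1"]
        )
    return ModelSpec(formula, trail)


def main_spec(random_slopes: bool = False) -> ModelSpec:
    """Condition-by-region analysis on original pairs."""
    trail = (
        ["1 + condition * region", "1 + condition + region", "1"]
        if random_slopes
        else ["1"]
    )
    return ModelSpec("wtc_value ~ condition * region", trail)


def fit_beta_glmm(
    table: pd.DataFrame, spec: ModelSpec, compute_se: bool = True,
    maxiter: int = 500,
) -> BetaMixedResults:
    """Fit the beta GLMM, reducing random slopes until convergence.

    The reduction trail (which structures were attempted) is recorded on the
    returned results.
    """
    trail_log: list[str] = []
    last_exc: Exception | None = None
    for re_formula in spec.re_trail:
        trail_log.append(re_formula)
        try:
            model = BetaMixedModel.from_formula(
                spec.formula, table, groups=spec.groups, re_formula=re_formula
            )
            res = model.fit(compute_se=compute_se, maxiter=maxiter)
        except (np.linalg.LinAlgError, ValueError, FitError) as e:
            last_exc = e
            continue
        if res.converged or not compute_se:
            res.reduction_trail = list(trail_log)
            return res
    if last_exc is not None:
        raise FitError(f"no random structure converged: {last_exc}")
    res.reduction_trail = list(trail_log)
    return res


# ---------------------------------------------------------------------------
# likelihood-ratio effect tests


def _formula_without_factor(formula: str, factor: str) -> str:
    """Remove a factor and every interaction containing it from a formula."""
    lhs, rhs = formula.split("~")
    from patsy import ModelDesc

    desc = ModelDesc.from_formula(formula)
    keep = []
    for term in desc.rhs_termlist:
        names = {f.name() for f in term.factors}
        if factor not in names:
            keep.append(term)
    rhs_parts = []
    has_intercept = any(len(t.factors) == 0 for t in keep)
    for t in keep:
        if t.factors:
            rhs_parts.append(":".join(f.name() for f in t.factors))
    rhs_s = " + ".join(rhs_parts) if rhs_parts else "1"
    if not has_intercept:
        rhs_s = "0 + " + rhs_s
    return f"{lhs.strip()} ~ {rhs_s}"


def _formula_without_term(formula: str, term: str) -> str:
    """Remove one interaction term and all higher-order terms containing it."""
    from patsy import ModelDesc

    target = set(term.split(":"))
    desc = ModelDesc.from_formula(formula)
    keep = []
    for t in desc.rhs_termlist:
        names = {f.name() for f in t.factors}
        if target <= names:
            continue
        keep.append(t)
    lhs = formula.split("~")[0].strip()
    parts = [":".join(f.name() for f in t.factors) for t in keep if t.factors]
    rhs = " + ".join(parts) if parts else "1"
    return f"{lhs} ~ {rhs}"


def lr_effect(
    table: pd.DataFrame,
    spec: ModelSpec,
    effect: str,
    *,
    full_fit: BetaMixedResults | None = None,
) -> dict:
    """LR test of one effect (a factor name or interaction like "a:b").

    The reduced model drops the effect together with every higher-order
    interaction that contains it (marginality-respecting), and both models
    share the random structure the full fit converged with.
    """
    if full_fit is None:
        full_fit = fit_beta_glmm(table, spec, compute_se=False)
    re_used = full_fit.reduction_trail[-1] if full_fit.reduction_trail else spec.re_trail[-1]
    if ":" in effect:
        reduced_formula = _formula_without_term(spec.formula, effect)
    else:
        reduced_formula = _formula_without_factor(spec.formula, effect)
    reduced = fit_beta_glmm(
        table, ModelSpec(reduced_formula, [re_used], spec.groups), compute_se=False
    )
    chi2, df, p = lr_test(full_fit, reduced)
    return {"effect": effect, "chi2": chi2, "df": df, "p": p,
            "full": full_fit, "reduced": reduced}


def wald_effect(fit: BetaMixedResults, effect: str) -> dict:
    """Wald chi-square test of all coefficients belonging to one effect."""
    cov = fit.cov_params()
    target = set(effect.split(":"))
    cols = []
    for i, name in enumerate(fit.params.index):
        terms = {p.split("[")[0].replace("C(", "").rstrip(")") for p in name.split(":")}
        if terms == target:
            cols.append(i)
    if not cols:
        raise ValueError(f"effect {effect!r} not found among fitted terms")
    b = fit.params.values[cols]
    V = cov.values[np.ix_(cols, cols)]
    chi2 = float(b @ np.linalg.solve(V, b))
    df = len(cols)
    return {"effect": effect, "chi2": chi2, "df": df,
            "p": float(stats.chi2.sf(chi2, df))}


# ---------------------------------------------------------------------------
# estimated marginal means and Tukey contrasts


def _grid(model: BetaMixedModel) -> pd.DataFrame:
    if model._fe_design_info is None or model._data is None:
        raise ValueError("contrasts require a formula-built model")
    levels = {}
    numeric = {}
    for f, info in model._fe_design_info.factor_infos.items():
        name = f.name()
        if info.type == "categorical":
            levels[name] = list(info.categories)
        else:
            try:
                numeric[name] = float(np.mean(model._data.eval(name)))
            except Exception:
                numeric[name] = float(np.mean(model._data[name]))
    if not levels:
        raise ValueError("model has no categorical factors")
    idx = pd.MultiIndex.from_product(levels.values(), names=levels.keys())
    grid = idx.to_frame(index=False)
    for name, v in numeric.items():
        grid[name] = v
    return grid


def emmeans_contrasts(
    fit: BetaMixedResults,
    factor: str,
    by: str | None = None,
    adjust: str = "tukey",
) -> pd.DataFrame:
    """All pairwise contrasts of a factor's estimated marginal means.

    Marginal means are equal-weight averages of the linear predictor over
    the levels of the other factors; with ``by`` given, contrasts are formed
    within each level of the conditioning factor.  ``adjust="tukey"`` uses
    the studentized-range convention (which reduces to the unadjusted test
    when the factor has two levels).
    """
    model = fit.model
    grid = _grid(model)
    if factor not in grid.columns:
        raise ValueError(f"factor {factor!r} not in the model")
    if by is not None and by not in grid.columns:
        raise ValueError(f"conditioning factor {by!r} not in the model")
    X = build_design_matrices([model._fe_design_info], grid)[0]
    X = np.asarray(X)
    cov = fit.cov_params().values
    beta = fit.params.values
    df = fit.df_resid

    lev = list(dict.fromkeys(grid[factor]))
    k = len(lev)
    by_levels = list(dict.fromkeys(grid[by])) if by is not None else [None]
    rows = []
    for bl in by_levels:
        sub = np.ones(len(grid), bool) if bl is None else (grid[by] == bl).values
        L = {}
        for l in lev:
            m = sub & (grid[factor] == l).values
            L[l] = X[m].mean(axis=0)
        for i in range(k):
            for j in range(i + 1, k):
                c = L[lev[i]] - L[lev[j]]
                est = float(c @ beta)
                se = float(np.sqrt(c @ cov @ c))
                t = est / se
                p_raw = float(2 * stats.t.sf(abs(t), df))
                if adjust == "tukey" and k > 2:
                    p_adj = float(
                        stats.studentized_range.sf(abs(t) * np.sqrt(2), k, df)
                    )
                    p_adj = min(1.0, max(p_adj, p_raw))
                else:
                    p_adj = p_raw
                rows.append(
                    {
                        "contrast": f"{lev[i]} - {lev[j]}",
                        "by": bl,
                        "estimate": est,
                        "se": se,
                        "t": t,
                        "df": df,
                        "p_unadj": p_raw,
                        "p_adj": p_adj,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariate models


def covariate_models(
    table: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_names: list[str],
    *,
    base_formula: str = "wtc_value ~ condition * region",
    re_trail: list[str] | None = None,
    on: list[str] | None = None,
    compute_se: bool = True,
) -> BetaMixedResults:
    """Refit the beta GLMM with per-dyad covariates as fixed effects.

    ``covariates`` is joined on dyad (and condition when present); missing
    matches or zero-variance covariates raise immediately.
    """
    on = on or [c for c in ("dyad", "condition") if c in covariates.columns]
    merged = table.merge(covariates, on=on, how="left", validate="many_to_one")
    for name in covariate_names:
        if merged[name].isna().any():
            bad = sorted(merged.loc[merged[name].isna(), "dyad"].unique())
            raise ValueError(f"covariate {name!r} missing for dyads {bad}")
        if np.var(merged[name]) == 0:
            raise np.linalg.LinAlgError(
                f"covariate {name!r} has zero variance (singular design)"
            )
    formula = base_formula + " + " + " + ".join(covariate_names)
    spec = ModelSpec(formula, re_trail or ["1"])
    return fit_beta_glmm(merged, spec, compute_se=compute_se)
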