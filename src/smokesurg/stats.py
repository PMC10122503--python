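"""Risk-factor statistics: odds ratios, logistic models, variable importance.

Unadjusted odds ratios come from 2x2 contingency tables with Wald
confidence intervals, ``exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`` — the
same formula a saturated two-group logistic model yields, which the test
suite verifies to numerical precision.  Adjusted models are maximum-
likelihood logistic regressions (IRLS, via statsmodels GLM) on a
treatment-coded design with declared reference levels (never-smoker,
female, ASA I, Charlson band 0).

Relative variable importance is reported two ways, as in the source
analysis: the partial Wald chi-squared of each variable's coefficient
block, X = bᵀV_b⁻¹b, expressed as a percentage share of the total across
variables; and the mean absolute Shapley value of each variable on the
log-odds scale.  For an additive linear predictor the Shapley value has the
closed form φ_j(i) = Σ_{k∈group j} β_k (x_ik − x̄_k) (dummy columns grouped
per variable, baseline = in-sample covariate means); a seeded Monte-Carlo
permutation estimator of the same quantity is provided for cross-checking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# 2x2 odds ratios

@dataclass(frozen=True)
class ContingencyTable2x2:
    cases_exposed: int
    noncases_exposed: int
    cases_ref: int
    noncases_ref: int

    def __post_init__(self):
        if min(
            self.cases_exposed, self.noncases_exposed,
            self.cases_ref, self.noncases_ref,
        ) < 0:
            raise ValueError("contingency counts must be non-negative")

    @classmethod
    def from_marginals(
        cls, cases_exposed: int, n_exposed: int, cases_ref: int, n_ref: int
    ) -> "ContingencyTable2x2":
        return cls(
            cases_exposed,
            n_exposed - cases_exposed,
            cases_ref,
            n_ref - cases_ref,
        )


class OddsRatioResult(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float


def odds_ratio_2x2(table: ContingencyTable2x2, z: float = Z95) -> OddsRatioResult:
    """Odds ratio with Wald 95% CI; requires all four cells positive."""
    a, b = table.cases_exposed, table.noncases_exposed
    c, d = table.cases_ref, table.noncases_ref
    if min(a, b, c, d) == 0:
        raise ValueError(
            "odds ratio undefined with a zero cell; collapse categories or "
            "use exact/penalized methods instead"
        )
    log_or = float(np.log((a / b) / (c / d)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return OddsRatioResult(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        log_or=log_or,
        se_log_or=se,
    )


# ---------------------------------------------------------------------------
# model specification and design construction

@dataclass(frozen=True)
class Covariate:
    name: str
    kind: str  # "continuous" | "categorical"
    reference: str | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValueError(f"categorical covariate {self.name} needs a reference")


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    covariates: tuple[Covariate, ...]

    def __post_init__(self):
        names = [c.name for c in self.covariates]
        if len(names) != len(set(names)):
            raise ValueError("duplicate covariate names")


def default_model_spec(outcome: str = "overall", adjusted: bool = True) -> ModelSpec:
    """Smoking status (ref never) plus, if adjusted, age/sex/ASA/CCI band."""
    covs = [Covariate("smoking_status", "categorical", "never")]
    if adjusted:
        covs += [
            Covariate("age_at_surgery", "continuous"),
            Covariate("sex", "categorical", "female"),
            Covariate("asa_class", "categorical", "1"),
            Covariate("cci_band", "categorical", "0"),
        ]
    return ModelSpec(outcome=outcome, covariates=tuple(covs))


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, dict[str, list[str]], pd.Index]:
    """Treatment-coded design matrix with intercept.

    Returns (X, groups, kept_index); rows with any missing covariate are
    dropped (complete-case) and reported via the index.  Dummy columns are
    named ``var[level]`` with the declared reference level omitted.
    """
    cols = [c.name for c in spec.covariates]
    sub = data[cols].copy()
    kept = sub.dropna().index
    sub = sub.loc[kept]

    pieces = {"const": pd.Series(1.0, index=kept)}
    groups: dict[str, list[str]] = {}
    for cov in spec.covariates:
        if cov.kind == "continuous":
            pieces[cov.name] = sub[cov.name].astype(float)
            groups[cov.name] = [cov.name]
        else:
            values = sub[cov.name].astype(str)
            levels = sorted(set(values))
            ref = str(cov.reference)
            if ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} of {cov.name} absent from data"
                )
            groups[cov.name] = []
            for level in levels:
                if level == ref:
                    continue
                col = f"{cov.name}[{level}]"
                pieces[col] = (values == level).astype(float)
                groups[cov.name].append(col)
    X = pd.DataFrame(pieces, index=kept)
    return X, groups, kept


def collapse_sparse_levels(
    values,
    outcome,
    ordered_levels: Sequence[str],
    min_count: int = 50,
    min_events: int = 5,
) -> pd.Series:
    """Merge sparse upper levels of an ordered categorical downward.

    Walking from the top, a level group is merged into the next lower one
    until it holds at least ``min_count`` rows and ``min_events`` events and
    non-events — the usual guard against quasi-complete separation of thin
    ordinal bands (ASA class, Charlson bands) in small samples.  Merged
    groups reaching the top level are labeled ``>=x``; the bottom group
    keeps its original label so declared reference levels stay valid.
    """
    values = pd.Series(values).astype(str).reset_index(drop=True)
    y = np.asarray(outcome, dtype=bool)
    levels = [lv for lv in ordered_levels if (values == lv).any()]
    groups = [[lv] for lv in levels]
    while len(groups) > 1:
        top = groups[-1]
        mask = values.isin(top)
        n, ev = int(mask.sum()), int(y[mask].sum())
        if n >= min_count and ev >= min_events and (n - ev) >= min_events:
            break
        merged = groups.pop()
        groups[-1] = groups[-1] + merged

    def label(group):
        if len(group) == 1:
            return group[0]
        if group[0] == ordered_levels[0]:
            return group[0] if len(groups) == 1 else group[0]
        first = group[0].lstrip(">=")
        return f">={first}" if group[-1] == levels[-1] else "-".join(group)

    mapping = {lv: label(g) for g in groups for lv in g}
    return values.map(mapping)


# ---------------------------------------------------------------------------
# logistic fit

class SeparationError(RuntimeError):
    pass


@dataclass
class LogisticModelFit:
    """Coefficients, covariance and likelihoods of one fitted logistic model."""

    params: pd.Series
    cov: pd.DataFrame
    llf: float
    llnull: float
    n: int
    converged: bool
    groups: Mapping[str, list[str]]
    spec: ModelSpec
    n_dropped_missing: int = 0
    design: pd.DataFrame | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)

    def odds_ratios(self, z: float = Z95) -> pd.DataFrame:
        se = pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)
        return pd.DataFrame(
            {
                "odds_ratio": np.exp(self.params),
                "ci_low": np.exp(self.params - z * se),
                "ci_high": np.exp(self.params + z * se),
            }
        )


def fit_logistic(
    data: pd.DataFrame,
    outcomes: Sequence[bool] | pd.Series,
    spec: ModelSpec,
    keep_design: bool = True,
) -> LogisticModelFit:
    """Maximum-likelihood logistic regression via IRLS.

    Rows with missing covariates are dropped first and counted.  Raises
    :class:`SeparationError` when a coefficient diverges (quasi-complete
    separation) and ``RuntimeError`` on non-convergence.
    """
    y_all = pd.Series(np.asarray(outcomes, dtype=float), index=data.index)
    X, groups, kept = build_design(data, spec)
    y = y_all.loc[kept].to_numpy()
    if len(X) <= X.shape[1]:
        raise ValueError("fewer rows than parameters")

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = model.fit(maxiter=50, tol=1e-10)
        except PerfectSeparationWarning as exc:
            raise SeparationError(
                f"perfect separation detected while fitting {spec.outcome!r}: {exc}"
            ) from None
    if not res.converged:
        raise RuntimeError(
            f"IRLS failed to converge in 50 iterations (deviance {res.deviance:.3g})"
        )
    big = res.params.drop(labels=["const"]).abs()
    if (big > 15).any():
        raise SeparationError(
            f"perfect separation suspected for {big.idxmax()!r} "
            f"(|coef| = {big.max():.1f})"
        )
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit()
    return LogisticModelFit(
        params=res.params,
        cov=res.cov_params(),
        llf=float(res.llf),
        llnull=float(null.llf),
        n=len(y),
        converged=bool(res.converged),
        groups=groups,
        spec=spec,
        n_dropped_missing=int(len(data) - len(kept)),
        design=X if keep_design else None,
        y=y if keep_design else None,
    )


# ---------------------------------------------------------------------------
# variable importance

def wald_partial_chisq(
    fit: LogisticModelFit, spec: ModelSpec | None = None
) -> pd.DataFrame:
    """Partial Wald chi-squared X = bᵀV_b⁻¹b per variable, with % shares."""
    rows = []
    for var, cols in fit.groups.items():
        if not cols:
            continue
        b = fit.params[cols].to_numpy()
        Vb = fit.cov.loc[cols, cols].to_numpy()
        try:
            x = float(b @ np.linalg.solve(Vb, b))
        except np.linalg.LinAlgError:
            warnings.warn(
                f"singular covariance block for {var}; using pseudo-inverse",
                stacklevel=2,
            )
            x = float(b @ np.linalg.pinv(Vb) @ b)
        rows.append((var, x, len(cols)))
    table = pd.DataFrame(rows, columns=["variable", "chisq", "df"]).set_index(
        "variable"
    )
    total = table["chisq"].sum()
    table["share_pct"] = 100.0 * table["chisq"] / total if total > 0 else 0.0
    return table


def shapley_importance(
    fit: LogisticModelFit,
    design: pd.DataFrame | None = None,
    mode: str = "exact_linear",
    n_permutations: int = 200,
    seed: int = 0,
) -> pd.Series:
    """Mean |Shapley value| per variable on the linear-predictor scale.

    ``exact_linear`` uses the closed form for additive predictors with the
    in-sample covariate means as baseline; ``montecarlo`` estimates the
    same by sampling variable orderings (>= 10 permutations required).
    """
    X = design if design is not None else fit.design
    if X is None:
        raise ValueError("no design rows available; pass `design`")
    variables = [v for v, cols in fit.groups.items() if cols]
    centered = {}
    for var in variables:
        cols = fit.groups[var]
        block = X[cols].to_numpy()
        centered[var] = (block - block.mean(axis=0)) @ fit.params[cols].to_numpy()
    G = np.column_stack([centered[v] for v in variables])  # (n, p) contributions

    if mode == "exact_linear":
        phi = G
    elif mode == "montecarlo":
        if n_permutations < 10:
            raise ValueError("montecarlo mode needs at least 10 permutations")
        rng = np.random.default_rng(seed)
        acc = np.zeros_like(G)
        p = len(variables)
        for _ in range(n_permutations):
            order = rng.permutation(p)
            running = np.zeros(G.shape[0])
            for j in order:
                with_j = running + G[:, j]
                acc[:, j] += with_j - running
                running = with_j
        phi = acc / n_permutations
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(
        np.abs(phi).mean(axis=0), index=pd.Index(variables, name="variable"),
        name="mean_abs_shapley",
    )


def shapley_rowwise(fit: LogisticModelFit, design: pd.DataFrame | None = None):
    """Per-row exact Shapley contributions (n, p) and the variable order."""
    X = design if design is not None else fit.design
    variables = [v for v, cols in fit.groups.items() if cols]
    G = np.column_stack(
        [
            (X[cols].to_numpy() - X[cols].to_numpy().mean(axis=0))
            @ fit.params[cols].to_numpy()
            for cols in (fit.groups[v] for v in variables)
        ]
    )
    return G, variables


class PseudoR2(NamedTuple):
    mcfadden: float
    cox_snell: float
    nagelkerke: float


def pseudo_r2(fit: LogisticModelFit) -> PseudoR2:
    """McFadden, Cox–Snell and Nagelkerke pseudo-R² from the likelihoods."""
    if fit.llnull == 0:
        raise ValueError("null log-likelihood is zero; pseudo-R2 undefined")
    mcfadden = 1.0 - fit.llf / fit.llnull
    cox_snell = 1.0 - float(np.exp(2.0 * (fit.llnull - fit.llf) / fit.n))
    nagelkerke = cox_snell / (1.0 - float(np.exp(2.0 * fit.llnull / fit.n)))
    return PseudoR2(mcfadden, cox_snell, nagelkerke)


# ---------------------------------------------------------------------------
# report assembly

@dataclass(frozen=True)
class ImportanceReport:
    """Per-variable Wald chi-squared (+shares) and mean |Shapley|, plus fit R²."""

    table: pd.DataFrame
    mcfadden: float
    nagelkerke: float


def importance_report(
    fit: LogisticModelFit, design: pd.DataFrame | None = None
) -> ImportanceReport:
    wald = wald_partial_chisq(fit)
    shap = shapley_importance(fit, design=design)
    table = wald.join(shap)
    r2 = pseudo_r2(fit)
    return ImportanceReport(
        table=table, mcfadden=r2.mcfadden, nagelkerke=r2.nagelkerke
    )


def unadjusted_or_table(
    data: pd.DataFrame,
    outcome: Sequence[bool],
    exposure: str = "smoking_status",
    reference: str = "never",
) -> pd.DataFrame:
    """Per-level 2x2 odds ratios versus the reference level."""
    y = np.asarray(outcome, dtype=bool)
    levels = [lv for lv in pd.unique(data[exposure]) if lv != reference]
    ref_mask = (data[exposure] == reference).to_numpy()
    rows = []
    for lv in sorted(levels):
        mask = (data[exposure] == lv).to_numpy()
        table = ContingencyTable2x2(
            int((y & mask).sum()), int((~y & mask).sum()),
            int((y & ref_mask).sum()), int((~y & ref_mask).sum()),
        )
        res = odds_ratio_2x2(table)
        rows.append((lv, res.odds_ratio, res.ci_low, res.ci_high))
    return pd.DataFrame(
        rows, columns=[exposure, "odds_ratio", "ci_low", "ci_high"]
    ).set_index(exposure)
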