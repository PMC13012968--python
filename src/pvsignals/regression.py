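"""Case/non-case logistic regression of IRAE reporting odds.

The outcome is whether a report carries at least one term from a
configurable immune-related adverse event (IRAE) list. The design codes
categorical covariates against fixed reference levels — sex (male), age
group (<65), weight group (50-100 kg), reporter type (MD) — with treatment
regimen as the primary exposure (reference: drug-B monotherapy, switchable
to obtain the secondary combination-vs-drug-A contrast by refitting).
Unknown demographic categories enter as explicit levels.

Estimates are maximum likelihood (Newton/IRLS via statsmodels) with Wald 95%
CIs on the log-odds scale. Quasi-complete separation is detected
deterministically — a zero margin in a term's event x level cross-tab, or a
diverging coefficient (|coef| > 10 with SE > 100) at the iteration cap — and
such terms are reported as non-estimable rather than with spurious numbers.
Model fit is summarised by McFadden's R^2, AIC and BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort
from .errors import DegenerateOutcomeError, NonConvergenceError

#: Default IRAE outcome list: the immune-related preferred terms screened in
#: the disproportionality stage.
DEFAULT_IRAE_TERMS = (
    "Diarrhoea", "Lymphocyte count decreased", "Arthralgia",
    "Neutrophil count decreased", "Pruritus", "Optic neuritis", "Cholangitis",
    "Thrombocytopenia", "Neutropenia", "Pancytopenia", "Lymphopenia", "Sepsis",
    "Febrile neutropenia", "Aspartate aminotransferase increased",
    "Aplastic anaemia", "Toxic epidermal necrolysis", "Hepatitis",
    "Pleural effusion", "Drug reaction with eosinophilia and systemic symptoms",
    "Progressive multifocal leukoencephalopathy", "Herpes simplex encephalitis",
    "Lichenoid keratosis", "Eosinophilia", "Erythema multiforme",
    "Diabetes insipidus", "Haemophagocytic lymphohistiocytosis",
    "Strongyloidiasis", "Epstein-Barr virus infection",
    "Pneumonia cytomegaloviral", "Nephrotic syndrome", "Enterocolitis",
)

_YOUNG_AGE_GROUPS = {"<2", "2-11", "12-17", "18-64"}
_OLD_AGE_GROUPS = {"65-85", ">85"}


@dataclass
class RegressionSpec:
    """Covariate coding contract: reference levels and the IRAE term list."""

    irae_terms: Tuple[str, ...] = DEFAULT_IRAE_TERMS
    regimen_reference: str = "DRUG_B_MONO"
    include_unknown_levels: bool = True

    def __post_init__(self):
        if not self.irae_terms:
            raise ValueError("IRAE term list must be non-empty")


def _age_band(age_group: str) -> str:
    if age_group in _YOUNG_AGE_GROUPS:
        return "<65"
    if age_group in _OLD_AGE_GROUPS:
        return ">=65"
    return "unknown"


def build_design(
    reports: pd.DataFrame,
    groups: pd.Series,
    outcome: pd.Series,
    spec: RegressionSpec,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Indicator-coded design matrix with stable, documented column order.

    Columns are ``const`` then, per variable, one indicator per non-reference
    level in a fixed order: sex, age band, weight group, reporter type,
    regimen. Unknown levels are kept as explicit indicators (switchable).
    """
    if outcome.nunique() < 2:
        raise DegenerateOutcomeError("outcome is constant; logistic model is undefined")

    df = pd.DataFrame(
        {
            "sex": reports["sex"],
            "age_band": reports["age_group"].map(_age_band),
            "weight_group": reports["weight_group"],
            "reporter_type": reports["reporter_type"],
            "regimen": groups.values,
        },
        index=reports.index,
    )
    plan = [
        ("sex", "male", ["female", "unknown"]),
        ("age_band", "<65", [">=65", "unknown"]),
        ("weight_group", "50-100kg", ["<50kg", ">100kg", "unknown"]),
        ("reporter_type", "MD", ["OT", "HP", "CN", "PH", "LW", "RN", "unknown"]),
        ("regimen", spec.regimen_reference,
         [g for g in ("COMBO", "DRUG_A_MONO", "DRUG_B_MONO") if g != spec.regimen_reference]),
    ]
    cols: Dict[str, np.ndarray] = {"const": np.ones(len(df))}
    for var, ref, levels in plan:
        present = set(df[var].unique())
        extra = sorted(present - set(levels) - {ref})
        for level in list(levels) + extra:
            if level not in present:
                continue
            if level == "unknown" and not spec.include_unknown_levels:
                continue
            cols[f"{var}[{level}]"] = (df[var] == level).astype(float).to_numpy()
    design = pd.DataFrame(cols, index=df.index)
    return design, outcome.astype(int)


def _separated_terms(design: pd.DataFrame, outcome: pd.Series) -> Set[str]:
    """Indicator terms with a zero margin in their event x level cross-tab."""
    bad = set()
    y = outcome.to_numpy()
    for col in design.columns:
        if col == "const":
            continue
        x = design[col].to_numpy() > 0
        cells = [
            np.sum(x & (y == 1)), np.sum(x & (y == 0)),
        ]
        if 0 in cells or x.all() or not x.any():
            bad.add(col)
    return bad


@dataclass
class TermEstimate:
    term: str
    odds_ratio: Optional[float]
    ci_lower: Optional[float]
    ci_upper: Optional[float]
    p_value: Optional[float]
    estimable: bool


class IRAELogit:
    """Logistic model of IRAE reporting odds over a cohort's report set."""

    def __init__(self, design: pd.DataFrame, outcome: pd.Series):
        self.design = design
        self.outcome = outcome

    @classmethod
    def from_cohort(cls, cohort: Cohort, spec: Optional[RegressionSpec] = None) -> "IRAELogit":
        spec = spec or RegressionSpec()
        assign = cohort.assignments
        study = assign.loc[assign["group"].isin(("COMBO", "DRUG_A_MONO", "DRUG_B_MONO"))]
        reports = (
            cohort.tables.reports.set_index("report_id")
            .loc[study["report_id"]]
            .reset_index()
        )
        irae_set = set(spec.irae_terms)
        ev = cohort.tables.events
        irae_reports = set(ev.loc[ev["event_term"].isin(irae_set), "report_id"])
        outcome = reports["report_id"].isin(irae_reports)
        design, y = build_design(reports, study["group"].reset_index(drop=True), outcome, spec)
        model = cls(design, y)
        model.spec = spec
        return model

    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> "IRAELogitResults":
        design, outcome = self.design, self.outcome
        if outcome.nunique() < 2:
            raise DegenerateOutcomeError("outcome is constant; logistic model is undefined")
        non_estimable = _separated_terms(design, outcome)
        kept = [c for c in design.columns if c not in non_estimable]
        X = design[kept]

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(outcome.to_numpy(), X.to_numpy())
            try:
                fit = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=False)
            except Exception as exc:  # singular Hessian etc. without detected separation
                raise NonConvergenceError(f"logistic fit failed: {exc}") from exc

        params = pd.Series(fit.params, index=kept)
        bse = pd.Series(fit.bse, index=kept)
        # post-fit separation sweep: diverging coefficient with exploding SE
        diverged = {c for c in kept if c != "const" and abs(params[c]) > 10 and bse[c] > 100}
        if diverged:
            non_estimable |= diverged
            kept = [c for c in design.columns if c not in non_estimable]
            X = design[kept]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(outcome.to_numpy(), X.to_numpy()).fit(
                    method="newton", maxiter=maxiter, tol=tol, disp=False
                )
            params = pd.Series(fit.params, index=kept)
            bse = pd.Series(fit.bse, index=kept)
        if not fit.mle_retvals.get("converged", False):
            raise NonConvergenceError(
                "logistic fit did not converge", trace=fit.mle_retvals
            )

        z = 1.959963984540054
        estimates: List[TermEstimate] = []
        pvalues = pd.Series(fit.pvalues, index=kept)
        for col in self.design.columns:
            if col in non_estimable:
                estimates.append(TermEstimate(col, None, None, None, None, False))
            else:
                beta, se = params[col], bse[col]
                estimates.append(
                    TermEstimate(
                        col,
                        float(np.exp(beta)),
                        float(np.exp(beta - z * se)),
                        float(np.exp(beta + z * se)),
                        float(pvalues[col]),
                        True,
                    )
                )

        # null (intercept-only) model on the same observations
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null_fit = sm.Logit(outcome.to_numpy(), np.ones((len(outcome), 1))).fit(
                method="newton", maxiter=maxiter, tol=tol, disp=False
            )
        return IRAELogitResults(
            self, estimates, float(fit.llf), float(null_fit.llf), len(kept), int(len(outcome))
        )


def fit_indices(ll_full: float, ll_null: float, k: int, n: int) -> Tuple[float, float, float]:
    """McFadden R^2 = 1 - ll_full/ll_null; AIC = 2k - 2 ll; BIC = k ln n - 2 ll."""
    if n <= 0:
        raise ValueError("fit indices require matching, non-empty datasets")
    mcfadden = 1.0 - ll_full / ll_null if ll_null != 0 else 0.0
    aic = 2 * k - 2 * ll_full
    bic = k * np.log(n) - 2 * ll_full
    return float(mcfadden), float(aic), float(bic)


class IRAELogitResults:
    """Per-term odds ratios with estimability flags plus fit indices."""

    def __init__(self, model: IRAELogit, estimates: List[TermEstimate],
                 llf: float, llnull: float, k: int, nobs: int):
        self.model = model
        self.estimates = estimates
        self.llf = llf
        self.llnull = llnull
        self.k = k
        self.nobs = nobs
        self.converged = True
        self.mcfadden_r2, self.aic, self.bic = fit_indices(llf, llnull, k, nobs)
        self.frame = pd.DataFrame(
            [
                {
                    "term": e.term,
                    "odds_ratio": e.odds_ratio,
                    "ci_lower": e.ci_lower,
                    "ci_upper": e.ci_upper,
                    "p_value": e.p_value,
                    "estimable": e.estimable,
                }
                for e in estimates
            ],
            columns=["term", "odds_ratio", "ci_lower", "ci_upper", "p_value", "estimable"],
        )

    def summary(self) -> str:
        lines = [
            "IRAE reporting-odds logistic regression",
            f"  n = {self.nobs}, parameters = {self.k}",
            f"  McFadden R^2 = {self.mcfadden_r2:.4f}, AIC = {self.aic:.2f}, BIC = {self.bic:.2f}",
            f"{'term':<28}{'OR':>10}{'95% CI':>22}{'p':>10}",
        ]
        for e in self.estimates:
            if e.estimable:
                lines.append(
                    f"{e.term:<28}{e.odds_ratio:>10.4f}"
                    f"{f'{e.ci_lower:.4f}-{e.ci_upper:.4f}':>22}{e.p_value:>10.4f}"
                )
            else:
                lines.append(f"{e.term:<28}{'Not estimable':>32}")
        return "\n".join(lines)


def fit_logistic(design: pd.DataFrame, outcome: pd.Series, **kwargs) -> IRAELogitResults:
    """Functional wrapper over :class:`IRAELogit`."""
    return IRAELogit(design, outcome).fit(**kwargs)


__all__ = [
    "RegressionSpec",
    "TermEstimate",
    "IRAELogit",
    "IRAELogitResults",
    "build_design",
    "fit_logistic",
    "fit_indices",
    "DEFAULT_IRAE_TERMS",
]
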