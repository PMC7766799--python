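"""Group-level overlap -> improvement model with variance decomposition.

Tremor improvement (percent) is regressed on tract overlap (mm^3) in a
linear mixed-effects model with a random intercept per lead
(patient x hemisphere), accounting for the repeated per-contact
testings of each lead:

    improvement_ij = beta0 + beta1 * overlap_ij + u_j + e_ij
    u_j ~ N(0, sigma_u^2),   e_ij ~ N(0, sigma_e^2)

Estimation is restricted maximum likelihood (REML) via statsmodels'
``MixedLM``; the slope p-value is a Wald test.  Variance explained is
decomposed after Nakagawa & Schielzeth:

    R2_marginal    = var(Xb) / (var(Xb) + sigma_u^2 + sigma_e^2)
    R2_conditional = (var(Xb) + sigma_u^2) / (same denominator)

with var(Xb) the population (1/n) variance of the fixed-effect
predictions over the data.  Overlap enters on its raw mm^3 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "MixedModelResult",
    "validate_lmm_dataset",
    "fit_lmm",
    "r2_nakagawa",
    "slope_positivity_by_lead",
]

REQUIRED_COLUMNS = ("lead_id", "contact_id", "overlap_mm3", "improvement_pct")

# residual variance (relative to response variance) below which the fit
# is treated as an exact linear relationship rather than sent to REML
_PERFECT_FIT_RTOL = 1e-12


@dataclass(frozen=True)
class MixedModelResult:
    """Fitted mixed-model summary with variance components and R^2."""

    beta0: float  # intercept, percent
    beta1: float  # slope, percent per mm^3
    se_beta1: float
    p_fixed: float
    sigma2_fixed: float  # variance of fixed-effect predictions
    sigma2_random: float  # random-intercept variance
    sigma2_resid: float  # residual variance
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_leads: int
    random_intercepts: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name in ("sigma2_fixed", "sigma2_random", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def validate_lmm_dataset(data: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format dataset the model expects.

    Needs >= 2 leads and >= 2 rows per lead (one row per tested
    contact) and nonzero overlap variance.
    """
    missing = set(REQUIRED_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"dataset missing columns: {sorted(missing)}")
    counts = data.groupby("lead_id").size()
    if len(counts) < 2:
        raise ValueError("need at least 2 leads for a mixed model")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"each lead needs >= 2 tested contacts; offending leads: {bad}")
    if np.var(data["overlap_mm3"].to_numpy()) == 0:
        raise ValueError("singular fit: overlap has zero variance")
    return data


def fit_lmm(data: pd.DataFrame, random_slope: bool = False) -> MixedModelResult:
    """Fit improvement ~ overlap with a per-lead random intercept (REML).

    ``random_slope=True`` additionally lets the overlap slope vary by
    lead; the default random-intercept-only model matches the repeated-
    testing design.  Degenerate noise-free data (zero residual variance)
    is resolved exactly instead of being passed to the iterative
    optimizer.
    """
    data = validate_lmm_dataset(data)
    y = data["improvement_pct"].to_numpy(dtype=float)
    x = data["overlap_mm3"].to_numpy(dtype=float)

    # exact-fit shortcut: all points on one line => zero variance components
    ols = np.polyfit(x, y, 1)
    resid = y - np.polyval(ols, x)
    y_var = max(np.var(y), 1.0)
    if np.var(resid) <= _PERFECT_FIT_RTOL * y_var:
        beta1, beta0 = float(ols[0]), float(ols[1])
        s2f = float(np.var(beta0 + beta1 * x))
        groups = sorted(data["lead_id"].unique())
        return MixedModelResult(
            beta0=beta0,
            beta1=beta1,
            se_beta1=0.0,
            p_fixed=0.0,
            sigma2_fixed=s2f,
            sigma2_random=0.0,
            sigma2_resid=0.0,
            r2_marginal=1.0 if s2f > 0 else 0.0,
            r2_conditional=1.0 if s2f > 0 else 0.0,
            n_obs=len(y),
            n_leads=len(groups),
            random_intercepts={g: 0.0 for g in groups},
        )

    re_formula = "~overlap_mm3" if random_slope else "~1"
    model = smf.mixedlm(
        "improvement_pct ~ overlap_mm3",
        data,
        groups=data["lead_id"],
        re_formula=re_formula,
    )
    try:
        fit = model.fit(reml=True, method="lbfgs")
    except np.linalg.LinAlgError:
        # boundary fits (random variance ~ 0) can make the gradient-based
        # optimizer's working matrices singular; Powell is derivative-free
        fit = model.fit(reml=True, method="powell")

    beta0 = float(fit.fe_params["Intercept"])
    beta1 = float(fit.fe_params["overlap_mm3"])
    sigma2_random = float(np.asarray(fit.cov_re)[0, 0])
    sigma2_resid = float(fit.scale)
    sigma2_fixed = float(np.var(beta0 + beta1 * x))  # population (1/n) variance
    r2m, r2c = r2_nakagawa(sigma2_fixed, sigma2_random, sigma2_resid)
    try:
        random_effects = {
            g: float(np.asarray(re).ravel()[0]) for g, re in fit.random_effects.items()
        }
    except ValueError:
        # boundary fit: zero random-intercept variance => all BLUPs are 0
        random_effects = {g: 0.0 for g in data["lead_id"].unique()}
    res = MixedModelResult(
        beta0=beta0,
        beta1=beta1,
        se_beta1=float(fit.bse_fe["overlap_mm3"]),
        p_fixed=float(fit.pvalues["overlap_mm3"]),
        sigma2_fixed=sigma2_fixed,
        sigma2_random=max(sigma2_random, 0.0),
        sigma2_resid=sigma2_resid,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_obs=len(y),
        n_leads=data["lead_id"].nunique(),
        random_intercepts=random_effects,
    )
    return res


def r2_nakagawa(
    sigma2_fixed: float, sigma2_random: float, sigma2_resid: float
) -> tuple[float, float]:
    """Marginal and conditional R^2 from the three variance components."""
    parts = (sigma2_fixed, sigma2_random, sigma2_resid)
    if any(p < 0 for p in parts):
        raise ValueError("variance components must be >= 0")
    denom = sum(parts)
    if denom == 0:
        raise ValueError("all variance components are zero; R^2 undefined")
    r2m = sigma2_fixed / denom
    r2c = (sigma2_fixed + sigma2_random) / denom
    return float(r2m), float(r2c)


def slope_positivity_by_lead(
    result: MixedModelResult, data: pd.DataFrame
) -> pd.DataFrame:
    """Sign of the fitted overlap-improvement relationship per lead.

    In the shared-slope random-intercept model every lead's fitted line
    has the same slope, so the sign equals sign(beta1) throughout; the
    table exists to report it per lead alongside each lead's intercept
    offset for plotting.
    """
    sign = int(np.sign(result.beta1))
    rows = []
    for lead in sorted(data["lead_id"].unique()):
        rows.append(
            {
                "lead_id": lead,
                "slope": result.beta1,
                "sign": sign,
                "intercept": result.beta0 + result.random_intercepts.get(lead, 0.0),
            }
        )
    return pd.DataFrame(rows)
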