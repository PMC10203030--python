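"""Standardized multi-component effect sizes.

Each response is regressed on the three landscape components together
(multiple OLS), with every variable z-scored first, so coefficients are
fully standardized and comparable across components.  Components are
measured either at their individually selected scales of effect or at a
common a priori scale (default 400 m, the median daily movement distance of
mosquitoes).

p-values come from classical OLS t-tests (two-sided, n - 4 residual df for
three predictors plus intercept); no multiple-testing correction is
applied.  Significance codes: p <= .10 'p' (marginal), <= .05 '*',
<= .01 '**', <= .001 '***'.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, InvalidArgumentError
from .landscape import COMPONENTS, CoverProfile

#: Default a priori scale (m): median daily movement distance of mosquitoes.
APRIORI_SCALE = 400.0

_SIGNIF_CUTS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.10, "p"))

#: Pairwise correlation beyond which the design is reported as collinear.
COLLINEARITY_LIMIT = 0.95


def signif_code(p: float) -> str:
    """Significance code for a p-value (most significant applicable cut)."""
    if not 0 <= p <= 1:
        raise InvalidArgumentError(f"p-value must lie in [0, 1], got {p}")
    for cut, code in _SIGNIF_CUTS:
        if p <= cut:
            return code
    return ""


def standardize(values, name: str = "variable") -> np.ndarray:
    """z-scores with mean 0 and sample SD 1 (n - 1 denominator)."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise InvalidArgumentError(f"{name}: need >= 2 values to standardize")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise InvalidArgumentError(f"{name}: zero variance, cannot standardize")
    return (vals - vals.mean()) / sd


def fit_effects(
    response: pd.Series,
    covers: pd.DataFrame,
    scales_used: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Standardized multiple regression of a response on component covers.

    Parameters
    ----------
    response
        Per-site response values (index = site_id, name = response kind).
    covers
        Per-site raw cover values, one column per component, same sites.
    scales_used
        Radius (m) at which each component column was measured; recorded in
        the output table.

    Returns
    -------
    DataFrame with one row per component:
    ``response_kind, component, scale_used_m, beta_std, se_std, p_value, signif``.
    """
    components = list(covers.columns)
    n = len(response)
    if n < 5:
        raise InvalidArgumentError(f"need >= 5 sites, got {n}")
    missing = [s for s in covers.index if s not in response.index]
    if missing:
        raise InvalidArgumentError(f"response lacks sites {missing}")
    y = standardize(response.loc[covers.index], name=str(response.name))
    Z = np.column_stack(
        [standardize(covers[c], name=f"cover {c!r}") for c in components]
    )
    # collinear components make individual betas meaningless; report, don't fit
    corr = np.corrcoef(Z, rowvar=False)
    for i in range(len(components)):
        for j in range(i + 1, len(components)):
            if abs(corr[i, j]) > COLLINEARITY_LIMIT:
                raise CollinearityError(
                    f"components {components[i]!r} and {components[j]!r} are "
                    f"collinear (|r| = {abs(corr[i, j]):.3f} > {COLLINEARITY_LIMIT})"
                )
    fit = sm.OLS(y, sm.add_constant(Z)).fit()
    rows = []
    for k, comp in enumerate(components):
        p = float(fit.pvalues[k + 1])
        rows.append(
            {
                "response_kind": str(response.name),
                "component": comp,
                "scale_used_m": float(scales_used[comp]) if scales_used else np.nan,
                "beta_std": float(fit.params[k + 1]),
                "se_std": float(fit.bse[k + 1]),
                "p_value": p,
                "signif": signif_code(p),
            }
        )
    return pd.DataFrame(rows)


def covers_at_scales(
    profile: CoverProfile, scales: Mapping[str, float]
) -> pd.DataFrame:
    """Per-site cover of each component at its own scale, as a design table."""
    cols = {}
    for comp, radius in scales.items():
        cols[comp] = profile.column(comp, radius)
    return pd.DataFrame(cols)


def fit_effects_at_scales(
    profile: CoverProfile,
    response: pd.Series,
    scales: Mapping[str, float],
) -> pd.DataFrame:
    """Fit standardized effects with each component at its selected scale."""
    return fit_effects(response, covers_at_scales(profile, scales), scales)


def fit_effects_apriori(
    profile: CoverProfile,
    response: pd.Series,
    apriori_scale: float = APRIORI_SCALE,
    components: tuple[str, ...] = COMPONENTS,
) -> pd.DataFrame:
    """Fit standardized effects with every component at one common radius."""
    scales = {c: float(apriori_scale) for c in components}
    return fit_effects_at_scales(profile, response, scales)
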