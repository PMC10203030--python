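"""Scale-of-effect selection: R² profiles over buffer radii and bootstrap.

For one landscape component (forest, urban or agricultural cover) and one
response, a simple linear regression of the response on the component's
cover is fitted at every buffer radius.  The *scale of effect* is the
radius maximizing R²; ties go to the smallest radius (parsimony).

Uncertainty in the selected scale is quantified by a nonparametric
bootstrap: sites (whole rows — the response together with all covers) are
resampled with replacement, the full R² profile is recomputed on each
resample, and the selected scale recorded.  Resamples with fewer than three
distinct sites or a constant response cannot support a regression; they are
redrawn so the number of replicates stays fixed, and the redraw count is
logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, InvalidArgumentError
from .landscape import CoverProfile

logger = logging.getLogger(__name__)


def r2_simple(x, y) -> float:
    """R² of the ordinary least-squares fit of ``y`` on ``x`` with intercept.

    For a single predictor this equals the squared Pearson correlation.  A
    zero-variance predictor carries no information, so its R² is defined as
    0 (rather than an error) to keep per-radius profiles total; a
    zero-variance *response* is an error, as is n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise InvalidArgumentError(f"need >= 3 points, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    if ss_y == 0:
        raise InvalidArgumentError("response has zero variance")
    ss_x = float(xc @ xc)
    if ss_x == 0:
        return 0.0
    r = float(xc @ yc) / np.sqrt(ss_x * ss_y)
    return min(r * r, 1.0)


def _r2_columns(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column R² (and slope signs) of y on each column of X.

    Zero-variance columns get R² 0 and sign 0.  Assumes y has variance.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    ss_x = (Xc * Xc).sum(axis=0)
    ss_y = float(yc @ yc)
    cov = yc @ Xc
    r2 = np.zeros(X.shape[1])
    ok = ss_x > 0
    r2[ok] = np.minimum(cov[ok] ** 2 / (ss_x[ok] * ss_y), 1.0)
    signs = np.sign(cov) * ok
    return r2, signs.astype(int)


def select_scale(profile) -> float:
    """Radius attaining the maximal R²; ties resolved to the smallest radius.

    Accepts a mapping ``radius -> r2`` or a pandas Series indexed by radius.
    """
    items = list(profile.items())
    if not items:
        raise InvalidArgumentError("empty R² profile")
    items.sort(key=lambda kv: kv[0])
    best_r, best_v = items[0]
    for r, v in items[1:]:
        if v > best_v:
            best_r, best_v = r, v
    return float(best_r)


@dataclass(frozen=True)
class ScaleProfile:
    """R² as a function of buffer radius for one component-response pair."""

    component: str
    response_kind: str
    radii: np.ndarray
    r2: np.ndarray
    slope_sign: np.ndarray
    selected_scale: float

    def __post_init__(self) -> None:
        if not (0 <= self.r2.min() and self.r2.max() <= 1):
            raise InvalidArgumentError("R² values must lie in [0, 1]")

    def as_series(self) -> pd.Series:
        return pd.Series(self.r2, index=self.radii, name="r2")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": self.component,
                "response_kind": self.response_kind,
                "radius_m": self.radii,
                "r2": self.r2,
                "slope_sign": self.slope_sign,
            }
        )


def _align(profile: CoverProfile, response: pd.Series, component: str):
    mat = profile.matrix(component)
    missing = [s for s in mat.index if s not in response.index]
    if missing:
        raise AlignmentError(
            f"response {response.name!r} lacks values for sites {missing}"
        )
    y = response.loc[list(mat.index)].to_numpy(dtype=float)
    return mat.to_numpy(dtype=float), y


def scale_profile(
    profile: CoverProfile, response: pd.Series, component: str
) -> ScaleProfile:
    """Full R² profile of one response against one component across radii."""
    X, y = _align(profile, response, component)
    if y.size < 3:
        raise InvalidArgumentError(f"need >= 3 sites, got {y.size}")
    if np.var(y) == 0:
        raise InvalidArgumentError(
            f"response {response.name!r} has zero variance across sites"
        )
    r2, signs = _r2_columns(X, y)
    if not np.all(r2 > 0):
        n_flat = int((~(r2 > 0)).sum())
        logger.debug(
            "%s/%s: %d radii with zero-variance or uncorrelated cover",
            component,
            response.name,
            n_flat,
        )
    radii = np.asarray(profile.radii, dtype=float)
    sel = select_scale(pd.Series(r2, index=radii))
    return ScaleProfile(
        component=component,
        response_kind=str(response.name),
        radii=radii,
        r2=r2,
        slope_sign=signs,
        selected_scale=sel,
    )


@dataclass(frozen=True)
class BootstrapScaleDistribution:
    """Selected scales over bootstrap resamples of the sites."""

    component: str
    response_kind: str
    B: int
    seed: int
    scales: np.ndarray
    n_redraws: int
    full_data_scale: float

    @property
    def mode(self) -> float:
        """Most frequent selected scale (ties to the smallest radius)."""
        vals, counts = np.unique(self.scales, return_counts=True)
        return float(vals[np.argmax(counts)])

    def central_interval(self, level: float = 0.95) -> tuple[float, float]:
        lo, hi = np.percentile(self.scales, [50 * (1 - level), 50 * (1 + level)])
        return float(lo), float(hi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": self.component,
                "response_kind": self.response_kind,
                "replicate": np.arange(1, self.B + 1),
                "selected_scale_m": self.scales,
            }
        )


def bootstrap_scale(
    profile: CoverProfile,
    response: pd.Series,
    component: str,
    B: int = 1000,
    seed: int | None = 0,
    max_redraw_factor: int = 100,
) -> BootstrapScaleDistribution:
    """Bootstrap distribution of the selected scale.

    Each replicate draws n sites with replacement (n = number of sites),
    recomputes the R² profile on the resampled rows and records the argmax
    radius.  Degenerate resamples (< 3 distinct sites, or zero response
    variance) are redrawn.
    """
    if B < 1:
        raise InvalidArgumentError(f"B must be >= 1, got {B}")
    X, y = _align(profile, response, component)
    n = y.size
    if np.unique(y).size < 2 or n < 3:
        raise InvalidArgumentError("need >= 3 sites and a non-constant response")
    radii = np.asarray(profile.radii, dtype=float)
    full = select_scale(pd.Series(_r2_columns(X, y)[0], index=radii))

    rng = np.random.default_rng(seed)
    scales = np.empty(B)
    n_redraws = 0
    max_draws = max_redraw_factor * B
    b = 0
    draws = 0
    while b < B:
        if draws >= max_draws:
            raise InvalidArgumentError(
                f"exceeded {max_draws} bootstrap draws; data too degenerate"
            )
        idx = rng.integers(0, n, size=n)
        draws += 1
        yb = y[idx]
        if np.unique(idx).size < 3 or np.var(yb) == 0:
            n_redraws += 1
            continue
        r2, _ = _r2_columns(X[idx], yb)
        scales[b] = select_scale(pd.Series(r2, index=radii))
        b += 1
    if n_redraws:
        logger.info(
            "bootstrap %s/%s: %d degenerate resamples redrawn",
            component,
            response.name,
            n_redraws,
        )
    return BootstrapScaleDistribution(
        component=component,
        response_kind=str(response.name),
        B=B,
        seed=seed if seed is not None else -1,
        scales=scales,
        n_redraws=n_redraws,
        full_data_scale=full,
    )
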