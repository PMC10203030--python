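"""Synthetic landscapes, sites and communities with known ground truth.

The generator emulates the structure of the Swiss mosquito survey that
motivates this package: 16 sampling sites split between natural- and
human-dominated landscapes, about 7 common taxa holding ~97% of all
individuals plus a rare tail, per-site totals near 750 with strong
overdispersion, and responses driven by land cover measured at a known
("planted") buffer radius.  Because the truth is planted, every pipeline
stage — cover extraction, scale selection, bootstrap, effect estimation —
can be tested for recovery without any external data.

Landscapes are categorical grids obtained by thresholding smooth spatially
correlated random fields (Gaussian-filtered white noise), one field per
non-complement class, at quantile levels that hit the target class
proportions exactly (up to one cell).  The autocorrelation range of the
fields controls how similar cover is at nearby radii, i.e. how hard nearby
scales are to tell apart.

Responses follow a linear model in the z-scored cover of each component at
its planted scale:

    eta_s = sum_c beta_c * z(cover at true_scale_c)_s

* gaussian family (diversity-like): response = eta + N(0, sigma).  Three
  noise conventions are supported: an absolute ``noise_sd``; a
  signal-to-noise ratio ``snr`` (sigma = sd(eta) / snr); or, when neither
  is given, sigma^2 = max(0, 1 - var(eta)) so the response has unit
  variance and the planted betas are themselves the standardized
  coefficients the effect models estimate.
* poisson / negative-binomial families (abundance-like): per-site totals
  with log mean = log(mean_total) + count_slope * eta, split across taxa
  with a dominant-taxa structure and across sampling sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .community import COUNT_COLUMNS
from .effect_models import fit_effects_at_scales, fit_effects_apriori
from .errors import FeasibilityError, InvalidArgumentError
from .landscape import (
    CLASSES,
    CoverProfile,
    LandscapeGrid,
    build_cover_profile,
    make_radius_series,
)
from .scale_selection import bootstrap_scale, scale_profile


def _default_proportions() -> dict[str, float]:
    return {"forest": 0.35, "urban": 0.20, "agriculture": 0.25}


def _default_true_scales() -> dict[str, float]:
    return {"forest": 200.0, "urban": 500.0, "agriculture": 2000.0}


def _default_betas() -> dict[str, float]:
    return {"forest": -0.5, "urban": 0.6, "agriculture": 0.0}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate the survey structure the pipeline targets: 16 sites,
    a 150-2000 m radius series coarsened to a 50 m step, planted scales of
    200 / 500 / 2000 m for forest / urban / agricultural cover, planted
    standardized effects (-0.5, +0.6, 0.0), 7 common taxa holding 97% of
    individuals, per-site totals with mean 750 and negative-binomial
    dispersion 4 (SD roughly half the mean across sites).
    """

    # landscape
    n_cells: int = 260
    cell_size: float = 25.0
    class_proportions: dict = field(default_factory=_default_proportions)
    autocorr_range: float = 300.0
    # sites
    n_sites: int = 16
    min_separation: float = 400.0
    buffer_margin: float = 2000.0
    effort_range: tuple[int, int] = (8, 20)
    # radius series
    r_min: float = 150.0
    r_max: float = 2050.0
    r_step: float = 50.0
    # planted truth
    true_scales: dict = field(default_factory=_default_true_scales)
    betas: dict = field(default_factory=_default_betas)
    # response model
    noise_sd: float | None = None
    snr: float | None = None
    family: str = "gaussian"
    mean_total: float = 750.0
    count_slope: float = 0.4
    dispersion: float = 4.0
    # community structure
    n_taxa: int = 18
    n_common: int = 7
    rare_tail_fraction: float = 0.03
    n_sessions: int = 5

    def __post_init__(self) -> None:
        p = self.class_proportions
        if any(v < 0 for v in p.values()) or sum(p.values()) > 1 + 1e-12:
            raise InvalidArgumentError(
                f"class proportions must be >= 0 and sum to <= 1, got {p}"
            )
        if self.n_sites < 5:
            raise InvalidArgumentError(f"n_sites must be >= 5, got {self.n_sites}")
        radii = self.radius_series()
        for comp, r in self.true_scales.items():
            if not np.any(np.isclose(radii, r)):
                raise InvalidArgumentError(
                    f"true scale {r} m for {comp!r} is not in the radius series "
                    f"[{radii[0]}, {radii[-1]}] step {self.r_step}"
                )
        if self.buffer_margin < radii[-1]:
            raise InvalidArgumentError(
                f"buffer_margin ({self.buffer_margin} m) must cover the largest "
                f"radius ({radii[-1]} m)"
            )
        if self.family not in ("gaussian", "poisson", "negative-binomial"):
            raise InvalidArgumentError(f"unknown response family {self.family!r}")
        if not 0 <= self.rare_tail_fraction < 1:
            raise InvalidArgumentError("rare_tail_fraction must lie in [0, 1)")
        if not 0 < self.n_common <= self.n_taxa:
            raise InvalidArgumentError("need 0 < n_common <= n_taxa")

    def radius_series(self) -> np.ndarray:
        return make_radius_series(self.r_min, self.r_max, self.r_step)

    @property
    def extent(self) -> float:
        return self.n_cells * self.cell_size

    def with_(self, **overrides) -> "SyntheticConfig":
        """A copy with the given fields replaced."""
        return replace(self, **overrides)


def single_component_config(
    component: str = "forest",
    true_scale: float = 1000.0,
    beta: float = 1.0,
    **overrides,
) -> SyntheticConfig:
    """Config with one planted component, for scale-recovery experiments."""
    betas = {c: 0.0 for c in _default_betas()}
    betas[component] = beta
    # zero-beta components share the same radius so any radius series that
    # contains the planted scale is valid
    scales = {c: float(true_scale) for c in betas}
    return SyntheticConfig(betas=betas, true_scales=scales, **overrides)


def attenuation_config(
    component: str = "forest",
    true_scale: float = 2000.0,
    beta: float = 0.6,
    **overrides,
) -> SyntheticConfig:
    """Design for a priori-vs-planted scale comparisons.

    Large buffers push class covers toward their compositional complement,
    so this design thins the class proportions and spreads sites further
    apart to keep large-radius design matrices well conditioned.
    """
    defaults: dict = dict(
        class_proportions={"forest": 0.25, "urban": 0.15, "agriculture": 0.15},
        n_cells=300,
        min_separation=600.0,
        noise_sd=0.0,
    )
    defaults.update(overrides)
    return single_component_config(component, true_scale, beta, **defaults)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def simulate_landscape(config: SyntheticConfig, seed=None) -> LandscapeGrid:
    """Categorical landscape from thresholded smooth random fields.

    One Gaussian-filtered white-noise field is drawn per declared class;
    classes claim their target share of cells in declaration order, each
    taking the highest-field cells still unassigned.  Quantile thresholding
    makes realized grid-wide proportions exact to within one cell.
    """
    rng = np.random.default_rng(seed)
    n = config.n_cells
    sigma = config.autocorr_range / (2.0 * config.cell_size)
    values = np.full(n * n, CLASSES.index("other"), dtype=np.int64)
    assigned = np.zeros(n * n, dtype=bool)
    for cls, target in config.class_proportions.items():
        code = CLASSES.index(cls)
        smooth = gaussian_filter(
            rng.standard_normal((n, n)), sigma, mode="wrap"
        ).ravel()
        k = int(round(target * n * n))
        if k == 0:
            continue
        avail = np.flatnonzero(~assigned)
        if k >= avail.size:
            chosen = avail
        else:
            chosen = avail[np.argpartition(smooth[avail], -k)[-k:]]
        values[chosen] = code
        assigned[chosen] = True
    return LandscapeGrid(
        values=values.reshape(n, n), cell_size=config.cell_size, origin=(0.0, 0.0)
    )


def simulate_sites(
    grid: LandscapeGrid,
    n_sites: int,
    min_separation: float,
    seed=None,
    margin: float = 0.0,
    effort_range: tuple[int, int] = (8, 20),
    max_restarts: int = 50,
) -> pd.DataFrame:
    """Random sites with pairwise separation, buffers guaranteed in-extent.

    Sites are placed by rejection sampling inside the grid shrunk by
    ``margin`` on every side, so any buffer of radius <= margin fits.
    Packing is retried from scratch a bounded number of times before
    raising :class:`FeasibilityError`.
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent
    lo_x, hi_x = xmin + margin, xmax - margin
    lo_y, hi_y = ymin + margin, ymax - margin
    if lo_x >= hi_x or lo_y >= hi_y:
        raise FeasibilityError(
            f"margin {margin} m leaves no room in a "
            f"{grid.width} x {grid.height} m grid"
        )
    for _ in range(max_restarts):
        xs: list[float] = []
        ys: list[float] = []
        tries = 0
        while len(xs) < n_sites and tries < 400 * n_sites:
            tries += 1
            x = rng.uniform(lo_x, hi_x)
            y = rng.uniform(lo_y, hi_y)
            if all(
                (x - a) ** 2 + (y - b) ** 2 >= min_separation**2
                for a, b in zip(xs, ys)
            ):
                xs.append(x)
                ys.append(y)
        if len(xs) == n_sites:
            efforts = rng.integers(effort_range[0], effort_range[1] + 1, n_sites)
            return pd.DataFrame(
                {
                    "site_id": [f"S{i + 1:02d}" for i in range(n_sites)],
                    "x": xs,
                    "y": ys,
                    "effort": efforts,
                }
            )
    raise FeasibilityError(
        f"could not place {n_sites} sites with separation {min_separation} m "
        f"in a {hi_x - lo_x:.0f} x {hi_y - lo_y:.0f} m core area"
    )


@dataclass(frozen=True)
class SimulatedResponse:
    """A planted response plus the ground truth that generated it."""

    response: pd.Series
    eta: pd.Series
    noise_sd: float
    community: pd.DataFrame | None
    true_scales: dict
    betas: dict


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise InvalidArgumentError("cover has zero variance across sites")
    return (v - v.mean()) / sd


def _taxon_weights(config: SyntheticConfig) -> np.ndarray:
    """Dominance structure: geometric common taxa + an even rare tail."""
    common = 0.55 ** np.arange(config.n_common)
    common = common / common.sum() * (1.0 - config.rare_tail_fraction)
    n_rare = config.n_taxa - config.n_common
    if n_rare == 0:
        return common / common.sum()
    rare = np.full(n_rare, config.rare_tail_fraction / n_rare)
    return np.concatenate([common, rare])


def draw_total(rng: np.random.Generator, mu: float, config: SyntheticConfig) -> int:
    """One per-site total count under the configured count family."""
    if config.family == "poisson":
        return int(rng.poisson(mu))
    k = config.dispersion
    return int(rng.negative_binomial(k, k / (k + mu)))


def simulate_response(
    profile: CoverProfile, config: SyntheticConfig, seed=None
) -> SimulatedResponse:
    """Planted response for the sites of a cover profile.

    Gaussian family returns a diversity-like continuous response.  Count
    families return the per-site total count as the response and a full
    long-format community table (taxa x sessions) alongside.
    """
    rng = np.random.default_rng(seed)
    sites = list(profile.site_ids)
    eta = np.zeros(len(sites))
    for comp, beta in config.betas.items():
        if beta == 0:
            continue
        r = config.true_scales[comp]
        cover = profile.column(comp, r).to_numpy(dtype=float)
        eta += beta * _zscore(cover)
    if config.noise_sd is not None:
        sd = float(config.noise_sd)
    elif config.snr is not None:
        sd = float(eta.std(ddof=1)) / config.snr
    else:
        sd = float(np.sqrt(max(0.0, 1.0 - eta.var(ddof=1))))
    eta_s = pd.Series(eta, index=sites, name="eta")

    if config.family == "gaussian":
        y = eta + (rng.normal(0.0, sd, len(sites)) if sd > 0 else 0.0)
        resp = pd.Series(y, index=sites, name="simulated")
        return SimulatedResponse(resp, eta_s, sd, None, dict(config.true_scales),
                                 dict(config.betas))

    taxa = [f"taxon_{i + 1:02d}" for i in range(config.n_taxa)]
    sessions = [f"session_{i + 1}" for i in range(config.n_sessions)]
    weights = _taxon_weights(config)
    rows = []
    totals = []
    for i, site in enumerate(sites):
        mu = config.mean_total * np.exp(config.count_slope * eta[i])
        total = draw_total(rng, mu, config)
        totals.append(total)
        by_taxon = rng.multinomial(total, weights)
        for t, taxon_count in zip(taxa, by_taxon):
            by_session = rng.multinomial(taxon_count, np.full(len(sessions), 1 / len(sessions)))
            for s, c in zip(sessions, by_session):
                if c > 0:
                    rows.append((site, t, s, int(c)))
    community = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    resp = pd.Series(totals, index=sites, name="total_count", dtype=float)
    return SimulatedResponse(resp, eta_s, sd, community, dict(config.true_scales),
                             dict(config.betas))


def simulate_dataset(config: SyntheticConfig, seed=None):
    """Landscape -> sites -> cover profile -> response, one call.

    Returns ``(grid, sites, profile, simulated_response)``.
    """
    ss = _as_seedseq(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_land, s_sites, s_resp = ss.spawn(3)
    grid = simulate_landscape(config, s_land)
    sites = simulate_sites(
        grid,
        config.n_sites,
        config.min_separation,
        s_sites,
        margin=config.buffer_margin,
        effort_range=config.effort_range,
    )
    profile = build_cover_profile(grid, sites, config.radius_series())
    sim = simulate_response(profile, config, s_resp)
    return grid, sites, profile, sim


# ---------------------------------------------------------------------------
# Recovery experiments (the package's self-validation harness)
# ---------------------------------------------------------------------------


def _well_conditioned_dataset(
    config: SyntheticConfig,
    seed_seq: np.random.SeedSequence,
    scale_maps: list[Mapping[str, float]] | None = None,
    max_retries: int = 20,
):
    """Simulate a dataset whose covers at the given scales support a fit.

    Mirrors the bootstrap convention for degenerate resamples: a replicate
    whose design matrix at any of the requested scale maps is collinear
    (pairwise |r| > 0.95) or has a zero-variance cover is redrawn with a
    fresh seed, keeping the number of replicates fixed.  Returns the
    dataset tuple and the number of redraws.
    """
    from .effect_models import COLLINEARITY_LIMIT

    if scale_maps is None:
        scale_maps = [config.true_scales]
    redraws = 0
    child = seed_seq
    for _ in range(max_retries):
        out = simulate_dataset(config, child)
        profile = out[2]
        ok = True
        for scales in scale_maps:
            try:
                Z = np.column_stack(
                    [
                        _zscore(profile.column(c, r).to_numpy(dtype=float))
                        for c, r in scales.items()
                    ]
                )
            except InvalidArgumentError:
                ok = False
                break
            corr = np.corrcoef(Z, rowvar=False)
            off_diag = np.abs(corr[~np.eye(corr.shape[0], dtype=bool)])
            if off_diag.max() > COLLINEARITY_LIMIT:
                ok = False
                break
        if ok:
            return out, redraws
        redraws += 1
        child = child.spawn(1)[0]
    raise FeasibilityError(
        f"no well-conditioned replicate after {max_retries} draws; the "
        "landscape design yields collinear covers at the planted scales"
    )
    raise FeasibilityError(
        f"no well-conditioned replicate after {max_retries} draws; the "
        "landscape design yields collinear covers at the planted scales"
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Scale- and effect-recovery outcomes over replicated synthetic runs."""

    scales: pd.DataFrame  # replicate, component, true_scale_m, selected_scale_m
    betas: pd.DataFrame  # replicate, component, beta_true, beta_hat
    r_step: float

    def error_steps(self) -> pd.Series:
        """Selected-minus-true scale error in radius-grid steps."""
        return (self.scales["selected_scale_m"] - self.scales["true_scale_m"]) / self.r_step

    def fraction_exact(self) -> float:
        return float((self.error_steps() == 0).mean())

    def median_abs_error_steps(self) -> float:
        return float(self.error_steps().abs().median())

    def mean_betas(self) -> pd.Series:
        return self.betas.groupby("component")["beta_hat"].mean()

    def beta_mc_se(self) -> pd.Series:
        """Monte-Carlo standard error of the mean estimated betas."""
        g = self.betas.groupby("component")["beta_hat"]
        return g.std(ddof=1) / np.sqrt(g.count())

    def sign_recovery(self) -> pd.Series:
        """Per-component share of replicates with the planted sign (nonzero betas)."""
        nz = self.betas[self.betas["beta_true"] != 0]
        return (
            np.sign(nz["beta_hat"]) == np.sign(nz["beta_true"])
        ).groupby(nz["component"]).mean()


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def recovery_experiment(
    config: SyntheticConfig, n_replicates: int, seed=None
) -> RecoveryReport:
    """Replicate simulate -> select -> fit and compare against planted truth.

    Per replicate, the scale of effect is selected for every component with
    a nonzero planted beta, and standardized effects are fitted with each
    component at its planted scale.
    """
    ss = _as_seedseq(seed)
    scale_rows = []
    beta_rows = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        (_, _, profile, sim), _ = _well_conditioned_dataset(config, child)
        for comp, beta in config.betas.items():
            if beta != 0:
                sp = scale_profile(profile, sim.response, comp)
                scale_rows.append(
                    (rep, comp, config.true_scales[comp], sp.selected_scale)
                )
        effects = fit_effects_at_scales(profile, sim.response, config.true_scales)
        for row in effects.itertuples(index=False):
            beta_rows.append(
                (rep, row.component, config.betas[row.component], row.beta_std)
            )
    return RecoveryReport(
        scales=pd.DataFrame(
            scale_rows,
            columns=["replicate", "component", "true_scale_m", "selected_scale_m"],
        ),
        betas=pd.DataFrame(
            beta_rows, columns=["replicate", "component", "beta_true", "beta_hat"]
        ),
        r_step=config.r_step,
    )


def bootstrap_mode_experiment(
    config: SyntheticConfig,
    component: str,
    n_replicates: int,
    B: int = 200,
    seed=None,
) -> pd.DataFrame:
    """Does the bootstrap mode reproduce the full-data selected scale?

    One row per replicate: the full-data selected scale, the bootstrap
    mode, whether they agree, and the share of bootstrap mass within two
    radius-grid steps of the mode (a concentration/unimodality proxy).
    """
    ss = _as_seedseq(seed)
    rows = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        _, _, profile, sim = simulate_dataset(config, child)
        boot_seed = int(child.generate_state(1)[0] % (2**31))
        dist = bootstrap_scale(profile, sim.response, component, B=B, seed=boot_seed)
        near = np.abs(dist.scales - dist.mode) <= 2 * config.r_step
        rows.append(
            (
                rep,
                dist.full_data_scale,
                dist.mode,
                dist.mode == dist.full_data_scale,
                float(near.mean()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["replicate", "full_data_scale_m", "mode_m", "mode_matches",
                 "mass_within_2_steps"],
    )


def attenuation_experiment(
    config: SyntheticConfig,
    component: str,
    n_replicates: int,
    seed=None,
    apriori_scale: float = 400.0,
) -> pd.DataFrame:
    """Effect-size attenuation when an a priori scale replaces the true one.

    For each replicate the standardized effect of ``component`` is fitted
    twice: with components at their planted scales, and with all components
    at ``apriori_scale``.  With the planted scale far from the a priori one
    the latter should be smaller in magnitude.
    """
    ss = _as_seedseq(seed)
    rows = []
    apriori_map = {c: float(apriori_scale) for c in config.betas}
    for rep, child in enumerate(ss.spawn(n_replicates)):
        (_, _, profile, sim), _ = _well_conditioned_dataset(
            config, child, scale_maps=[config.true_scales, apriori_map]
        )
        at_true = fit_effects_at_scales(profile, sim.response, config.true_scales)
        at_apriori = fit_effects_apriori(profile, sim.response, apriori_scale)
        b_true = float(
            at_true.loc[at_true["component"] == component, "beta_std"].iloc[0]
        )
        b_apriori = float(
            at_apriori.loc[at_apriori["component"] == component, "beta_std"].iloc[0]
        )
        rows.append((rep, b_true, b_apriori, abs(b_apriori) < abs(b_true)))
    return pd.DataFrame(
        rows, columns=["replicate", "beta_at_true_scale", "beta_at_apriori",
                       "attenuated"]
    )
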