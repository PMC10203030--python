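"""End-to-end orchestration: inputs -> responses -> profiles -> effects.

A run is driven by a YAML config naming the grid, site and count files, the
radius series, the responses to analyse and the bootstrap settings.  All
outputs are CSV tables (plus a JSON manifest) in the output directory, one
profile / selected scale / bootstrap file per response x component pair and
one effect-size table per response at the selected scales and at the a
priori scale.  Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import (
    abundance_response,
    filter_common_taxa,
    read_counts,
    shannon_response,
    subset_sessions,
)
from .effect_models import APRIORI_SCALE, fit_effects_apriori, fit_effects_at_scales
from .errors import InvalidArgumentError, ScaleOfEffectError
from .landscape import (
    COMPONENTS,
    build_cover_profile,
    make_radius_series,
    read_grid,
    read_sites,
)
from .scale_selection import bootstrap_scale, scale_profile

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    grid: Path
    sites: Path
    counts: Path
    out_dir: Path
    seed: int
    r_min: float = 150.0
    r_max: float = 5000.0
    r_step: float = 10.0
    include_shannon: bool = True
    abundance_taxa: str | list = "common"
    min_fraction: float = 0.97
    bootstrap_b: int = 1000
    apriori_scale: float = APRIORI_SCALE
    sessions_keep: list | None = None
    figures: bool = False


_REQUIRED_KEYS = ("grid", "sites", "counts", "out_dir", "seed")


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config; errors are aggregated.

    Every detectable problem is reported in one exception rather than
    failing on the first.
    """
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise InvalidArgumentError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            errors.append(f"unknown key {key!r}")
    for key in _REQUIRED_KEYS:
        if key not in raw:
            errors.append(f"missing required key {key!r}")
    for key in ("grid", "sites", "counts"):
        if key in raw and not Path(raw[key]).exists():
            errors.append(f"{key}: file {raw[key]!r} does not exist")
    if "seed" in raw and not isinstance(raw["seed"], int):
        errors.append("seed must be an explicit integer")
    for key in ("r_min", "r_max", "r_step", "min_fraction", "apriori_scale"):
        if key in raw and not isinstance(raw[key], (int, float)):
            errors.append(f"{key} must be numeric")
    if isinstance(raw.get("bootstrap_b"), int) and raw["bootstrap_b"] < 1:
        errors.append("bootstrap_b must be >= 1")
    if all(isinstance(raw.get(k, 0), (int, float)) for k in ("r_min", "r_max", "r_step")):
        r_min = raw.get("r_min", 150.0)
        r_max = raw.get("r_max", 5000.0)
        r_step = raw.get("r_step", 10.0)
        if r_min <= 0 or r_step <= 0 or r_max <= r_min:
            errors.append("radius series requires 0 < r_min < r_max and step > 0")
        else:
            apriori = raw.get("apriori_scale", APRIORI_SCALE)
            if isinstance(apriori, (int, float)) and not (r_min <= apriori < r_max):
                errors.append(
                    f"apriori_scale {apriori} lies outside the radius span "
                    f"[{r_min}, {r_max})"
                )
    mf = raw.get("min_fraction", 0.97)
    if isinstance(mf, (int, float)) and not 0 < mf <= 1:
        errors.append("min_fraction must lie in (0, 1]")
    if errors:
        raise InvalidArgumentError(
            f"{path}: invalid run config:\n  - " + "\n  - ".join(errors)
        )
    kwargs = dict(raw)
    for key in ("grid", "sites", "counts", "out_dir"):
        kwargs[key] = Path(kwargs[key])
    return RunConfig(**kwargs)


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def _slug(name: str) -> str:
    return name.replace(":", "_").replace("/", "_").replace(" ", "_")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all artifacts.

    Returns the run manifest (also written to ``manifest.json``).  Any
    stage failure aborts the run with the stage name in the message and a
    ``FAILED.txt`` flag in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counter = _WarningCounter()
    root = logging.getLogger("scaleofeffect")
    root.addHandler(counter)
    stage = "setup"
    try:
        stage = "read inputs"
        grid = read_grid(config.grid)
        sites = read_sites(config.sites)
        counts = read_counts(config.counts)
        if config.sessions_keep:
            counts = subset_sessions(counts, config.sessions_keep)

        stage = "responses"
        responses: list[pd.Series] = []
        if config.include_shannon:
            responses.append(shannon_response(counts))
        if config.abundance_taxa == "common":
            taxa = filter_common_taxa(counts, config.min_fraction)
        else:
            taxa = list(config.abundance_taxa)
        for taxon in taxa:
            responses.append(abundance_response(counts, sites, taxon))
        resp_frame = pd.concat(
            [r.rename("value").to_frame().assign(response_kind=r.name) for r in responses]
        )
        resp_frame.index.name = "site_id"
        resp_frame.reset_index()[["site_id", "response_kind", "value"]].to_csv(
            out / "responses.csv", index=False
        )

        stage = "cover extraction"
        radii = make_radius_series(config.r_min, config.r_max, config.r_step)
        profile = build_cover_profile(grid, sites, radii)
        profile.to_csv(out / "cover_profile.csv")

        stage = "scale selection"
        (out / "profiles").mkdir(exist_ok=True)
        (out / "bootstrap").mkdir(exist_ok=True)
        seed_root = np.random.SeedSequence(config.seed)
        selected_rows = []
        boot_summary_rows = []
        profiles = {}
        for resp in responses:
            for comp in COMPONENTS:
                sp = scale_profile(profile, resp, comp)
                profiles[(resp.name, comp)] = sp
                sp.to_frame().to_csv(
                    out / "profiles" / f"{_slug(resp.name)}__{comp}.csv", index=False
                )
                selected_rows.append((comp, resp.name, sp.selected_scale))
        stage = "bootstrap"
        for (resp_name, comp), sp in profiles.items():
            resp = next(r for r in responses if r.name == resp_name)
            child_seed = int(seed_root.spawn(1)[0].generate_state(1)[0] % (2**31))
            dist = bootstrap_scale(
                profile, resp, comp, B=config.bootstrap_b, seed=child_seed
            )
            dist.to_frame().to_csv(
                out / "bootstrap" / f"{_slug(resp_name)}__{comp}.csv", index=False
            )
            lo, hi = dist.central_interval()
            boot_summary_rows.append(
                (comp, resp_name, dist.B, dist.mode, lo, hi, dist.n_redraws)
            )
        pd.DataFrame(
            selected_rows, columns=["component", "response_kind", "selected_scale_m"]
        ).to_csv(out / "selected_scales.csv", index=False)
        pd.DataFrame(
            boot_summary_rows,
            columns=["component", "response_kind", "B", "mode_m",
                     "ci_low_m", "ci_high_m", "n_redraws"],
        ).to_csv(out / "bootstrap_summary.csv", index=False)

        stage = "effect models"
        eff_sel = []
        eff_apriori = []
        for resp in responses:
            scales = {
                comp: profiles[(resp.name, comp)].selected_scale
                for comp in COMPONENTS
            }
            eff_sel.append(fit_effects_at_scales(profile, resp, scales))
            eff_apriori.append(
                fit_effects_apriori(profile, resp, config.apriori_scale)
            )
        effects_selected = pd.concat(eff_sel, ignore_index=True)
        effects_apriori = pd.concat(eff_apriori, ignore_index=True)
        effects_selected.to_csv(out / "effects_selected_scales.csv", index=False)
        effects_apriori.to_csv(out / "effects_apriori.csv", index=False)

        if config.figures:
            stage = "figures"
            from . import viz

            (out / "figures").mkdir(exist_ok=True)
            for (resp_name, comp), sp in profiles.items():
                viz.plot_scale_profile(
                    sp, out / "figures" / f"profile_{_slug(resp_name)}__{comp}.png"
                )
            viz.plot_effect_sizes(
                effects_selected, out / "figures" / "effects_selected.png"
            )
            viz.plot_effect_sizes(
                effects_apriori, out / "figures" / "effects_apriori.png"
            )

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": {
                k: str(v) if isinstance(v, Path) else v
                for k, v in vars(config).items()
            },
            "n_sites": int(len(sites)),
            "n_radii": int(radii.size),
            "responses": [r.name for r in responses],
            "selected_scales": {
                f"{rn}|{c}": sp.selected_scale for (rn, c), sp in profiles.items()
            },
            "warnings": counter.messages,
        }
        with (out / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except ScaleOfEffectError as exc:
        (out / "FAILED.txt").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(counter)
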