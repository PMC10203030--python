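"""R² profiles, argmax scale selection and bootstrap uncertainty."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from scaleofeffect.errors import AlignmentError, InvalidArgumentError
from scaleofeffect.landscape import CoverProfile
from scaleofeffect.scale_selection import (
    bootstrap_scale,
    r2_simple,
    scale_profile,
    select_scale,
)
from scaleofeffect.synthetic import simulate_dataset, single_component_config


def toy_profile(rng, n_sites=10, radii=(100.0, 200.0, 300.0, 400.0, 500.0)):
    """A random cover profile with simplex-valued class proportions."""
    raw = rng.dirichlet(np.ones(4), size=(n_sites, len(radii)))
    return CoverProfile(
        site_ids=tuple(f"s{i}" for i in range(n_sites)),
        radii=np.asarray(radii, dtype=float),
        classes=("forest", "urban", "agriculture", "other"),
        proportions=raw,
    )


class TestR2Simple:
    def test_perfect_linear_fit(self):
        x = np.arange(5.0)
        assert r2_simple(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_predictor_is_zero(self):
        assert r2_simple(np.ones(6), np.arange(6.0)) == 0.0

    def test_matches_squared_pearson(self, rng):
        for _ in range(10):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            r, _ = scipy.stats.pearsonr(x, y)
            assert r2_simple(x, y) == pytest.approx(r**2, abs=1e-12)

    @pytest.mark.parametrize(
        "x, y",
        [([1, 2], [3, 4]), ([1, 2, 3], [5, 5, 5])],
    )
    def test_preconditions(self, x, y):
        with pytest.raises(InvalidArgumentError):
            r2_simple(np.asarray(x, float), np.asarray(y, float))

    @given(
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-10, 10),
        c=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        d=st.floats(-10, 10),
    )
    def test_affine_invariance(self, a, b, c, d):
        rng = np.random.default_rng(42)
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        assert r2_simple(a * x + b, c * y + d) == pytest.approx(
            r2_simple(x, y), abs=1e-9
        )


class TestSelectScale:
    def test_unique_maximum(self):
        assert select_scale({150: 0.2, 200: 0.9, 250: 0.5}) == 200

    def test_tie_breaks_to_smallest_radius(self):
        assert select_scale({200: 0.4, 150: 0.4}) == 150

    def test_empty_profile_is_an_error(self):
        with pytest.raises(InvalidArgumentError):
            select_scale({})

    def test_matches_linear_scan_argmax(self, rng):
        radii = np.arange(150.0, 5000.0, 10.0)
        for _ in range(5):
            r2 = rng.uniform(0, 1, size=radii.size)
            # independent oracle: explicit scan keeping the first maximum
            best = radii[0]
            best_v = r2[0]
            for r, v in zip(radii[1:], r2[1:]):
                if v > best_v:
                    best, best_v = r, v
            assert select_scale(pd.Series(r2, index=radii)) == best


class TestScaleProfile:
    def test_planted_noise_free_signal(self, rng):
        prof = toy_profile(rng, n_sites=12)
        y = pd.Series(
            prof.column("urban", 300.0).to_numpy() * 3.0 - 1.0,
            index=list(prof.site_ids),
            name="resp",
        )
        sp = scale_profile(prof, y, "urban")
        assert sp.selected_scale == 300.0
        assert sp.r2[np.flatnonzero(prof.radii == 300.0)[0]] == pytest.approx(1.0, abs=1e-12)

    def test_matches_per_radius_refits(self, rng):
        prof = toy_profile(rng)
        y = pd.Series(rng.normal(size=10), index=list(prof.site_ids), name="resp")
        sp = scale_profile(prof, y, "forest")
        for j, r in enumerate(prof.radii):
            expected = r2_simple(
                prof.column("forest", r).to_numpy(), y.to_numpy()
            )
            assert sp.r2[j] == pytest.approx(expected, abs=1e-12)

    def test_constant_cover_gives_flat_profile_and_smallest_radius(self, rng):
        n, R = 8, 4
        props = np.zeros((n, R, 4))
        props[:, :, 0] = 1.0  # all-forest everywhere
        prof = CoverProfile(
            tuple(f"s{i}" for i in range(n)),
            np.array([100.0, 200.0, 300.0, 400.0]),
            ("forest", "urban", "agriculture", "other"),
            props,
        )
        y = pd.Series(rng.normal(size=n), index=list(prof.site_ids), name="resp")
        sp = scale_profile(prof, y, "forest")
        assert np.all(sp.r2 == 0)
        assert sp.selected_scale == 100.0

    def test_site_mismatch_is_an_alignment_error(self, rng):
        prof = toy_profile(rng)
        y = pd.Series([1.0, 2.0, 3.0], index=["s0", "s1", "zzz"], name="resp")
        with pytest.raises(AlignmentError, match="s2"):
            scale_profile(prof, y, "forest")

    def test_recovers_planted_scale_on_synthetic_landscape(self):
        config = single_component_config(
            "forest", 800.0, 1.0, snr=10.0, r_max=1050.0, buffer_margin=1000.0,
            n_cells=200,
        )
        _, _, profile, sim = simulate_dataset(config, seed=5)
        sp = scale_profile(profile, sim.response, "forest")
        assert abs(sp.selected_scale - 800.0) <= 2 * config.r_step


class TestBootstrap:
    def test_deterministic_under_seed(self, rng):
        prof = toy_profile(rng)
        y = pd.Series(rng.normal(size=10), index=list(prof.site_ids), name="resp")
        d1 = bootstrap_scale(prof, y, "urban", B=40, seed=9)
        d2 = bootstrap_scale(prof, y, "urban", B=40, seed=9)
        assert np.array_equal(d1.scales, d2.scales)

    def test_noise_free_signal_degenerate_distribution(self, rng):
        prof = toy_profile(rng, n_sites=12)
        y = pd.Series(
            prof.column("agriculture", 400.0).to_numpy(),
            index=list(prof.site_ids),
            name="resp",
        )
        dist = bootstrap_scale(prof, y, "agriculture", B=50, seed=1)
        assert np.all(dist.scales == 400.0)
        assert dist.mode == 400.0 == dist.full_data_scale

    def test_matches_independent_resampling_loop(self, rng):
        """From-scratch reimplementation with the same generator algorithm."""
        prof = toy_profile(rng, n_sites=9)
        y = pd.Series(rng.normal(size=9), index=list(prof.site_ids), name="resp")
        B, seed = 30, 123
        dist = bootstrap_scale(prof, y, "forest", B=B, seed=seed)

        X = prof.matrix("forest").to_numpy()
        yv = y.to_numpy()
        oracle_rng = np.random.default_rng(seed)
        expected = []
        while len(expected) < B:
            idx = oracle_rng.integers(0, 9, size=9)
            if np.unique(idx).size < 3 or np.var(yv[idx]) == 0:
                continue
            r2s = [r2_simple(X[idx, j], yv[idx]) for j in range(X.shape[1])]
            expected.append(select_scale(pd.Series(r2s, index=prof.radii)))
        assert np.allclose(dist.scales, expected)

    def test_invalid_b(self, rng):
        prof = toy_profile(rng)
        y = pd.Series(rng.normal(size=10), index=list(prof.site_ids), name="resp")
        with pytest.raises(InvalidArgumentError):
            bootstrap_scale(prof, y, "forest", B=0, seed=1)
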