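"""Analytic bodies, Debye evaluation, fitting, mixtures, SVD counting."""

import warnings

import numpy as np
import pytest
from scipy.optimize import brentq

from saskit.curve import ScatteringCurve
from saskit.formfactors import (
    Body,
    MixtureComponent,
    MixtureModel,
    SizeDispersion,
    body_intensity,
    body_volume,
    build_formfactor_table,
    debye_intensity,
    fit_body,
    fit_mixture,
    mixture_intensity,
    oligomer_fractions,
    svd_rank,
)
from saskit.io import read_bead_model, write_bead_model, write_formfactor_table, read_formfactor_table
from saskit.synthetic import NoiseModel, bead_sphere, simulate_curve


S_GRID = np.linspace(0.0, 0.4, 150)


class TestBodyIntensity:
    def test_sphere_value_at_x_pi(self):
        # normalized sphere amplitude at sR = pi: (3/pi^2)^2
        r = 30.0
        c = body_intensity(Body("sphere", {"radius": r}), np.array([0.0, np.pi / r]))
        assert c.i[1] == pytest.approx((3 / np.pi**2) ** 2, rel=1e-10)

    @pytest.mark.parametrize(
        "body",
        [
            Body("sphere", {"radius": 30.0}),
            Body("cylinder", {"radius": 20.0, "length": 100.0}),
            Body("ellipsoid_of_revolution", {"equatorial_radius": 25.0, "axial_ratio": 2.0}),
            Body("parallelepiped", {"a": 40.0, "b": 60.0, "c": 80.0}),
            Body("dumbbell", {"radius1": 15.0, "radius2": 15.0, "separation": 60.0}),
            Body(
                "core_shell_sphere",
                {"core_radius": 20.0, "shell_radius": 30.0, "core_contrast": 1.0, "shell_contrast": -0.5},
            ),
            Body(
                "core_shell_cylinder",
                {"core_radius": 15.0, "shell_radius": 20.0, "length": 80.0, "core_contrast": 1.0, "shell_contrast": 0.5},
            ),
        ],
        ids=lambda b: b.kind,
    )
    def test_normalized_forward_intensity_is_one(self, body):
        c = body_intensity(body, np.array([0.0, 0.01]))
        assert c.i[0] == pytest.approx(1.0, rel=1e-9)

    def test_absolute_forward_intensity_is_volume_squared(self):
        body = Body("cylinder", {"radius": 20.0, "length": 100.0})
        c = body_intensity(body, np.array([0.0, 1e-4]), normalized=False)
        assert c.i[0] == pytest.approx(body_volume(body) ** 2, rel=1e-9)

    def test_ellipsoid_ratio_one_degenerates_to_sphere(self):
        e = body_intensity(
            Body("ellipsoid_of_revolution", {"equatorial_radius": 25.0, "axial_ratio": 1.0}), S_GRID
        )
        s = body_intensity(Body("sphere", {"radius": 25.0}), S_GRID)
        np.testing.assert_allclose(e.i, s.i, rtol=1e-6, atol=1e-12)

    def test_quadrature_converged_at_default_order(self):
        body = Body("cylinder", {"radius": 20.0, "length": 100.0})
        c1 = body_intensity(body, S_GRID)
        c2 = body_intensity(body, S_GRID, quadrature_order=2048)
        assert np.abs(c1.i - c2.i).max() < 1e-6 * c1.i.max()

    def test_sphere_first_minimum_at_root_of_tan(self):
        # root-finding oracle: first minimum where tan x = x
        x_min = brentq(lambda x: np.tan(x) - x, np.pi / 2 + 1e-6, 1.5 * np.pi - 1e-6)
        assert x_min == pytest.approx(4.4934, abs=1e-3)
        r = 30.0
        xs = np.linspace(3.5, 5.5, 4001)
        c = body_intensity(Body("sphere", {"radius": r}), xs / r)
        assert xs[np.argmin(c.i)] == pytest.approx(x_min, abs=1e-3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            Body("sphere", {"radius": -5.0})
        with pytest.raises(ValueError, match="shell"):
            Body(
                "core_shell_sphere",
                {"core_radius": 30.0, "shell_radius": 20.0, "core_contrast": 1.0, "shell_contrast": 1.0},
            )
        with pytest.raises(ValueError, match="kind"):
            Body("torus", {"radius": 5.0})


class TestDebye:
    def test_single_point_unit_intensity(self):
        c = debye_intensity(np.array([[0.0, 0.0, 0.0]]), np.array([1.0]), S_GRID)
        np.testing.assert_allclose(c.i, 1.0)

    def test_two_points_coherent_limit(self):
        pts = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        c = debye_intensity(pts, np.ones(2), np.array([1e-9, 0.1]))
        assert c.i[0] == pytest.approx(4.0, rel=1e-9)

    def test_bead_sphere_matches_analytic(self):
        pts, w = bead_sphere(30.0, 2.2, seed=1)
        assert len(pts) >= 3000
        s = np.linspace(0.004, 4.0 / 30.0, 60)
        dc = debye_intensity(pts, w, s)
        an = body_intensity(Body("sphere", {"radius": 30.0}), s)
        rel = np.abs(dc.i / dc.i[0] - an.i) / an.i
        assert rel.max() < 0.02

    def test_histogram_path_agrees_with_direct_sum(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-20, 20, (1600, 3))  # just above the direct-path cutoff
        s = np.linspace(0.01, 0.3, 20)
        fast = debye_intensity(pts, None, s)
        iu, ju = np.triu_indices(len(pts), k=1)
        d = np.sqrt(((pts[iu] - pts[ju]) ** 2).sum(axis=1))
        direct = np.array(
            [len(pts) + 2 * np.sinc(sk * d / np.pi).sum() for sk in s]
        )
        np.testing.assert_allclose(fast.i, direct, rtol=1e-6)


class TestBeadModelIO:
    def test_round_trip_preserves_coordinates(self, tmp_path):
        pts, _ = bead_sphere(15.0, 4.0, seed=2)
        path = tmp_path / "beads.pdb"
        write_bead_model(pts, path)
        back, weights = read_bead_model(path)
        assert len(back) == len(pts)
        np.testing.assert_allclose(back, pts, atol=1e-3)
        np.testing.assert_array_equal(weights, 1.0)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(ValueError, match="ATOM"):
            read_bead_model(path)


class TestFitBody:
    @pytest.fixture(scope="class")
    @staticmethod
    def sphere_data():
        s = np.linspace(0.004, 0.4, 200)
        return simulate_curve(Body("sphere", {"radius": 30.0}), s, NoiseModel(relative_level=0.0))

    def test_sphere_recovered(self, sphere_data):
        body, chi2 = fit_body(sphere_data, "sphere", n_restarts=3, seed=3)
        assert body.params["radius"] == pytest.approx(30.0, rel=0.005)

    def test_far_init_rescued_by_restarts(self, sphere_data):
        body, _ = fit_body(sphere_data, "sphere", init={"radius": 300.0}, n_restarts=5, seed=3)
        assert body.params["radius"] == pytest.approx(30.0, rel=0.01)

    def test_wrong_model_fits_worse(self, sphere_data):
        _, chi2_sphere = fit_body(sphere_data, "sphere", n_restarts=3, seed=3)
        _, chi2_cyl = fit_body(sphere_data, "cylinder", n_restarts=3, seed=3)
        assert chi2_cyl > chi2_sphere

    def test_deterministic_given_seed(self, sphere_data):
        b1, c1 = fit_body(sphere_data, "sphere", n_restarts=3, seed=9)
        b2, c2 = fit_body(sphere_data, "sphere", n_restarts=3, seed=9)
        assert b1.params == b2.params
        assert c1 == c2


class TestMixture:
    def test_single_component_fractions(self):
        f1 = body_intensity(Body("sphere", {"radius": 20.0}), S_GRID).i
        m = MixtureModel(
            [
                MixtureComponent(Body("sphere", {"radius": 20.0}), 1.0),
                MixtureComponent(Body("sphere", {"radius": 50.0}), 0.0),
            ]
        )
        np.testing.assert_allclose(mixture_intensity(m, S_GRID).i, f1, rtol=1e-12)

    def test_linearity_in_fractions(self):
        f1 = body_intensity(Body("sphere", {"radius": 20.0}), S_GRID).i
        f2 = body_intensity(Body("sphere", {"radius": 50.0}), S_GRID).i
        m = MixtureModel(
            [
                MixtureComponent(Body("sphere", {"radius": 20.0}), 0.3),
                MixtureComponent(Body("sphere", {"radius": 50.0}), 0.7),
            ]
        )
        np.testing.assert_allclose(mixture_intensity(m, S_GRID).i, 0.3 * f1 + 0.7 * f2, rtol=1e-12)

    def test_zero_dispersion_equals_body_intensity(self):
        body = Body("sphere", {"radius": 30.0})
        m = MixtureModel(
            [MixtureComponent(body, 1.0, dispersion=SizeDispersion("gaussian", 0.0))]
        )
        np.testing.assert_allclose(
            mixture_intensity(m, S_GRID).i, body_intensity(body, S_GRID).i, rtol=1e-12
        )

    def test_dispersion_smears_minima(self):
        body = Body("sphere", {"radius": 30.0})
        sharp = mixture_intensity(MixtureModel([MixtureComponent(body, 1.0)]), S_GRID).i
        wide = mixture_intensity(
            MixtureModel(
                [MixtureComponent(body, 1.0, dispersion=SizeDispersion("gaussian", 0.15))]
            ),
            S_GRID,
        ).i
        assert wide[sharp < 1e-6].min() > sharp[sharp < 1e-6].min()

    def test_component_limit_enforced(self):
        comps = [MixtureComponent(Body("sphere", {"radius": 10.0 + k}), 0.1) for k in range(11)]
        with pytest.raises(ValueError, match="component limit"):
            MixtureModel(comps)

    def test_fit_mixture_recovers_fractions_and_radii(self):
        s = np.linspace(0.004, 0.4, 200)
        f1 = body_intensity(Body("sphere", {"radius": 20.0}), s).i
        f2 = body_intensity(Body("sphere", {"radius": 50.0}), s).i
        data = 0.4 * f1 + 0.6 * f2
        rng = np.random.default_rng(5)
        sigma = 0.01 * np.abs(data)
        noisy = ScatteringCurve(s=s, i=data + rng.normal(0, 1, len(s)) * sigma, sigma=sigma)
        template = MixtureModel(
            [
                MixtureComponent(Body("sphere", {"radius": 25.0}), 0.5),
                MixtureComponent(Body("sphere", {"radius": 45.0}), 0.5),
            ]
        )
        fitted, _ = fit_mixture(
            noisy, template, free_params=[["radius"], ["radius"]], seed=5
        )
        radii = sorted(c.body.params["radius"] for c in fitted.components)
        fracs = [c.fraction for c in fitted.components]
        assert radii[0] == pytest.approx(20.0, rel=0.03)
        assert radii[1] == pytest.approx(50.0, rel=0.03)
        assert min(fracs) == pytest.approx(0.4, abs=0.05)


class TestOligomer:
    @pytest.fixture(scope="class")
    @staticmethod
    def components():
        f1 = body_intensity(Body("sphere", {"radius": 20.0}), S_GRID, normalized=False).i
        f2 = body_intensity(Body("sphere", {"radius": 50.0}), S_GRID, normalized=False).i
        return f1, f2

    def test_exact_linear_recovery(self, components):
        f1, f2 = components
        data = 0.3 * f1 + 0.7 * f2
        c = ScatteringCurve(s=S_GRID, i=data, sigma=0.01 * np.abs(data) + 1e-9)
        res = oligomer_fractions(c, [f1, f2])
        np.testing.assert_allclose(res.fractions, [0.3, 0.7], atol=1e-6)
        assert res.chi2_reduced < 1e-10

    def test_matches_grid_search_oracle_under_noise(self, components):
        f1, f2 = components
        rng = np.random.default_rng(21)
        data = 0.3 * f1 + 0.7 * f2
        sigma = 0.01 * np.abs(data) + 1e-9
        noisy = data + rng.normal(0, 1, len(data)) * sigma
        c = ScatteringCurve(s=S_GRID, i=noisy, sigma=sigma)
        res = oligomer_fractions(c, [f1, f2], normalize=True)
        # exhaustive 0.01-step simplex scan
        grid = np.arange(0.0, 1.0001, 0.01)
        chis = [(((w * f1 + (1 - w) * f2 - noisy) / sigma) ** 2).sum() for w in grid]
        w_best = grid[int(np.argmin(chis))]
        assert abs(res.fractions[0] - w_best) <= 0.01 + 1e-9

    def test_unphysical_data_hit_boundary(self, components):
        f1, _ = components
        c = ScatteringCurve(s=S_GRID, i=-f1, sigma=0.01 * f1 + 1e-9)
        res = oligomer_fractions(c, [f1])
        assert res.fractions[0] == 0.0

    def test_duplicate_component_warns_rank_deficient(self, components):
        f1, f2 = components
        data = f1 + f2
        c = ScatteringCurve(s=S_GRID, i=data, sigma=0.01 * np.abs(data) + 1e-9)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            res = oligomer_fractions(c, [f1, f1])
        assert res.rank_deficient
        assert any("rank deficient" in str(w.message) for w in rec)


class TestFormfactorTable:
    def test_schema_and_round_trip(self, tmp_path):
        bodies = [Body("sphere", {"radius": r}) for r in (15.0, 25.0, 40.0)]
        s, cols = build_formfactor_table(bodies, S_GRID)
        assert len(cols) == 3
        path = tmp_path / "table.dat"
        write_formfactor_table(s, cols, path)
        first_row = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")][0]
        assert len(first_row.split()) == 4
        s_back, cols_back = read_formfactor_table(path)
        np.testing.assert_allclose(s_back, s, rtol=1e-6, atol=1e-12)
        for a, b in zip(cols, cols_back):
            np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_body_column_equals_body_intensity(self):
        body = Body("sphere", {"radius": 25.0})
        _, cols = build_formfactor_table([body], S_GRID)
        np.testing.assert_allclose(cols[0], body_intensity(body, S_GRID, normalized=False).i)


class TestSvdRank:
    @staticmethod
    def component_series(n_curves=10, seed=2, noise=0.0):
        rng = np.random.default_rng(seed)
        f = [
            body_intensity(Body("sphere", {"radius": 20.0}), S_GRID, normalized=False).i,
            body_intensity(Body("sphere", {"radius": 50.0}), S_GRID, normalized=False).i,
            body_intensity(Body("cylinder", {"radius": 15.0, "length": 80.0}), S_GRID, normalized=False).i,
        ]
        curves = []
        for _ in range(n_curves):
            w = rng.dirichlet([1.0, 1.0, 1.0])
            mix = w @ np.array(f)
            sigma = np.full(len(S_GRID), max(noise, 1e-6) * np.abs(mix).mean())
            i_obs = mix + (rng.normal(0, 1, len(S_GRID)) * sigma if noise > 0 else 0.0)
            curves.append(ScatteringCurve(s=S_GRID, i=i_obs, sigma=sigma))
        return curves

    def test_three_components_counted_exactly(self):
        res = svd_rank(self.component_series(), seed=9)
        assert res.n_significant == 3
        sv = res.singular_values
        assert sv[3] / sv[0] < 1e-8

    def test_pure_noise_counts_zero(self):
        rng = np.random.default_rng(9)
        curves = [
            ScatteringCurve(s=S_GRID, i=rng.normal(0, 1, len(S_GRID)), sigma=np.ones(len(S_GRID)))
            for _ in range(10)
        ]
        assert svd_rank(curves, seed=9).n_significant == 0

    def test_scale_invariance_under_sigma_normalization(self):
        curves = self.component_series()
        scaled = [c.copy(i=10 * c.i, sigma=10 * c.sigma) for c in curves]
        assert (
            svd_rank(curves, seed=9).n_significant
            == svd_rank(scaled, seed=9).n_significant
        )
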