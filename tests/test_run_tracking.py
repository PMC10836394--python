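"""Iteration series, class distributions, FSC and angular histograms."""

import numpy as np
import pytest

from emlive import fixtures as fx
from emlive.run_tracking import (
    TrackingError,
    angular_histogram,
    class_distribution,
    discover_iterations,
    extract_series,
    fsc_crossing,
    job_backlog,
    model_spectra,
)
from emlive.star_io import StarLookupError


@pytest.fixture(scope="module")
def run_project(tmp_path_factory):
    """Project with planted classification series for exact recovery."""
    root = tmp_path_factory.mktemp("runproj") / "proj"
    plan = fx.RunPlan(
        kind="Class2D",
        n_classes=3,
        n_iterations=4,
        changes_optimal_classes=[0.9, 0.5, 0.2, 0.05],
        current_resolution=[12.0, 8.0, 5.0, 4.0],
        class_distributions=[
            [0.4, 0.35, 0.25],
            [0.5, 0.3, 0.2],
            [0.6, 0.25, 0.15],
            [0.7, 0.2, 0.1],
        ],
    )
    spec = fx.FixtureSpec(seed=2, n_micrographs=3, write_images=False,
                          run_plan=plan)
    fx.make_project(spec, root)
    return root / "Class2D/job005"


class TestDiscoverIterations:
    def test_all_pairs_found_in_order(self, run_project):
        triples = discover_iterations(run_project)
        assert [t[0] for t in triples] == [0, 1, 2, 3]
        for _, model, opt in triples:
            assert model.exists() and opt.exists()

    def test_empty_directory(self, tmp_path):
        assert discover_iterations(tmp_path) == []

    def test_incomplete_pair_excluded(self, tmp_path, caplog):
        (tmp_path / "run_it000_model.star").write_text("data_x\n_a 1\n")
        (tmp_path / "run_it000_optimiser.star").write_text("data_x\n_a 1\n")
        (tmp_path / "run_it001_optimiser.star").write_text("data_x\n_a 1\n")
        triples = discover_iterations(tmp_path)
        assert [t[0] for t in triples] == [0]


class TestExtractSeries:
    def test_planted_changes_recovered_exactly(self, run_project):
        series = extract_series(run_project, "ChangesOptimalClasses")
        assert series.iterations == [0, 1, 2, 3]
        assert series.values == [0.9, 0.5, 0.2, 0.05]

    def test_planted_resolution_from_model_files(self, run_project):
        # CurrentResolution lives in the model file pairs, found after
        # the optimiser files are searched
        series = extract_series(run_project, "CurrentResolution")
        assert series.values == [12.0, 8.0, 5.0, 4.0]

    def test_single_iteration(self, tmp_path):
        plan = fx.RunPlan(n_iterations=1,
                          changes_optimal_classes=[0.33])
        fx.make_project(
            fx.FixtureSpec(seed=1, n_micrographs=2, write_images=False,
                           run_plan=plan),
            tmp_path / "p",
        )
        series = extract_series(tmp_path / "p/Class2D/job005",
                                "ChangesOptimalClasses")
        assert series.iterations == [0] and series.values == [0.33]

    def test_unknown_label_lists_available(self, run_project):
        with pytest.raises(StarLookupError, match="ChangesOptimalClasses"):
            extract_series(run_project, "NoSuchLabel")


class TestClassDistribution:
    def test_planted_matrix_recovered_exactly(self, run_project):
        matrix = class_distribution(run_project)
        assert matrix.iterations == [0, 1, 2, 3]
        assert matrix.classes == [1, 2, 3]
        np.testing.assert_array_equal(
            matrix.fractions[-1], [0.7, 0.2, 0.1]
        )

    def test_rows_sum_to_one(self, run_project):
        matrix = class_distribution(run_project)
        np.testing.assert_allclose(matrix.fractions.sum(axis=1), 1.0,
                                   atol=1e-6)

    def test_single_class_all_ones(self, tmp_path):
        plan = fx.RunPlan(n_classes=1, n_iterations=3)
        fx.make_project(
            fx.FixtureSpec(seed=4, n_micrographs=2, write_images=False,
                           run_plan=plan),
            tmp_path / "p",
        )
        matrix = class_distribution(tmp_path / "p/Class2D/job005")
        np.testing.assert_array_equal(matrix.fractions, 1.0)

    def test_random_planted_simplex_rows(self, tmp_path, rng):
        rows = rng.dirichlet(np.ones(4), size=5).tolist()
        plan = fx.RunPlan(n_classes=4, n_iterations=5,
                          class_distributions=rows)
        fx.make_project(
            fx.FixtureSpec(seed=5, n_micrographs=2, write_images=False,
                           run_plan=plan),
            tmp_path / "p",
        )
        matrix = class_distribution(tmp_path / "p/Class2D/job005")
        np.testing.assert_allclose(matrix.fractions.sum(axis=1), 1.0,
                                   atol=1e-6)
        # the generator quantizes fractions to the 6-decimal STAR format
        # and rebalances the last class so each row sums to exactly 1
        np.testing.assert_allclose(matrix.fractions, rows, atol=2e-6)


class TestModelSpectra:
    def test_planted_fsc_recovered_point_for_point(self, tmp_path):
        fsc = [(0.05 * k, round(1.0 - 0.09 * k, 6)) for k in range(1, 10)]
        plan = fx.RunPlan(n_classes=2, n_iterations=2, fsc=fsc)
        fx.make_project(
            fx.FixtureSpec(seed=6, n_micrographs=2, write_images=False,
                           run_plan=plan),
            tmp_path / "p",
        )
        curves = model_spectra(
            tmp_path / "p/Class2D/job005/run_it001_model.star",
            "GoldStandardFsc",
        )
        assert len(curves) == 2
        freqs, values = curves[0]
        np.testing.assert_array_equal(freqs, [fx.quantize(f) for f, _ in fsc])
        np.testing.assert_array_equal(values, [v for _, v in fsc])

    def test_one_curve_per_class(self, run_project):
        curves = model_spectra(run_project / "run_it003_model.star",
                               "SpectralOrientabilityContribution")
        assert len(curves) == 3

    def test_unknown_label_raises(self, run_project):
        with pytest.raises(StarLookupError):
            model_spectra(run_project / "run_it000_model.star", "NoSuchLabel")


class TestFscCrossing:
    def test_linear_curve_closed_form(self):
        # FSC falling linearly from 1 at f=0 to 0 at f=0.5:
        # crossing of 0.143 at f = 0.5 * (1 - 0.143)
        curve = [(0.0, 1.0), (0.5, 0.0)]
        result = fsc_crossing(curve, threshold=0.143)
        assert not result.at_nyquist
        assert result.resolution == pytest.approx(1.0 / (0.5 * (1 - 0.143)),
                                                  rel=1e-9)

    def test_constant_one_flags_at_nyquist(self):
        curve = [(0.1, 1.0), (0.3, 1.0), (0.5, 1.0)]
        result = fsc_crossing(curve, threshold=0.143)
        assert result.at_nyquist
        assert result.resolution == pytest.approx(2.0)

    def test_exact_sample_crossing(self):
        curve = [(0.1, 1.0), (0.2, 0.143), (0.3, 0.0)]
        result = fsc_crossing(curve, threshold=0.143)
        assert result.resolution == pytest.approx(5.0)

    def test_non_monotonic_frequencies_rejected(self):
        with pytest.raises(TrackingError, match="increasing"):
            fsc_crossing([(0.2, 1.0), (0.1, 0.0)])

    def test_piecewise_linear_agrees_with_closed_form(self, rng):
        for _ in range(10):
            f0, f1 = 0.05, float(rng.uniform(0.3, 0.5))
            v0, v1 = float(rng.uniform(0.5, 1.0)), float(rng.uniform(0, 0.1))
            thr = float(rng.uniform(v1 + 0.01, v0 - 0.01))
            f_cross = f0 + (v0 - thr) / (v0 - v1) * (f1 - f0)
            result = fsc_crossing([(f0, v0), (f1, v1)], threshold=thr)
            assert result.resolution == pytest.approx(1.0 / f_cross,
                                                      rel=1e-9)


class TestAngularHistogram:
    def _particles(self, rot, tilt):
        from emlive.star_io import LoopTable

        return LoopTable(
            ["_rlnAngleRot", "_rlnAngleTilt"],
            [(float(r), float(t)) for r, t in zip(rot, tilt)],
        )

    def test_single_particle_single_cell(self):
        hist = angular_histogram(self._particles([0.0], [90.0]))
        assert hist.n_particles == 1
        assert (hist.counts > 0).sum() == 1

    def test_matches_brute_force_binning(self, rng):
        n = 10_000
        rot = rng.uniform(-180, 180, n)
        tilt = rng.uniform(0, 180, n)
        hist = angular_histogram(self._particles(rot, tilt),
                                 n_rot_bins=72, n_tilt_bins=36)
        # brute-force oracle with explicit last-bin-inclusive rule
        counts = np.zeros((72, 36), dtype=int)
        for r, t in zip(rot, tilt):
            i = min(int((r + 180) / 5.0), 71)
            j = min(int(t / 5.0), 35)
            counts[i, j] += 1
        np.testing.assert_array_equal(hist.counts, counts)

    def test_count_conserved_for_any_binning(self, rng):
        n = 500
        rot = rng.uniform(-180, 180, n)
        tilt = rng.uniform(0, 180, n)
        table = self._particles(rot, tilt)
        for bins in [(72, 36), (10, 7), (1, 1)]:
            hist = angular_histogram(table, *bins)
            assert hist.n_particles == n

    def test_edge_values_fall_in_last_bin(self):
        hist = angular_histogram(self._particles([180.0], [180.0]))
        assert hist.counts[-1, -1] == 1

    def test_out_of_range_angles_listed(self):
        with pytest.raises(TrackingError, match=r"\[1\]"):
            angular_histogram(self._particles([0.0, 200.0], [90.0, 90.0]))

    def test_two_optics_groups_occupy_different_tilt_bands(self, rng):
        # untilted vs 40°-tilted collections land in distinct tilt bands
        particles = fx.make_particles(
            2000,
            [(0.5, 90.0, 3.0), (0.5, 50.0, 3.0)],
            seed=9,
        )
        groups = np.array(particles.column("OpticsGroup"))
        tilt = np.array(particles.column("AngleTilt"), dtype=float)
        rot = np.array(particles.column("AngleRot"), dtype=float)
        for gid in (1, 2):
            mask = groups == gid
            hist = angular_histogram(
                self._particles(rot[mask], tilt[mask]), n_tilt_bins=36
            )
            occupied = np.nonzero(hist.counts.sum(axis=0))[0]
            center = 90.0 if gid == 1 else 50.0
            assert np.all(np.abs((occupied + 0.5) * 5.0 - center) < 15.0)


class TestJobBacklog:
    def test_partial_processing_counts(self, tmp_path):
        from emlive.pipeline_graph import read_pipeline

        root = tmp_path / "p"
        fx.make_project(
            fx.FixtureSpec(seed=1, n_micrographs=10, n_processed=7,
                           write_images=False),
            root,
        )
        graph = read_pipeline(root / "pipeline.star")
        backlog = job_backlog(root, graph)
        assert backlog["MotionCorr/job002/"] == (7, 3)
        assert backlog["CtfFind/job003/"] == (7, 0)

    def test_all_processed_pending_zero(self, metadata_project):
        from emlive.pipeline_graph import read_pipeline

        graph = read_pipeline(metadata_project / "pipeline.star")
        backlog = job_backlog(metadata_project, graph)
        assert backlog["MotionCorr/job002/"] == (10, 0)

    def test_missing_output_counts_all_pending(self, metadata_project):
        from emlive.pipeline_graph import read_pipeline

        graph = read_pipeline(metadata_project / "pipeline.star")
        backlog = job_backlog(metadata_project, graph)
        # the External ice job has not produced its output STAR yet
        assert backlog["External/job004/"] == (0, 10)

    def test_output_ahead_of_input_clamped(self, tmp_path, caplog):
        from emlive.pipeline_graph import read_pipeline
        from emlive.star_io import read_star, write_star_file

        root = tmp_path / "p"
        fx.make_project(
            fx.FixtureSpec(seed=1, n_micrographs=5, write_images=False), root
        )
        # truncate the Import output below MotionCorr's row count to
        # emulate a poll racing a rewrite
        movies = root / "Import/job001/movies.star"
        doc = read_star(movies)
        table = doc.get_block("movies").table
        table.rows[:] = table.rows[:2]
        write_star_file(doc, movies)
        graph = read_pipeline(root / "pipeline.star")
        backlog = job_backlog(root, graph)
        assert backlog["MotionCorr/job002/"] == (5, 0)
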