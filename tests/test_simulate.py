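"""Synthetic cohort generator: templates, label paths, rendering, cohorts."""
import numpy as np
import pytest

from eegstates.microstates import TemplateSet, backfit
from eegstates.simulate import (CohortSpec, GroundTruthSpec, GroupSpec,
                                iter_cohort, make_canonical_templates,
                                render_eeg, simulate_cohort,
                                simulate_label_path, write_cohort)


class TestCanonicalTemplates:
    def test_average_referenced_unit_norm(self, positions19):
        maps = make_canonical_templates(positions=positions19)
        np.testing.assert_allclose(maps.sum(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(maps, axis=1), 1, atol=1e-9)

    def test_pairwise_correlations_moderate(self, positions19):
        maps = make_canonical_templates(positions=positions19)
        corr = np.abs(np.corrcoef(maps))
        off = corr[~np.eye(4, dtype=bool)]
        assert off.max() < 0.8

    def test_left_right_mirror_symmetry(self):
        # a perfectly symmetric grid: A and B are mirror images
        g = np.array([[x, y] for x in (-1.0, -0.5, 0.5, 1.0)
                      for y in (-1.0, 0.0, 1.0)])
        maps = make_canonical_templates(positions=g)
        mirror = {i: np.flatnonzero((g[:, 0] == -g[i, 0]) & (g[:, 1] == g[i, 1]))[0]
                  for i in range(len(g))}
        perm = [mirror[i] for i in range(len(g))]
        np.testing.assert_allclose(maps[0], maps[1][perm], atol=1e-12)
        assert np.linalg.norm(maps[0]) == pytest.approx(np.linalg.norm(maps[1]))

    def test_too_few_or_collinear_electrodes_rejected(self):
        with pytest.raises(ValueError):
            make_canonical_templates(positions=np.array([[0, 0], [1, 0], [2, 0]]))
        collinear = np.array([[x, 0.0] for x in np.linspace(-1, 1, 8)])
        with pytest.raises(ValueError, match="layout"):
            make_canonical_templates(positions=collinear)


class TestLabelPath:
    def test_two_classes_strictly_alternate(self, positions19):
        spec = GroundTruthSpec(
            n_channels=19, templates=make_canonical_templates(
                positions=positions19)[:2],
            mean_dwell_ms=np.array([20.0, 20.0]),
            class_rate=np.array([0.5, 0.5]))
        labels = simulate_label_path(spec, 5000, 0)
        runs = np.flatnonzero(np.diff(labels)) + 1
        bounded = np.concatenate(([0], runs))
        seq = labels[bounded]
        assert np.all(seq[1:] != seq[:-1])
        assert set(seq) == {0, 1}

    def test_mean_segment_length_matches_geometric_mean(self):
        spec = GroundTruthSpec(mean_dwell_ms=np.full(4, 80.0))
        labels = simulate_label_path(spec, 1_000_000, 123)
        changes = np.flatnonzero(np.diff(labels)) + 1
        seg_lengths = np.diff(np.concatenate(([0], changes, [labels.size])))
        assert seg_lengths.mean() == pytest.approx(80.0, rel=0.05)

    def test_deterministic_given_seed(self, small_spec):
        a = simulate_label_path(small_spec, 4000, 7)
        b = simulate_label_path(small_spec, 4000, 7)
        np.testing.assert_array_equal(a, b)

    def test_nonpositive_dwell_rejected(self, small_spec):
        with pytest.raises(ValueError, match="dwell"):
            simulate_label_path(small_spec, 100, 0,
                                mean_dwell_ms=np.array([10.0, -1.0, 5.0, 5.0]))

    def test_entry_rates_respected(self, small_spec):
        labels = simulate_label_path(small_spec, 500_000, 5,
                                     class_rate=np.array([0.4, 0.3, 0.2, 0.1]))
        changes = np.flatnonzero(np.diff(labels)) + 1
        entries = labels[changes]
        freq = np.bincount(entries, minlength=4) / entries.size
        # stationary entry frequencies for the restricted chain are close
        # to the configured rates when rates are not extreme
        assert np.argsort(freq).tolist() == [3, 2, 1, 0]


class TestRenderEeg:
    def test_noise_free_samples_proportional_to_templates(self, noise_free_spec):
        labels = simulate_label_path(noise_free_spec, 2000, 3)
        rec = render_eeg(labels, noise_free_spec, 3)
        ts = TemplateSet(noise_free_spec.templates,
                         ch_names=noise_free_spec.ch_names,
                         labels=["A", "B", "C", "D"])
        seg = backfit(rec, ts)
        np.testing.assert_array_equal(seg.labels, labels)
        assert seg.gev == pytest.approx(1.0, abs=1e-9)

    def test_noise_free_gfp_equals_projection_over_sqrt_n(self, noise_free_spec):
        from eegstates.microstates import compute_gfp

        labels = simulate_label_path(noise_free_spec, 1000, 4)
        rec = render_eeg(labels, noise_free_spec, 4)
        gfp = compute_gfp(rec)
        amplitude = np.abs(np.einsum(
            "ct,ct->t", noise_free_spec.templates[labels].T, rec.potentials))
        np.testing.assert_allclose(
            gfp, amplitude / np.sqrt(noise_free_spec.n_channels), rtol=1e-9)

    def test_noise_monotonically_degrades_template_correlation(self):
        from eegstates.simulate import mean_template_correlation

        corrs = [mean_template_correlation(
            GroundTruthSpec(n_channels=19, noise_sd=sd), n_samples=3000)
            for sd in (1.0, 4.0, 10.0)]
        assert corrs[0] > corrs[1] > corrs[2]

    def test_output_average_referenced(self, rendered_subject):
        _, rec = rendered_subject
        assert np.abs(rec.potentials.mean(axis=0)).max() < 1e-9

    def test_invalid_labels_rejected(self, small_spec):
        with pytest.raises(ValueError, match="labels"):
            render_eeg(np.array([0, 5]), small_spec, 0)


class TestCohort:
    def _cohort(self, **kw):
        defaults = dict(
            groups=[GroupSpec("HC", 3, hamd_baseline=(3.0, 1.0),
                              hamd_post=(3.0, 1.0)),
                    GroupSpec("PSD", 3,
                              dwell_effect=np.array([1, 1, 1, 0.7]),
                              hamd_baseline=(20.0, 2.0), hamd_post=(11.0, 4.0))],
            recording_length_s=4.0, subject_variability_cv=0.1, seed=9)
        defaults.update(kw)
        return CohortSpec(**defaults)

    def test_identity_effects_zero_variability_share_truth(self, small_spec):
        cohort = self._cohort(
            groups=[GroupSpec("HC", 4)], subject_variability_cv=0.0)
        records = simulate_cohort(cohort, small_spec, render=False)
        for rec in records:
            np.testing.assert_allclose(rec.true_dwell_ms, small_spec.mean_dwell_ms)
            np.testing.assert_allclose(rec.true_rate, small_spec.class_rate)

    def test_group_dwell_effect_recovered_in_truth_parameters(self, small_spec):
        cohort = CohortSpec(
            groups=[GroupSpec("HC", 40), GroupSpec(
                "PSD", 40, dwell_effect=np.array([1, 1, 1, 0.7]))],
            recording_length_s=1.0, subject_variability_cv=0.1, seed=2)
        records = simulate_cohort(cohort, small_spec, render=False)
        hc = np.mean([r.true_dwell_ms[3] for r in records if r.group == "HC"])
        psd = np.mean([r.true_dwell_ms[3] for r in records if r.group == "PSD"])
        assert psd / hc == pytest.approx(0.7, rel=0.08)

    def test_fixed_seed_reproduces_cohort_exactly(self, small_spec):
        cohort = self._cohort()
        a = simulate_cohort(cohort, small_spec)
        b = simulate_cohort(cohort, small_spec)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.recording.potentials,
                                          rb.recording.potentials)
            assert ra.hamd_baseline == rb.hamd_baseline

    def test_hamd_scores_respect_scale_bounds(self, small_spec):
        cohort = self._cohort(groups=[GroupSpec(
            "X", 30, hamd_baseline=(2.0, 5.0), hamd_post=(74.0, 5.0))],
            recording_length_s=0.2)
        records = simulate_cohort(cohort, small_spec, render=False)
        for r in records:
            assert 0.0 <= r.hamd_baseline <= 76.0
            assert 0.0 <= r.hamd_post <= 76.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            GroupSpec("HC", 0)

    def test_write_cohort_round_trip(self, small_spec, tmp_path):
        from eegstates.io import read_metadata, read_recording

        cohort = self._cohort(recording_length_s=1.0)
        records = simulate_cohort(cohort, small_spec)
        out = write_cohort(records, tmp_path / "cohort", truth=small_spec)
        meta = read_metadata(out / "metadata.csv")
        assert len(meta) == 6
        first = records[0]
        back = read_recording(out / f"{first.subject_id}.csv")
        np.testing.assert_allclose(back.potentials,
                                   first.recording.potentials, atol=1e-5)
        assert (out / "ground_truth.json").exists()

    def test_streaming_matches_materialized(self, small_spec):
        cohort = self._cohort(recording_length_s=0.5)
        streamed = [r.subject_id for r in iter_cohort(cohort, small_spec,
                                                      render=False)]
        listed = [r.subject_id for r in simulate_cohort(cohort, small_spec,
                                                        render=False)]
        assert streamed == listed
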