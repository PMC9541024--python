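"""Synthetic study generation, percent-of-control transform, dataset I/O."""

import numpy as np
import pandas as pd
import pytest

from piglet_pkpd.datasets import (
    DatasetFormatError,
    StudyDesign,
    generate_study,
    percent_of_control,
    read_dataset,
    write_dataset,
)
from piglet_pkpd.population import ErrorSpec, PopulationModel
from piglet_pkpd.simulate import simulate_individual


class TestGenerate:
    def test_noiseless_dataset_equals_typical_predictions(self, keto_pge2, designs):
        design = designs["ketoprofen_pge2"]
        pop = PopulationModel(
            structural=keto_pge2.structural,
            omega2={},
            error={k: ErrorSpec(v.kind, 0.0) for k, v in keto_pge2.error.items()},
        )
        ds = generate_study(design, pop, seed=1)
        model = pop.structural.with_dose(design.dose)
        for stream in ("plasma", "isf", "pd"):
            obs = ds.observations(stream, include_blq=True)
            sub = obs[obs["ID"] == 1]
            traj = simulate_individual(model, times=sub["TIME"].to_numpy())
            pred = traj.stream(stream)
            kept = sub["BLQ"].to_numpy() == 0
            np.testing.assert_allclose(sub["DV"].to_numpy()[kept], pred[kept], rtol=1e-9)

    def test_blq_censoring_increases_with_time(self, keto_pge2, designs):
        ds = generate_study(designs["ketoprofen_pge2"], keto_pge2, seed=2)
        obs = ds.observations("plasma", include_blq=True)
        late = obs[obs["TIME"] >= 36.0]
        early = obs[obs["TIME"] <= 8.0]
        assert late["BLQ"].mean() > 0.5  # > 10 absorption-to-elimination half-lives
        assert early["BLQ"].mean() < late["BLQ"].mean()
        # censored records carry the LOQ as their value
        assert (late[late["BLQ"] == 1]["DV"] == 0.05).all()

    def test_seed_reproducibility(self, flunixin, designs):
        design = designs["flunixin_cortisol"]
        a = generate_study(design, flunixin, seed=3)
        b = generate_study(design, flunixin, seed=3)
        c = generate_study(design, flunixin, seed=4)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        assert not a.frame["DV"].equals(c.frame["DV"])

    def test_one_dose_record_per_subject(self, keto_cortisol, designs):
        ds = generate_study(designs["ketoprofen_cortisol"], keto_cortisol, seed=5)
        doses = ds.frame[ds.frame["EVID"] == 1]
        assert len(doses) == 8
        assert (doses["AMT"] == 3.0).all()

    def test_design_validation(self):
        with pytest.raises(ValueError):
            StudyDesign(n_per_group=1)
        with pytest.raises(ValueError):
            StudyDesign(schedule={"plasma": [0.0, 72.0]})
        with pytest.raises(ValueError):
            StudyDesign(schedule={"urine": [1.0]})


class TestPercentOfControl:
    def test_identical_to_control(self):
        control = np.full((8, 5), 40.0)
        treated = np.full(5, 40.0)
        np.testing.assert_allclose(percent_of_control(treated, control), 100.0)
        np.testing.assert_allclose(
            percent_of_control(treated, control, mode="difference"), 0.0, atol=1e-9
        )

    def test_half_of_control(self):
        control = np.full((4, 3), 10.0)
        assert percent_of_control(np.full(3, 5.0), control) == pytest.approx(50.0)

    def test_recovers_model_scale_against_noisy_flat_control(self, rng):
        # raw treated biomarker = E/100 * control level; the transform should
        # recover E up to residual noise in the control geometric mean
        e_model = np.array([90.0, 45.0, 20.0, 60.0, 85.0])
        control_level = 12.0
        noise = lambda shape: np.exp(rng.normal(0.0, 0.1, shape))
        control = control_level * noise((8, 5))
        treated = (e_model / 100.0) * control_level * noise((20, 5))
        out = percent_of_control(treated, control)
        np.testing.assert_allclose(out.mean(axis=0), e_model, rtol=0.1)

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError):
            percent_of_control(np.ones(4), np.ones((3, 5)))

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            percent_of_control(np.ones(3), np.zeros((2, 3)))


class TestIO:
    def test_round_trip(self, flunixin, designs, tmp_path):
        ds = generate_study(designs["flunixin_cortisol"], flunixin, seed=6)
        path = tmp_path / "study.csv"
        write_dataset(ds, path)
        back = read_dataset(path)
        pd.testing.assert_frame_equal(ds.frame, back.frame, check_dtype=False)
        assert back.n_blq() == ds.n_blq()

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("ID,TIME\n1,0\n")
        with pytest.raises(DatasetFormatError, match="format declaration"):
            read_dataset(path)

    def test_unknown_stream_rejected(self, flunixin, designs, tmp_path):
        ds = generate_study(designs["flunixin_cortisol"], flunixin, seed=6)
        frame = ds.frame.copy()
        frame.loc[frame["EVID"] == 0, "DVID"] = 9
        path = tmp_path / "bad_stream.csv"
        path.write_text("# piglet-pkpd dataset v1\n" + frame.to_csv(index=False))
        with pytest.raises(DatasetFormatError, match="unknown observation stream"):
            read_dataset(path)

    def test_duplicate_dose_record_rejected(self, flunixin, designs):
        from piglet_pkpd.datasets import StudyDataset

        ds = generate_study(designs["flunixin_cortisol"], flunixin, seed=6)
        frame = pd.concat([ds.frame, ds.frame[ds.frame["EVID"] == 1]], ignore_index=True)
        frame = frame.sort_values(["ID", "TIME"]).reset_index(drop=True)
        with pytest.raises(DatasetFormatError, match="dose records"):
            StudyDataset(frame=frame)

    def test_subject_without_observations_warned_but_kept(self, flunixin, designs):
        from piglet_pkpd.datasets import StudyDataset

        ds = generate_study(designs["flunixin_cortisol"], flunixin, seed=6)
        frame = ds.frame[(ds.frame["ID"] != 3) | (ds.frame["EVID"] == 1)].reset_index(drop=True)
        with pytest.warns(UserWarning, match="no observations"):
            kept = StudyDataset(frame=frame)
        assert 3 in kept.subjects
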