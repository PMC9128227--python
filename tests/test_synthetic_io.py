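import json

import numpy as np
import pandas as pd
import pytest

from tetherdrive import io as tio
from tetherdrive.cage import CageConfig
from tetherdrive.crosses import carrier_rate_from_frame, predict_cross, tare_het_female_x_wild
from tetherdrive.dynamics import FitnessComponent, FitnessModel, ReleaseEvent
from tetherdrive.genetics import DriveParams, HomingLocusRule, diplotype, drive_haplotype
from tetherdrive.synthetic import (
    CageSyntheticSpec,
    CrossSyntheticSpec,
    default_cage_spec,
    gen_cage_dataset,
    gen_cross_dataset,
)


class TestGenCrossDataset:
    def test_seed_reproducibility(self, measured_params):
        spec = CrossSyntheticSpec(params=measured_params, n_vials=8, seed=5)
        df1, t1 = gen_cross_dataset(spec)
        df2, t2 = gen_cross_dataset(spec)
        pd.testing.assert_frame_equal(df1, df2)
        assert t1 == t2

    def test_zero_vials_empty_frame(self, measured_params):
        df, truth = gen_cross_dataset(
            CrossSyntheticSpec(params=measured_params, n_vials=0)
        )
        assert len(df) == 0
        assert list(df.columns)[0] == "vial_id"

    def test_pooled_rate_converges_to_prediction(self, measured_params):
        truth_rate = predict_cross(
            tare_het_female_x_wild(), measured_params
        ).carrier_frac_tare
        spec = CrossSyntheticSpec(
            params=measured_params, n_vials=400, mean_eggs=300, dispersion=0.0, seed=9
        )
        df, _ = gen_cross_dataset(spec)
        est = carrier_rate_from_frame(df, drive="tare")
        assert est.rate == pytest.approx(truth_rate, abs=0.005)

    def test_dispersion_inflates_between_vial_variance(self, measured_params):
        def vial_sd(disp, seed):
            spec = CrossSyntheticSpec(
                params=measured_params, n_vials=200, mean_eggs=300,
                dispersion=disp, seed=seed,
            )
            df, _ = gen_cross_dataset(spec)
            tot = df[["n_egfp", "n_dsred", "n_both", "n_neither"]].sum(axis=1)
            return ((df["n_egfp"] + df["n_both"]) / tot).std()

        assert vial_sd(0.3, 1) > 2 * vial_sd(0.0, 1)

    def test_counts_internally_consistent(self, measured_params):
        df, _ = gen_cross_dataset(
            CrossSyntheticSpec(params=measured_params, n_vials=30, seed=2)
        )
        pheno = df[["n_egfp", "n_dsred", "n_both", "n_neither"]].sum(axis=1)
        assert (pheno == df["n_pupae"]).all()
        assert (df["n_pupae"] <= df["n_eggs"]).all()

    def test_invalid_spec_rejected(self, measured_params):
        with pytest.raises(ValueError):
            CrossSyntheticSpec(params=measured_params, dispersion=1.0)


class TestGenCageDataset:
    def test_experiment_scale_defaults(self):
        trajs, truth = gen_cage_dataset(default_cage_spec(seed=4))
        assert len(trajs) == 4
        assert all(t.counts["census"].iloc[0] == 3500 for t in trajs)
        assert truth["ne_fraction"] == 0.036
        assert truth["fitness"]["f_hom"] == 0.867

    def test_near_deterministic_at_full_effective_size(self, measured_params):
        spec = CageSyntheticSpec(
            params=measured_params,
            fitness=FitnessModel(0.867),
            release_proportions=(0.6,),
            n_generations=6,
            census=100000,
            ne_fraction=1.0,
            seed=3,
        )
        trajs, _ = gen_cage_dataset(spec)
        from tetherdrive.dynamics import PopulationState, iterate

        det = iterate(
            PopulationState.release_into_wild(0.6, diplotype(drive_haplotype(), drive_haplotype())),
            measured_params,
            FitnessModel(0.867),
            6,
        ).summary()["carrier_freq_tare"].to_numpy()
        sim = trajs[0].carrier_freq("tare")
        assert np.max(np.abs(det - sim)) < 0.01

    def test_threshold_straddling_mixed_outcomes(self, measured_params, measured_fitness):
        """Releases just around the introduction boundary go both ways under
        drift (bistability plus noise)."""
        spec = CageSyntheticSpec(
            params=measured_params,
            fitness=measured_fitness,
            release_proportions=(0.12,) * 10,
            n_generations=20,
            census=3500,
            ne_fraction=0.036,
            seed=11,
        )
        trajs, _ = gen_cage_dataset(spec)
        finals = [t.carrier_freq("tare")[-1] for t in trajs]
        assert any(f > 0.5 for f in finals)
        assert any(f < 0.2 for f in finals)

    def test_homing_release_schedule(self):
        params = DriveParams(
            c_germ_tare=0.888,
            c_embryo_tare=0.632,
            homing_germ_cut=0.9,
            homing_conversion_frac=0.7,
            c_embryo_homing=0.3,
            homing_locus_rule=HomingLocusRule.HAPLOLETHAL_RESCUE,
        )
        spec = CageSyntheticSpec(
            params=params,
            fitness=FitnessModel(1.0),
            release_proportions=(0.6,),
            n_generations=10,
            homing_release=(0.33, 4),
            seed=6,
        )
        trajs, truth = gen_cage_dataset(spec)
        dsred = trajs[0].carrier_freq("homing")
        assert (dsred[:4] == 0).all()
        assert dsred[4] > 0
        assert truth["homing_release"] == [0.33, 4]


class TestCrossCsvIO:
    def test_roundtrip(self, tmp_path, measured_params):
        df, _ = gen_cross_dataset(
            CrossSyntheticSpec(params=measured_params, n_vials=12, seed=1)
        )
        path = tmp_path / "cross.csv"
        tio.write_cross_csv(df, path)
        assert path.read_text().splitlines()[0].startswith("# tetherdrive-cross-csv")
        df2 = tio.read_cross_csv(path)
        pd.testing.assert_frame_equal(df.reset_index(drop=True), df2)

    def test_missing_header_rejected(self, tmp_path, measured_params):
        df, _ = gen_cross_dataset(
            CrossSyntheticSpec(params=measured_params, n_vials=2, seed=1)
        )
        path = tmp_path / "cross.csv"
        df.to_csv(path, index=False)
        with pytest.raises(tio.FileFormatError, match="schema header"):
            tio.read_cross_csv(path)

    def test_negative_count_names_line(self, tmp_path, measured_params):
        df, _ = gen_cross_dataset(
            CrossSyntheticSpec(params=measured_params, n_vials=3, seed=1)
        )
        df.loc[1, "n_egfp"] = -5
        path = tmp_path / "cross.csv"
        tio.write_cross_csv(df, path)
        with pytest.raises(tio.FileFormatError, match="line 4"):
            tio.read_cross_csv(path)

    def test_bad_genotype_string_rejected(self, tmp_path, measured_params):
        df, _ = gen_cross_dataset(
            CrossSyntheticSpec(params=measured_params, n_vials=2, seed=1)
        )
        df.loc[0, "mother_genotype"] = "nonsense"
        path = tmp_path / "cross.csv"
        tio.write_cross_csv(df, path)
        with pytest.raises(tio.FileFormatError, match="mother_genotype"):
            tio.read_cross_csv(path)


class TestCageCsvIO:
    def _traj(self, measured_params, measured_fitness):
        trajs, _ = gen_cage_dataset(default_cage_spec(seed=8))
        return trajs[0]

    def test_roundtrip(self, tmp_path, measured_params, measured_fitness):
        traj = self._traj(measured_params, measured_fitness)
        path = tmp_path / "cage.csv"
        tio.write_cage_csv(traj, path)
        back = tio.read_cage_csv(path)
        pd.testing.assert_frame_equal(traj.counts, back.counts)

    def test_sum_mismatch_names_row(self, tmp_path, measured_params, measured_fitness):
        traj = self._traj(measured_params, measured_fitness)
        df = traj.counts.copy()
        df.loc[2, "n_neither"] += 1
        path = tmp_path / "cage.csv"
        tio.write_cage_csv(df, path)
        with pytest.raises(tio.FileFormatError, match="line 5"):
            tio.read_cage_csv(path)

    def test_nonconsecutive_generations_rejected(
        self, tmp_path, measured_params, measured_fitness
    ):
        traj = self._traj(measured_params, measured_fitness)
        df = traj.counts.copy()
        df.loc[1, "generation"] = 7
        path = tmp_path / "cage.csv"
        tio.write_cage_csv(df, path)
        with pytest.raises(tio.FileFormatError, match="consecutive"):
            tio.read_cage_csv(path)


class TestConfigIO:
    def test_roundtrip(self, tmp_path, measured_params):
        cage = CageConfig(
            n_generations=9,
            census_sizes=[3000] * 10,
            ne_fraction=0.04,
            releases=(ReleaseEvent(0, diplotype(drive_haplotype(), drive_haplotype()), 0.61),),
            seed=13,
        )
        path = tmp_path / "cfg.yaml"
        tio.write_config(path, measured_params,
                         FitnessModel(0.867, component=FitnessComponent.FEMALE_FECUNDITY),
                         cage)
        cfg = tio.read_config(path)
        assert cfg["params"] == measured_params
        assert cfg["fitness"].f_hom == 0.867
        assert cfg["fitness"].component is FitnessComponent.FEMALE_FECUNDITY
        assert cfg["cage"].releases == cage.releases
        assert cfg["cage"].census_schedule() == cage.census_schedule()

    def test_probability_out_of_range_names_field(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("drive_params:\n  c_germ_tare: 1.2\n")
        with pytest.raises(tio.FileFormatError, match="c_germ_tare"):
            tio.read_config(path)

    def test_unknown_section_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("drvie_params:\n  c_germ_tare: 0.9\n")
        with pytest.raises(tio.FileFormatError, match="drvie_params"):
            tio.read_config(path)

    def test_bad_component_names_field(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("fitness:\n  component: sideways\n")
        with pytest.raises(tio.FileFormatError, match="component"):
            tio.read_config(path)


class TestFitJsonIO:
    def test_roundtrip(self, tmp_path, measured_params, measured_fitness):
        from tetherdrive.cage import simulate_cage
        from tetherdrive.likelihood import fit_fitness

        trajs, _ = gen_cage_dataset(default_cage_spec(seed=21))
        fit = fit_fitness(trajs, measured_params, profile_ci=False)
        path = tmp_path / "fit.json"
        tio.write_fit_json(fit, path)
        back = tio.read_fit_json(path)
        assert back.f_hom == fit.f_hom
        assert back.component is fit.component
        assert back.ne_fraction == fit.ne_fraction
        pd.testing.assert_frame_equal(back.per_transition, fit.per_transition)

    def test_wrong_schema_rejected(self, tmp_path):
        path = tmp_path / "fit.json"
        path.write_text(json.dumps({"schema": "something-else"}))
        with pytest.raises(tio.FileFormatError, match="schema"):
            tio.read_fit_json(path)
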