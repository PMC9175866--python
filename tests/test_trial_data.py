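"""Data model, IO round-trips, pooling, and match-covariate encoding."""

import numpy as np
import pandas as pd
import pytest

from vtdmaic.trial_data import (
    AggregateProfile,
    IPDTable,
    MatchTarget,
    SchemaError,
    ValidationError,
    default_match_spec,
    encode_for_matching,
    pool_trials,
    read_ipd,
    read_profile,
    response_counts,
    write_ipd,
)
from vtdmaic.synthetic_trials import (
    CovariateModel,
    SimConfig,
    default_paperlike_config,
    profile_from_ipd,
    simulate_trial,
)


def _tiny_frame(n=3, trial="T1"):
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "trial_id": trial,
            "arm": "A",
            "age": 55.0,
            "sex": "male",
            "ecog_ge1": 0,
            "myeloma_type": "IgG",
            "iss": "II",
            "creatinine_clearance": 90.0,
        }
    )


class TestIPDTable:
    def test_valid_three_row_file_round_trips(self, tmp_path):
        path = tmp_path / "ipd.csv"
        path.write_text(_tiny_frame().to_csv(index=False))
        ipd = read_ipd(path)
        assert ipd.n == 3

    def test_invalid_iss_names_offending_row(self):
        frame = _tiny_frame()
        frame.loc[1, "iss"] = "IV"
        with pytest.raises(ValidationError, match="iss.*rows 2"):
            IPDTable(frame)

    def test_missing_mandatory_column_is_schema_error(self):
        with pytest.raises(SchemaError, match="iss"):
            IPDTable(_tiny_frame().drop(columns=["iss"]))

    def test_non_numeric_age_names_column(self, tmp_path):
        frame = _tiny_frame()
        frame["age"] = frame["age"].astype(object)
        frame.loc[2, "age"] = "old"
        path = tmp_path / "bad.csv"
        path.write_text(frame.to_csv(index=False))
        with pytest.raises(SchemaError, match="age"):
            read_ipd(path)

    def test_flag_and_time_invariants(self):
        frame = _tiny_frame()
        frame["os_event"] = [0, 1, 2]
        with pytest.raises(ValidationError, match="os_event"):
            IPDTable(frame)
        frame = _tiny_frame()
        frame["os_time"] = [1.0, -2.0, 3.0]
        with pytest.raises(ValidationError, match="os_time"):
            IPDTable(frame)

    def test_write_read_round_trip_lossless(self, paper_trials, tmp_path):
        mod, _ = paper_trials
        path = tmp_path / "mod.csv"
        write_ipd(mod, path)
        back = read_ipd(path)
        pd.testing.assert_frame_equal(back.frame, mod.frame, check_dtype=False)

    def test_response_counts_nest(self, paper_trials):
        mod, label = paper_trials
        for ipd in (mod, label):
            for tp in ("postinduction", "posttransplant"):
                c = response_counts(ipd, tp)
                assert c["cr_plus"] <= c["vgpr_plus"] <= c["orr"] <= c["n"]


class TestPooling:
    @pytest.mark.parametrize("sizes, total", [((49, 542), 591), ((538, 49), 587)])
    def test_pooled_size_is_sum(self, sizes, total):
        tables = [
            IPDTable(_tiny_frame(n, trial=f"T{i}"))
            for i, n in enumerate(sizes)
        ]
        assert pool_trials(tables).n == total

    def test_pool_of_one_is_identity(self, paper_trials):
        mod, _ = paper_trials
        pooled = pool_trials([mod])
        pd.testing.assert_frame_equal(pooled.frame, mod.frame)

    def test_patient_collision_rejected(self):
        a = IPDTable(_tiny_frame(3, trial="T"))
        b = IPDTable(_tiny_frame(2, trial="T"))
        with pytest.raises(ValidationError, match="duplicate"):
            pool_trials([a, b])


class TestProfileIO:
    def test_published_style_profile_has_seven_targets(self, tmp_path):
        path = tmp_path / "profile.yaml"
        path.write_text(
            "source_n: 591\n"
            "targets:\n"
            "  - {variable: age, statistic: median, value: 58}\n"
            "  - {variable: sex, statistic: proportion, level: male, value: 0.58}\n"
            "  - {variable: ecog_ge1, statistic: proportion, level: 1, value: 0.52}\n"
            "  - {variable: myeloma_type, statistic: proportion, level: IgG, value: 0.61}\n"
            "  - {variable: iss, statistic: proportion, level: I, value: 0.41}\n"
            "  - {variable: iss, statistic: proportion, level: II, value: 0.43}\n"
            "  - {variable: creatinine_clearance, statistic: median, value: 95.2}\n"
        )
        profile = read_profile(path)
        assert len(profile.targets) == 7
        assert profile.source_n == 591
        assert profile.targets[-1].value == pytest.approx(95.2)

    def test_empty_target_list_rejected(self):
        with pytest.raises(ValidationError):
            AggregateProfile(targets=(), source_n=100)

    def test_out_of_range_proportion_rejected(self):
        with pytest.raises(ValidationError):
            MatchTarget("sex", "proportion", 1.2, "male")

    def test_duplicate_target_rejected(self):
        t = MatchTarget("sex", "proportion", 0.5, "male")
        with pytest.raises(ValidationError, match="duplicate"):
            AggregateProfile(targets=(t, t), source_n=10)

    def test_proportion_requires_level(self):
        with pytest.raises(ValidationError, match="level"):
            MatchTarget("sex", "proportion", 0.5)


class TestEncoding:
    def test_exactly_matching_sample_centres_to_zero(self):
        frame = _tiny_frame(4)
        frame["sex"] = ["male", "male", "female", "female"]
        profile = AggregateProfile(
            (MatchTarget("sex", "proportion", 0.5, "male"),), source_n=4
        )
        design = encode_for_matching(IPDTable(frame), profile)
        assert design["sex[male]"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_iss_dummy_columns_centre_at_target_gap(self):
        n = 100
        frame = _tiny_frame(n)
        frame["iss"] = ["I"] * 34 + ["II"] * 44 + ["III"] * 22
        profile = AggregateProfile(
            (
                MatchTarget("iss", "proportion", 0.41, "I"),
                MatchTarget("iss", "proportion", 0.43, "II"),
            ),
            source_n=n,
        )
        design = encode_for_matching(IPDTable(frame), profile)
        assert design["iss[I]"].mean() == pytest.approx(0.34 - 0.41)
        assert design["iss[II]"].mean() == pytest.approx(0.44 - 0.43)

    def test_median_indicator_centres_at_half(self):
        frame = _tiny_frame(10)
        frame["age"] = np.arange(50.0, 60.0)  # 5 of 10 values <= 54.5
        profile = AggregateProfile(
            (MatchTarget("age", "median", 54.5),), source_n=10
        )
        design = encode_for_matching(IPDTable(frame), profile)
        assert design["age"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_absent_target_variable_is_configuration_error(self, paper_trials):
        mod, _ = paper_trials
        profile = AggregateProfile(
            (MatchTarget("hemoglobin_weird", "median", 11.0),), source_n=10
        )
        with pytest.raises(SchemaError, match="hemoglobin_weird"):
            encode_for_matching(mod, profile)

    def test_missing_covariates_are_excluded_not_imputed(self, paper_trials):
        mod, _ = paper_trials
        frame = mod.frame.copy()
        frame.loc[:4, "iss"] = np.nan
        ipd = IPDTable(frame)
        profile = profile_from_ipd(mod)
        design = encode_for_matching(ipd, profile)
        assert len(design) == mod.n - 5

    def test_centering_property_at_large_n(self):
        """A sample drawn exactly at the targets has near-zero column means."""
        cfg = SimConfig(
            trial_id="BIG",
            arm="A",
            n=100_000,
            covariates=CovariateModel(),
            seed=77,
        )
        ipd = simulate_trial(cfg)
        cov = cfg.covariates
        profile = AggregateProfile(
            (
                MatchTarget("age", "median", cov.age_mean),
                MatchTarget("sex", "proportion", cov.male, "male"),
                MatchTarget("ecog_ge1", "proportion", cov.ecog_ge1, 1),
                MatchTarget("myeloma_type", "proportion", cov.igg, "IgG"),
                MatchTarget("iss", "proportion", cov.iss[0], "I"),
                MatchTarget("iss", "proportion", cov.iss[1], "II"),
                MatchTarget("creatinine_clearance", "median", cov.crcl_median),
            ),
            source_n=cfg.n,
        )
        design = encode_for_matching(ipd, profile)
        assert np.abs(design.mean(axis=0)).max() < 0.02
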