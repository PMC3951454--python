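import numpy as np
import pandas as pd
import pytest

from capturebayes.domain import (CaptureDataset, DegenerateCovariateError,
                                 IntegrityError, SchemaError,
                                 build_design_matrix, read_site_table)

from conftest import make_visit


class TestReadWrite:
    def test_round_trip_is_lossless(self, tiny_dataset, tmp_path):
        path = tmp_path / "visits.csv"
        tiny_dataset.write_csv(path)
        back = read_site_table(path)
        assert len(back) == 3
        assert len(back.site_coordinates()[0]) == 2
        for a, b in zip(tiny_dataset.visits, back.visits):
            assert a.site_id == b.site_id and a.year == b.year
            assert a.counts == b.counts
            assert a.season == b.season
            assert a.effort == b.effort
            for k, v in a.covariates.items():
                assert (np.isnan(v) and np.isnan(b.covariates[k])) or \
                    b.covariates[k] == pytest.approx(v)

    def test_missing_column_names_the_column(self, tiny_dataset, tmp_path):
        df = tiny_dataset.to_frame().drop(columns=["traps"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="traps"):
            read_site_table(path)

    def test_count_exceeding_effort_rejected(self, tiny_dataset, tmp_path):
        df = tiny_dataset.to_frame()
        df.loc[0, "y_total"] = 99
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(IntegrityError, match="row 0"):
            read_site_table(path)

    def test_effort_column_checked_against_traps_times_nights(
            self, tiny_dataset, tmp_path):
        df = tiny_dataset.to_frame()
        df["effort"] = df["traps"] * df["nights"]
        df.loc[1, "effort"] = 1
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(IntegrityError, match="effort"):
            read_site_table(path)

    def test_webs_unavailable_before_2011(self, tmp_path):
        visits = [make_visit(site="s0", year=2004),
                  make_visit(site="s0", year=2005),
                  make_visit(site="s1", x=900.0, year=2011,
                             covariates={"Webs": 3.0})]
        path = tmp_path / "v.csv"
        CaptureDataset(visits=visits).write_csv(path)
        ds = read_site_table(path)
        assert ds.availability_mask[("Webs", 2004)] is False
        assert ds.availability_mask[("Webs", 2005)] is False
        assert ds.availability_mask[("Webs", 2011)] is True


class TestInvariants:
    def test_f2_exceeding_females_rejected(self):
        v = make_visit(counts={"total": 3, "males": 1, "females": 2, "f2": 3})
        with pytest.raises(IntegrityError, match="f2"):
            v.validate()

    def test_males_plus_females_cannot_exceed_total(self):
        v = make_visit(counts={"total": 2, "males": 2, "females": 1})
        with pytest.raises(IntegrityError, match="total"):
            v.validate()

    def test_revisit_coordinates_must_match(self):
        visits = [make_visit(site="s0", x=0.0),
                  make_visit(site="s0", x=5.0, year=2005)]
        with pytest.raises(IntegrityError, match="coordinates"):
            CaptureDataset(visits=visits).validate()

    def test_close_sites_warn_not_fail(self):
        visits = [make_visit(site="s0", x=0.0),
                  make_visit(site="s1", x=100.0)]
        with pytest.warns(UserWarning, match="300"):
            CaptureDataset(visits=visits).validate()


class TestDesignMatrix:
    def test_standardization_closed_form(self):
        visits = [make_visit(site=f"s{i}", x=i * 1000.0,
                             covariates={"Condition": c})
                  for i, c in enumerate([2.0, 4.0, 6.0])]
        dm = build_design_matrix(CaptureDataset(visits=visits))
        z = np.sqrt(1.5)  # (2-4)/sd with sd = sqrt(8/3)
        np.testing.assert_allclose(dm.column("Condition"),
                                   [-z, 0.0, z], atol=1e-9)

    def test_all_missing_webs_gives_zero_column_and_mask(self):
        visits = [make_visit(site=f"s{i}", x=i * 1000.0, year=2004)
                  for i in range(3)]
        dm = build_design_matrix(CaptureDataset(visits=visits))
        j = dm.covariate_names.index("Webs")
        assert dm.column("Webs").sum() == 0.0
        assert dm.missing_mask[:, j].all()

    def test_life_stage_indicators(self):
        visits = [make_visit(site="s0", season="breeding"),
                  make_visit(site="s1", x=1000.0, season="JD"),
                  make_visit(site="s2", x=2000.0, season="postJD")]
        dm = build_design_matrix(CaptureDataset(visits=visits))
        np.testing.assert_array_equal(dm.column("JD"), [0, 1, 0])
        np.testing.assert_array_equal(dm.column("PostJD"), [0, 0, 1])

    def test_idempotent_on_standardized_input(self, tiny_dataset):
        dm1 = build_design_matrix(tiny_dataset)
        # feed the standardized values back through as raw covariates
        visits = []
        for i, v in enumerate(tiny_dataset.visits):
            visits.append(make_visit(
                site=v.site_id, x=v.x, y=v.y, year=v.year, season=v.season,
                covariates={"Condition": dm1.column("Condition")[i]}))
        dm2 = build_design_matrix(CaptureDataset(visits=visits))
        np.testing.assert_allclose(dm2.column("Condition"),
                                   dm1.column("Condition"), atol=1e-9)

    def test_back_transform_reproduces_linear_predictor(self, tiny_dataset):
        dm = build_design_matrix(tiny_dataset)
        rng = np.random.default_rng(0)
        beta_std = rng.normal(size=dm.X.shape[1])
        eta_std = 0.7 + dm.X @ beta_std
        a_raw, beta_raw = dm.raw_linear_predictor(beta_std, 0.7)
        raw = np.zeros_like(dm.X)
        for j, name in enumerate(dm.covariate_names):
            if name in dm.sds:
                col = dm.X[:, j] * dm.sds[name] + dm.means[name]
                col[dm.missing_mask[:, j]] = dm.means[name]
                raw[:, j] = col
            else:
                raw[:, j] = dm.X[:, j]
        np.testing.assert_allclose(a_raw + raw @ beta_raw, eta_std, atol=1e-9)

    def test_zero_variance_covariate_rejected(self):
        visits = [make_visit(site=f"s{i}", x=i * 1000.0,
                             covariates={"Logs": 50.0}) for i in range(3)]
        with pytest.raises(DegenerateCovariateError, match="Logs"):
            build_design_matrix(CaptureDataset(visits=visits))

    def test_transform_matches_training_scaling(self, tiny_dataset):
        dm = build_design_matrix(tiny_dataset)
        X2 = dm.transform(tiny_dataset)
        np.testing.assert_allclose(X2, dm.X, atol=1e-12)
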