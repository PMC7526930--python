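"""Literature-database ingestion: parsing, resolution, encoding, splitting."""

import numpy as np
import pandas as pd
import pytest

from chrysopt import database
from chrysopt.database import (
    FEATURE_NAMES,
    ConfigError,
    EncodingError,
    ParseError,
    ResolutionPolicy,
    TransformationRecord,
)


class TestLoad:
    def test_fixture_has_49_studies(self, records):
        assert len(records) == 49

    def test_first_record_fields(self, records):
        first = records[0]
        assert first.strains == ("LBA4404",)
        assert first.od_wavelength_nm == 550
        assert first.efficiency_pct == "4.3-13.4"
        assert first.kanamycin is None  # "-" preserved as absent

    def test_trailing_percent_sign_is_tolerated(self, records):
        shao = [r for r in records if r.reference_id.startswith("Shao")][0]
        assert shao.efficiency_pct.rstrip("%") == "6.4"
        rows = database.resolve_records([shao])
        assert rows["efficiency"].iloc[0] == pytest.approx(6.4)

    def test_malformed_cell_names_row_and_column(self, tmp_path, records):
        fixture = database.fixture_path().read_text().splitlines()
        fixture[3] = fixture[3].replace("660", "650")  # unknown wavelength
        bad = tmp_path / "bad.csv"
        bad.write_text("\n".join(fixture))
        with pytest.raises(ParseError, match="row 4.*od_wavelength_nm"):
            database.load_database(bad)

    def test_record_invariants_enforced(self):
        with pytest.raises(ParseError):
            TransformationRecord(
                strains=(),
                od_value="0.5",
                od_wavelength_nm=600,
                ccp_days="2",
                kanamycin=None,
                hygromycin=None,
                paromomycin=None,
                geneticin=None,
                vancomycin=None,
                cefotaxime=None,
                carbenicillin=None,
                ticarcillin=None,
                efficiency_pct="5",
                reference_id="x",
            )


class TestResolve:
    def test_midpoint_min_max_policies(self, records):
        lowe = [r for r in records if r.reference_id.startswith("Lowe")][0]
        assert lowe.kanamycin == "15-25"
        for policy, expected in [("midpoint", 20.0), ("min", 15.0), ("max", 25.0)]:
            rows = database.resolve_records(
                [lowe], ResolutionPolicy(range_policy=policy)
            )
            assert rows["K"].iloc[0] == pytest.approx(expected)

    def test_multi_strain_rows_expand(self, records):
        ledger = [r for r in records if r.reference_id.startswith("Ledger")][0]
        rows = database.resolve_records([ledger])
        assert list(rows["strain"]) == ["LBA4404", "A2002"]
        # all other fields duplicated
        assert rows.drop(columns="strain").nunique().max() == 1

    def test_expansion_conservation(self, records, resolved_rows):
        assert len(resolved_rows) == sum(len(r.strains) for r in records)

    def test_absent_antibiotic_is_zero_dose(self, records):
        first_rows = database.resolve_records(records[:1])
        assert first_rows["K"].iloc[0] == 0.0  # kanamycin "-" in the fixture
        assert first_rows["VA"].iloc[0] == 400.0

    def test_csv_round_trip(self, resolved_rows, tmp_path):
        path = tmp_path / "resolved.csv"
        database.export_resolved(resolved_rows, path)
        back = pd.read_csv(path, float_precision="round_trip")
        for col in FEATURE_NAMES[1:] + ("efficiency",):
            np.testing.assert_array_equal(back[col].to_numpy(),
                                          resolved_rows[col].to_numpy())


class TestEncode:
    def test_eleven_features(self, dataset):
        assert dataset.features.shape[1] == 11
        assert dataset.feature_names == FEATURE_NAMES

    def test_strain_codebook_first_appearance(self, dataset):
        assert dataset.strain_codebook["LBA4404"] == 0
        assert dataset.strain_codebook["A2002"] == 1
        codes = list(dataset.strain_codebook.values())
        assert sorted(codes) == list(range(len(codes)))  # injective

    def test_scaled_to_unit_interval(self, dataset):
        assert dataset.features.min() >= 0.0
        assert dataset.features.max() <= 1.0
        assert np.isfinite(dataset.features).all()

    def test_midpoint_scaling_example(self):
        rows = pd.DataFrame(
            {
                "strain": ["A", "B", "A"],
                **{n: [0.0, 500.0, 250.0] for n in FEATURE_NAMES[1:]},
                "efficiency": [1.0, 2.0, 3.0],
            }
        )
        ds = database.encode(rows)
        assert ds.features[2, 1] == pytest.approx(0.5)

    def test_scaling_is_invertible(self, dataset, rng):
        raw = dataset.unscale(dataset.features)
        again = dataset.scale(raw)
        np.testing.assert_allclose(again, dataset.features, atol=1e-12)

    def test_unseen_strain_raises(self, resolved_rows, dataset):
        rows = resolved_rows.copy()
        rows.loc[rows.index[0], "strain"] = "GV9999"
        with pytest.raises(EncodingError, match="GV9999"):
            database.encode(rows, strain_codebook=dataset.strain_codebook)

    def test_targets_on_percent_scale(self, dataset):
        assert dataset.targets.min() >= 0.0
        assert dataset.targets.max() <= 100.0


class TestSplit:
    @pytest.mark.parametrize(
        "n,sizes", [(10, (7, 2, 1)), (49, (34, 10, 5)), (75, (53, 15, 7))]
    )
    def test_largest_remainder_sizes(self, n, sizes):
        sp = database.split(n, seed=0)
        assert (len(sp.train_idx), len(sp.test_idx), len(sp.val_idx)) == sizes

    def test_deterministic_given_seed(self):
        a = database.split(49, seed=42)
        b = database.split(49, seed=42)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.val_idx, b.val_idx)

    def test_partition_property_over_seeds(self):
        for seed in range(100):
            sp = database.split(49, seed=seed)
            merged = np.concatenate([sp.train_idx, sp.test_idx, sp.val_idx])
            assert sorted(merged) == list(range(49))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigError):
            database.split(49, fractions=(0.7, 0.2, 0.2), seed=0)
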