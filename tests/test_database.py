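"""Database ingest, repeat collapsing, classifications and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riverc14 import database as db
from riverc14.database import (
    BIOME_MAP,
    LITHOLOGY_MAP,
    SIZE_CLASSES,
    IngestError,
    ObservationSet,
    classify_size,
    collapse_repeats,
    group_test,
    ingest,
    paired_offset,
    simplify_biome,
    simplify_lithology,
    summarize,
)
from riverc14.isotope import delta14c_to_f14c


def _obs_frame(rows):
    base = {c: np.nan for c in db._CANONICAL_COLUMNS}
    records = []
    for r in rows:
        rec = dict(base)
        rec.update(r)
        records.append(rec)
    df = pd.DataFrame(records)
    df["modern"] = df["f14c"].astype(float) > 1
    return ObservationSet(
        df, {"n_input": len(df), "n_kept": len(df), "n_dropped": 0, "dropped": []}
    )


class TestIngest:
    def test_well_formed_fixture(self, obs_csv):
        obs = ingest(obs_csv)
        assert len(obs) == 3
        assert obs.metadata["n_dropped"] == 0
        # classifications attached
        assert obs.data.loc[0, "lithology_class"] == "sedimentary"
        assert obs.data.loc[2, "size_binary"] == "small"

    def test_invalid_rows_dropped_and_logged(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {
                "site_id": ["A", "B", "C", "D"],
                "year": [2000, 2000, 1920, 2005],
                "compound": ["DIC", "N2O", "DIC", "DIC"],
                "f14c": [0.9, 0.9, 0.9, -0.2],
            }
        ).to_csv(path, index=False)
        obs = ingest(path)
        assert len(obs) == 1
        reasons = "; ".join(r for _, r in obs.metadata["dropped"])
        assert "N2O" in reasons
        assert "1920" in reasons
        assert "non-positive" in reasons
        # conservation: kept + dropped = input
        assert obs.metadata["n_kept"] + obs.metadata["n_dropped"] == 4

    def test_delta14c_only_rows_backfilled(self, tmp_path):
        path = tmp_path / "delta.csv"
        pd.DataFrame(
            {
                "site_id": ["A"],
                "year": [2005],
                "compound": ["DIC"],
                "f14c": [np.nan],
                "delta14c": [-50.0],
            }
        ).to_csv(path, index=False)
        obs = ingest(path)
        assert obs.data.loc[0, "f14c"] == pytest.approx(
            delta14c_to_f14c(-50.0, 2005)
        )

    def test_missing_mandatory_columns(self, tmp_path):
        path = tmp_path / "nocol.csv"
        pd.DataFrame({"f14c": [0.9]}).to_csv(path, index=False)
        with pytest.raises(IngestError):
            ingest(path)

    def test_column_mapping(self, tmp_path):
        path = tmp_path / "mapped.csv"
        pd.DataFrame(
            {"Station": ["A"], "Year": [2000], "Gas": ["DIC"], "FM": [0.9]}
        ).to_csv(path, index=False)
        obs = ingest(
            path,
            column_map={
                "site_id": "Station",
                "year": "Year",
                "compound": "Gas",
                "f14c": "FM",
            },
        )
        assert len(obs) == 1

    def test_date_year_conflict_dropped(self, tmp_path):
        path = tmp_path / "conflict.csv"
        pd.DataFrame(
            {
                "site_id": ["A"],
                "year": [2000],
                "date": ["2001-05-01"],
                "compound": ["DIC"],
                "f14c": [0.9],
            }
        ).to_csv(path, index=False)
        obs = ingest(path)
        assert len(obs) == 0 and obs.metadata["n_dropped"] == 1


class TestCollapseRepeats:
    def test_five_replicates_averaged(self):
        obs = _obs_frame(
            [
                {"site_id": "S", "year": 2000, "compound": "DIC", "f14c": f}
                for f in (0.90, 0.92, 0.94, 0.96, 0.98)
            ]
        )
        out = collapse_repeats(obs)
        assert len(out) == 1
        assert out.data.loc[0, "f14c"] == pytest.approx(0.94)
        assert out.metadata["collapsed_groups"] == 1
        # conservation: kept + removed = input
        assert len(out) + out.metadata["rows_removed_by_collapse"] == len(obs)

    def test_exactly_four_pass_through(self):
        obs = _obs_frame(
            [
                {"site_id": "S", "year": 2000, "compound": "DIC", "f14c": f}
                for f in (0.90, 0.92, 0.94, 0.96)
            ]
        )
        out = collapse_repeats(obs)
        assert len(out) == 4

    def test_compounds_collapse_separately(self):
        rows = [
            {"site_id": "S", "year": 2000, "compound": comp, "f14c": 0.9 + i * 0.01}
            for comp in ("DIC", "CO2")
            for i in range(5)
        ]
        out = collapse_repeats(_obs_frame(rows))
        assert len(out) == 2
        assert set(out.data["compound"]) == {"DIC", "CO2"}

    def test_uncertainty_rule(self):
        rows = [
            {
                "site_id": "S",
                "year": 2000,
                "compound": "DIC",
                "f14c": f,
                "sigma_f14c": 0.004,
            }
            for f in (0.90, 0.92, 0.94, 0.96, 0.98)
        ]
        out = collapse_repeats(_obs_frame(rows))
        fvals = np.array([0.90, 0.92, 0.94, 0.96, 0.98])
        sem = fvals.std(ddof=1) / np.sqrt(5)
        assert out.data.loc[0, "sigma_f14c"] == pytest.approx(max(sem, 0.004))

    def test_idempotent_and_never_grows(self):
        rng = np.random.default_rng(0)
        rows = [
            {
                "site_id": f"S{rng.integers(3)}",
                "year": int(rng.integers(2000, 2003)),
                "compound": "DIC",
                "f14c": float(rng.uniform(0.8, 1.2)),
            }
            for _ in range(40)
        ]
        obs = _obs_frame(rows)
        once = collapse_repeats(obs)
        twice = collapse_repeats(once)
        assert len(once) <= len(obs)
        pd.testing.assert_frame_equal(
            once.data.reset_index(drop=True), twice.data.reset_index(drop=True)
        )


class TestClassifications:
    @pytest.mark.parametrize(
        "area, binary, expo",
        [
            (10.0, "small", "0-10"),
            (10.1, "large", "100"),
            (0.5, "small", "0-10"),
            (100.0, "large", "100"),
            (100.5, "large", "1000"),
            (250000.0, "large", "1000000"),
            (5e6, "large", "1000000"),
        ],
    )
    def test_size_examples(self, area, binary, expo):
        sc = classify_size(area)
        assert sc.binary == binary and sc.exponential == expo

    def test_size_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            classify_size(0.0)

    @settings(max_examples=300, derandomize=True)
    @given(area=st.floats(1e-6, 1e9))
    def test_size_partitions_positive_reals(self, area):
        sc = classify_size(area)
        assert sc.exponential in SIZE_CLASSES
        assert (sc.binary == "small") == (sc.exponential == "0-10")

    def test_lithology_mapping_total_and_exact(self):
        assert simplify_lithology("SC") == "sedimentary"
        assert simplify_lithology("PY") == "igneous"
        assert simplify_lithology("IG") == "excluded"
        for code, cls in LITHOLOGY_MAP.items():
            assert simplify_lithology(code) == cls
        # surjective onto the three target classes
        assert set(LITHOLOGY_MAP.values()) == {
            "sedimentary",
            "igneous",
            "metamorphic",
            "excluded",
        }
        with pytest.warns(UserWarning):
            assert simplify_lithology("XX") == "excluded"

    def test_biome_mapping(self):
        assert simplify_biome(9) == "tropical grasslands and shrublands"
        assert simplify_biome(11) == "tundra"
        assert simplify_biome(15) == "deserts"
        assert len(set(BIOME_MAP.values())) == 8
        for code in BIOME_MAP:
            assert simplify_biome(code) == BIOME_MAP[code]
        with pytest.warns(UserWarning):
            assert simplify_biome(14) == "unclassified"


class TestSummarize:
    def test_single_observation(self):
        obs = _obs_frame(
            [{"site_id": "A", "year": 2000, "compound": "DIC", "f14c": 0.9}]
        )
        (g,) = summarize(obs)
        assert g.n == 1 and g.mean == g.median == 0.9 and g.sd == 0.0

    def test_fraction_above_one(self):
        obs = _obs_frame(
            [
                {"site_id": "A", "year": 2000, "compound": "DIC", "f14c": 0.8},
                {"site_id": "B", "year": 2000, "compound": "DIC", "f14c": 1.2},
            ]
        )
        (g,) = summarize(obs)
        assert g.mean == pytest.approx(1.0)
        assert g.fraction_above_one == pytest.approx(0.5)

    def test_large_sample_moments(self):
        rng = np.random.default_rng(11)
        vals = np.abs(rng.normal(0.92, 0.18, 5000))
        obs = _obs_frame(
            [
                {"site_id": f"S{i}", "year": 2000, "compound": "DIC", "f14c": v}
                for i, v in enumerate(vals)
            ]
        )
        (g,) = summarize(obs)
        assert g.mean == pytest.approx(0.92, abs=0.01)
        assert g.sd == pytest.approx(0.18, abs=0.01)

    def test_grouped_and_normalized(self, flat_record):
        obs = _obs_frame(
            [
                {"site_id": "A", "year": 2000, "compound": "DIC", "f14c": 1.25},
                {"site_id": "B", "year": 2000, "compound": "CO2", "f14c": 2.5},
            ]
        )
        groups = summarize(
            obs, group_by="compound", normalized=True, record=flat_record
        )
        by_name = {g.group: g for g in groups}
        assert by_name["DIC"].mean == pytest.approx(1.0)
        assert by_name["CO2"].mean == pytest.approx(2.0)


class TestPairedOffset:
    def test_printed_pair(self):
        obs = _obs_frame(
            [
                {"site_id": "A", "year": 2000, "date": "2000-05-01",
                 "compound": "DIC", "f14c": 1.0},
                {"site_id": "A", "year": 2000, "date": "2000-05-01",
                 "compound": "CO2", "f14c": 0.98},
            ]
        )
        res = paired_offset(obs)
        assert res.n_pairs == 1
        assert res.mean_offset == pytest.approx(0.02)
        assert round(res.age_equivalents[0]) == 162

    def test_identical_pair_zero(self):
        obs = _obs_frame(
            [
                {"site_id": "A", "year": 2000, "compound": "DIC", "f14c": 0.95},
                {"site_id": "A", "year": 2000, "compound": "CO2", "f14c": 0.95},
            ]
        )
        res = paired_offset(obs)
        assert res.mean_offset == 0.0 and res.age_equivalents[0] == 0.0

    def test_three_pairs_mean_and_max(self):
        rows = []
        for i, off in enumerate((0.01, 0.02, 0.03)):
            rows.append({"site_id": f"S{i}", "year": 2000, "compound": "DIC",
                         "f14c": 1.0})
            rows.append({"site_id": f"S{i}", "year": 2000, "compound": "CO2",
                         "f14c": 1.0 - off})
        res = paired_offset(_obs_frame(rows))
        assert res.n_pairs == 3
        assert res.mean_offset == pytest.approx(0.02)
        assert res.max_offset == pytest.approx(0.03)

    def test_no_pairs_returns_none(self):
        obs = _obs_frame(
            [{"site_id": "A", "year": 2000, "compound": "DIC", "f14c": 1.0}]
        )
        assert paired_offset(obs) is None


def test_group_test_detects_separated_groups():
    rng = np.random.default_rng(3)
    rows = []
    for i in range(60):
        rows.append(
            {"site_id": f"A{i}", "year": 2000, "compound": "DIC",
             "f14c": float(rng.normal(0.85, 0.02)), "lithology_raw": "SC"}
        )
        rows.append(
            {"site_id": f"B{i}", "year": 2000, "compound": "DIC",
             "f14c": float(rng.normal(0.96, 0.02)), "lithology_raw": "MT"}
        )
    obs = _obs_frame(rows)
    db._attach_classes(obs.data)
    stat, p = group_test(obs, "lithology")
    assert p < 1e-6
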