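"""Record validation, CSV round-trips, distances and the transfer table."""

import math

import numpy as np
import pandas as pd
import pytest

from pollenflow import io as pio
from pollenflow.datamodel import (
    CameraRecord,
    CommunityMatrix,
    DyeObservation,
    GerminationRecord,
    PlantRecord,
    ValidationError,
)
from pollenflow.transfers import (
    DyeSource,
    build_transfer_table,
    classify_transfer,
    distance_matrix,
    estimate_total_flowers,
    pairwise_distance,
    transfer_summary,
)


def make_plant(**kw):
    base = dict(plant_id="p1", population_id="A", ecotype="Ca", x=0.0, y=0.0,
                role="recipient", n_inflorescences=3,
                open_flowers_on_five_infl=[2, 2, 2], n_flowers_sampled=7)
    base.update(kw)
    return PlantRecord(**base)


class TestValidation:
    def test_negative_particle_count_rejected(self):
        with pytest.raises(ValidationError, match="particle_count"):
            DyeObservation("p1", "f1", "blue", -1)

    def test_bad_enum_values_rejected(self):
        with pytest.raises(ValidationError):
            make_plant(ecotype="Xx")
        with pytest.raises(ValidationError):
            DyeObservation("p1", "f1", "violet", 2)

    def test_non_finite_coordinates_rejected(self):
        with pytest.raises(ValidationError, match="coordinate"):
            make_plant(x=float("nan"))

    def test_germination_invariants(self):
        with pytest.raises(ValidationError):
            GerminationRecord("A", "Ca", 100, 120, 0, 0)
        with pytest.raises(ValidationError):
            GerminationRecord("A", "Ca", 100, 50, 40, 20)

    def test_camera_rate_consistency(self):
        rec = CameraRecord("A", "Ca", "2020-05-19", 7.25, 34, 1, 1)
        assert rec.visits_per_h == pytest.approx(1 / 7.25)
        with pytest.raises(ValidationError):
            CameraRecord("A", "Ca", "d", 0.0, 10, 0, 0)

    def test_community_matrix_invariants(self):
        df = pd.DataFrame({"t1": [1, 2], "t2": [0, 3]}, index=["a", "b"])
        m = CommunityMatrix(df, ["Ca", "Si"], [2019, 2019])
        assert m.taxa == ["t1", "t2"]
        with pytest.raises(ValidationError):
            CommunityMatrix(df.rename(index={"b": "a"}), ["Ca", "Si"], [2019, 2019])
        with pytest.raises(ValidationError):
            CommunityMatrix(df - 5, ["Ca", "Si"], [2019, 2019])


class TestIO:
    def test_empty_dye_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "dye.csv"
        p.write_text("plant_id,flower_id,dye_color,particle_count\n")
        assert pio.read_dye_observations(p) == []

    def test_plant_round_trip(self, tmp_path):
        plants = [make_plant(plant_id=f"p{i}", x=float(i), y=2.0 * i) for i in range(3)]
        path = tmp_path / "plants.csv"
        pio.write_plants(plants, path)
        assert pio.read_plants(path) == plants

    @pytest.mark.parametrize("writer,reader,records", [
        (pio.write_dye_observations, pio.read_dye_observations,
         [DyeObservation("p1", "f1", "blue", 3), DyeObservation("p1", "f2", "blue", 0)]),
        (pio.write_cameras, pio.read_cameras,
         [CameraRecord("A", "Ca", "2020-05-19", 2.5, 30, 5, 2)]),
        (pio.write_germination, pio.read_germination,
         [GerminationRecord("A", "Si", 150, 140, 2, 1)]),
    ])
    def test_round_trips(self, tmp_path, writer, reader, records):
        path = tmp_path / "t.csv"
        writer(records, path)
        assert reader(path) == records

    def test_community_round_trip(self, tmp_path):
        df = pd.DataFrame({"t1": [1, 2], "t2": [0, 3]}, index=["a", "b"])
        m = CommunityMatrix(df, ["Ca", "Si"], [2019, 2020])
        path = tmp_path / "c.csv"
        pio.write_community(m, path)
        m2 = pio.read_community(path)
        pd.testing.assert_frame_equal(m.counts, m2.counts)
        assert list(m2.ecotype) == ["Ca", "Si"]

    def test_validation_error_names_row(self, tmp_path):
        p = tmp_path / "dye.csv"
        p.write_text("plant_id,flower_id,dye_color,particle_count\n"
                     "p1,f1,blue,2\np1,f2,blue,-1\n")
        with pytest.raises(ValidationError, match="row 2"):
            pio.read_dye_observations(p)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "dye.csv"
        p.write_text("plant_id,flower_id,particle_count\np1,f1,2\n")
        with pytest.raises(pio.SchemaError, match="dye_color"):
            pio.read_dye_observations(p)

    def test_latlon_helper_scale(self):
        # 0.01 deg latitude is ~1111 m anywhere
        x, y = pio.latlon_to_planar([50.0, 50.01], [5.0, 5.0])
        assert np.hypot(x[1] - x[0], y[1] - y[0]) == pytest.approx(1111.9, rel=1e-3)


class TestDistances:
    def test_three_four_five(self):
        a = make_plant(x=0, y=0)
        b = make_plant(plant_id="p2", x=3, y=4)
        assert pairwise_distance(a, b) == 5.0
        assert pairwise_distance(a, a) == 0.0

    def test_matrix_matches_brute_force(self, rng):
        pts = rng.uniform(0, 50, (10, 2))
        d = distance_matrix(pts)
        for i in range(10):
            for j in range(10):
                assert d[i, j] == pytest.approx(math.hypot(*(pts[i] - pts[j])))
        assert np.allclose(d, d.T)


class TestTotalFlowers:
    def test_examples(self):
        assert estimate_total_flowers(make_plant(
            n_inflorescences=10, open_flowers_on_five_infl=[2] * 5)) == 20.0
        assert estimate_total_flowers(make_plant(
            n_inflorescences=4, open_flowers_on_five_infl=[1, 3])) == 8.0

    def test_empty_counts_error(self):
        with pytest.raises(ValueError, match="no inflorescence"):
            estimate_total_flowers(make_plant(open_flowers_on_five_infl=[]))

    def test_randomized_against_oracle(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 9, rng.integers(1, 6)).tolist()
            n = int(rng.integers(1, 30))
            p = make_plant(n_inflorescences=n, open_flowers_on_five_infl=counts)
            assert estimate_total_flowers(p) == pytest.approx(n * sum(counts) / len(counts))


SRC = {"blue": DyeSource("A", "Ca", 0.0, 0.0)}


class TestTransferTable:
    def test_mean_and_sum_arithmetic(self):
        p = make_plant(x=10, y=0, n_flowers_sampled=7)
        obs = [DyeObservation("p1", f"f{i}", "blue", c)
               for i, c in enumerate([0, 0, 2, 0, 1, 0, 0])]
        t = build_transfer_table([p], obs, SRC)
        assert t.loc[0, "sum_count"] == 3
        assert t.loc[0, "mean_count_per_flower"] == pytest.approx(3 / 7)
        assert t.loc[0, "n_flowers_with_dye"] == 2

    def test_all_zero_recipient_still_one_record_per_color(self):
        p = make_plant(x=5, y=0)
        src2 = {**SRC, "pink": DyeSource("B", "Si", 100.0, 0.0)}
        t = build_transfer_table([p], [], src2)
        assert len(t) == 2
        assert (t["sum_count"] == 0).all()
        assert (t["mean_count_per_flower"] == 0).all()

    def test_unmapped_color_error(self):
        p = make_plant(x=5, y=0)
        with pytest.raises(ValidationError, match="source mapping"):
            build_transfer_table([p], [DyeObservation("p1", "f1", "pink", 1)], SRC)

    def test_class_labels_match_independent_oracle(self, default_landscape, default_transfers):
        cfg, plants, dye, src = default_landscape
        eco = {p.plant_id: p.ecotype for p in plants}
        pop = {p.plant_id: p.population_id for p in plants}
        for row in default_transfers.itertuples():
            s = src[row.dye_color]
            assert row.direction == f"{s.ecotype}To{eco[row.recipient_id]}"
            if s.population_id == pop[row.recipient_id]:
                expected = "intrapopulation"
            elif s.ecotype == eco[row.recipient_id]:
                expected = "intra_ecotypic"
            else:
                expected = "inter_ecotypic"
            assert row.transfer_class == expected

    def test_sum_mean_invariant_on_synthetic(self, default_transfers):
        t = default_transfers
        err = (t["sum_count"] - t["mean_count_per_flower"] * t["n_flowers_sampled"]).abs()
        assert (err < 1e-9).all()

    def test_classify_transfer_direct(self):
        src = DyeSource("A", "Ca", 0, 0)
        assert classify_transfer(src, make_plant(population_id="A")) == \
            ("intrapopulation", "CaToCa")
        assert classify_transfer(src, make_plant(population_id="B", ecotype="Si")) == \
            ("inter_ecotypic", "CaToSi")


class TestTransferSummary:
    def _table(self, sums, n_hits=None):
        recs = []
        n_hits = n_hits or [min(s, 7) for s in sums]
        for i, s in enumerate(sums):
            p = make_plant(plant_id=f"p{i}", x=10, y=0)
            obs = [DyeObservation(f"p{i}", f"f{j}", "blue", 1)
                   for j in range(n_hits[i])]
            if s == 0:
                obs = []
            recs.append((p, obs))
        plants = [p for p, _ in recs]
        obs = [o for _, os_ in recs for o in os_]
        return build_transfer_table(plants, obs, SRC)

    def test_half_of_recipients_with_dye(self):
        t = self._table([1, 1, 0, 0])
        s = transfer_summary(t)
        assert s.loc[0, "pct_individuals_with_dye"] == 50.0

    def test_all_zero_gives_zero_mean_and_se(self):
        t = self._table([0, 0, 0])
        s = transfer_summary(t)
        assert s.loc[0, "pct_individuals_with_dye"] == 0.0
        assert s.loc[0, "mean_pct_flowers_with_dye"] == 0.0
        assert s.loc[0, "se_pct_flowers_with_dye"] == 0.0

    def test_flower_percentage_matches_binomial_truth(self, rng):
        # 200 recipients, 7 flowers each, per-flower hit probability 0.3
        plants, obs = [], []
        for i in range(200):
            plants.append(make_plant(plant_id=f"p{i}", x=10, y=0))
            for j in range(7):
                c = int(rng.uniform() < 0.3)
                obs.append(DyeObservation(f"p{i}", f"f{j}", "blue", c))
        s = transfer_summary(build_transfer_table(plants, obs, SRC))
        mean = s.loc[0, "mean_pct_flowers_with_dye"]
        se = 100 * math.sqrt(0.3 * 0.7 / 7) / math.sqrt(200)
        assert abs(mean - 30.0) < 3 * se

    def test_invariant_to_row_order_and_file_split(self, default_landscape):
        cfg, plants, dye, src = default_landscape
        t1 = build_transfer_table(plants, dye, src)
        t2 = build_transfer_table(plants[::-1], dye[::-1], src)
        s1 = transfer_summary(t1).sort_values(
            ["source_population", "recipient_population"]).reset_index(drop=True)
        s2 = transfer_summary(t2).sort_values(
            ["source_population", "recipient_population"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(s1, s2)
        # splitting the dye observations into parts does not change sums
        half = len(dye) // 2
        t3 = build_transfer_table(plants, dye[:half] + dye[half:], src)
        pd.testing.assert_frame_equal(
            t1.sort_values(["recipient_id", "dye_color"]).reset_index(drop=True),
            t3.sort_values(["recipient_id", "dye_color"]).reset_index(drop=True))
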