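"""Enzymatic normalization, MHI/MRC indices, and qPCR mtDNA measures."""

import math

import numpy as np
import pytest

from mitomotor.bioenergetics import (
    ASSAYS,
    EnzymeAssayRecord,
    QpcrRecord,
    build_feature_table,
    mean_center,
    mhi,
    mrc,
    mrc_per_animal,
    mtdna_cn,
    mtdna_density,
    plate_normalize,
    specific_activity,
)


def rec(sample, plate, assay, r1, r2, nonspec, ref=False):
    return EnzymeAssayRecord(sample, plate, assay, r1, r2, nonspec, ref)


class TestSpecificActivity:
    def test_duplicate_mean_minus_nonspecific(self):
        assert specific_activity(rec("s", "P1", "CI", 10, 12, 1)) == 10.0
        assert specific_activity(rec("s", "P1", "CI", 5, 5, 5)) == 0.0

    def test_single_surviving_duplicate_used(self):
        assert specific_activity(rec("s", "P1", "CI", 8.0, None, 2.0)) == 6.0

    def test_both_duplicates_missing_rejected(self):
        with pytest.raises(ValueError, match="duplicates missing"):
            specific_activity(rec("s", "P1", "CI", None, None, 1.0))

    def test_matches_arithmetic_oracle(self, rng):
        for _ in range(20):
            r1, r2, ns = rng.uniform(1, 50, size=3)
            got = specific_activity(rec("s", "P1", "CS", r1, r2, ns))
            assert got == pytest.approx((r1 + r2) / 2 - ns, abs=1e-12)


def two_plate_records(effect=2.0):
    """Plate P2's wells all scaled by `effect` relative to P1."""
    records = []
    for assay in ASSAYS:
        for plate, eff in (("P1", 1.0), ("P2", effect)):
            for j in range(5):  # reference aliquots at true activity 10
                records.append(rec(f"ref-{assay}-{plate}-{j}", plate, assay,
                                   10 * eff + 2, 10 * eff + 2, 2, ref=True))
            for j in range(3):  # samples at true activities 6, 8, 12
                true = [6.0, 8.0, 12.0][j]
                records.append(rec(f"s{j}-{plate}", plate, assay,
                                   true * eff + 2, true * eff + 2, 2))
    return records


class TestPlateNormalize:
    def test_single_plate_is_identity(self):
        records = [r for r in two_plate_records() if r.plate_id == "P1"]
        out = plate_normalize(records)
        np.testing.assert_allclose(out["normalized_activity"],
                                   out["specific_activity"], atol=1e-12)

    def test_known_plate_effect_recovered(self):
        out = plate_normalize(two_plate_records(effect=2.0))
        refs = out[out["is_reference"]]
        for assay, sub in refs.groupby("assay"):
            means = sub.groupby("plate_id")["normalized_activity"].mean()
            assert means["P1"] == pytest.approx(means["P2"], rel=1e-9)
        # sample activities on the scaled plate come back to plate-1 scale
        samples = out[~out["is_reference"]].set_index("sample_id")
        for j, true in enumerate([6.0, 8.0, 12.0]):
            a = samples.loc[f"s{j}-P1"].groupby("assay")["normalized_activity"].mean()
            b = samples.loc[f"s{j}-P2"].groupby("assay")["normalized_activity"].mean()
            np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_idempotent(self):
        out = plate_normalize(two_plate_records())
        again = [rec(r.sample_id, r.plate_id, r.assay,
                     r.normalized_activity, r.normalized_activity, 0.0,
                     r.is_reference)
                 for r in out.itertuples()]
        out2 = plate_normalize(again)
        np.testing.assert_allclose(out2["normalized_activity"],
                                   out["normalized_activity"], rtol=1e-12)

    def test_missing_references_named_in_error(self):
        records = [r for r in two_plate_records()
                   if not (r.plate_id == "P2" and r.is_reference
                           and r.assay == "CIV")]
        with pytest.raises(ValueError, match="P2.*CIV"):
            plate_normalize(records)

    def test_negative_specific_activity_flagged_not_clamped(self):
        records = [r for r in two_plate_records() if r.plate_id == "P1"]
        records.append(rec("neg", "P1", "CI", 1.0, 1.0, 5.0))
        out = plate_normalize(records).set_index("sample_id")
        assert out.loc["neg", "qc_negative"]
        assert out.loc["neg", "specific_activity"] == -4.0


class TestMeanCenter:
    def test_examples(self):
        np.testing.assert_allclose(mean_center([3.0, 3.0, 3.0]), [1, 1, 1])
        np.testing.assert_allclose(mean_center([2.0, 4.0]), [2 / 3, 4 / 3])

    def test_output_mean_is_one_and_idempotent(self, rng):
        v = rng.uniform(0.5, 5.0, size=17)
        c = mean_center(v)
        assert c.mean() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(mean_center(c), c, atol=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            mean_center([-1.0, 1.0])


class TestMhiMrc:
    def test_average_animal_scores_100(self):
        assert mhi(1, 1, 1, 1, 1) == pytest.approx(100.0, abs=1e-12)

    def test_zero_numerator(self):
        assert mhi(0, 0, 0, 1, 1) == 0.0

    def test_matches_direct_formula(self, rng):
        for _ in range(20):
            ci, cii, civ, cs, d = rng.uniform(0.2, 2.0, size=5)
            assert mhi(ci, cii, civ, cs, d) == pytest.approx(
                (ci + cii + civ) / (cs + d + 1) * 100, abs=1e-12)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            mhi(1, 1, 1, -0.6, -0.6)

    def test_mrc_unit_features(self):
        ones = np.ones(4)
        assert mrc(ones, ones, ones, ones, ones) == pytest.approx(150.0, abs=1e-12)

    def test_mrc_single_animal_exact_roots(self):
        assert mrc([4.0], [4.0], [4.0], [1.0], [1.0]) == pytest.approx(300.0)
        assert mrc_per_animal([4.0], [4.0], [4.0], [1.0], [1.0])[0] == \
            pytest.approx(300.0)

    def test_mrc_matches_direct_formula(self, rng):
        feats = [rng.uniform(0.3, 2.0, size=6) for _ in range(5)]
        ci, cii, civ, cs, d = feats
        expected = (np.mean(np.sqrt(ci) + np.sqrt(cii) + np.sqrt(civ))
                    / np.mean(np.cbrt(d) + np.cbrt(cs)) * 100)
        assert mrc(ci, cii, civ, cs, d) == pytest.approx(expected, abs=1e-12)

    def test_mrc_negative_feature_rejected(self):
        with pytest.raises(ValueError):
            mrc([1.0], [1.0], [-0.1], [1.0], [1.0])


class TestQpcr:
    def test_delta_ct_examples(self):
        assert mtdna_cn(QpcrRecord("s", (20, 20, 20), (20, 20, 20))) == 2.0
        assert mtdna_cn(QpcrRecord("s", (20, 20, 20), (25, 25, 25))) == 64.0

    def test_doubling_in_delta_ct(self):
        base = mtdna_cn(QpcrRecord("s", (20, 20, 20), (23, 23, 23)))
        up = mtdna_cn(QpcrRecord("s", (20, 20, 20), (24, 24, 24)))
        assert up == pytest.approx(2 * base, rel=1e-12)

    def test_outlier_replicate_dropped(self):
        # 22 is >1 Ct from median(20, 20.2, 22); mean of survivors = 20.1
        got = mtdna_cn(QpcrRecord("s", (20.0, 20.2, 22.0), (25.0, 25.0, 25.0)))
        assert got == pytest.approx(2 ** (25.0 - 20.1) * 2, rel=1e-12)

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            mtdna_cn(QpcrRecord("s", (20.0, None, None), (25, 25, 25)))

    def test_density_as_printed_and_inverse(self):
        r = QpcrRecord("s", (10.0, 10.0, 10.0), (25, 25, 25))
        assert mtdna_density(r) == pytest.approx(1024e-12, rel=1e-12)
        assert mtdna_density(r, direction="inverse") == \
            pytest.approx(2**-10 * 1e-12, rel=1e-12)

    def test_density_matches_direct_evaluation(self, rng):
        for _ in range(10):
            cts = tuple(rng.uniform(15, 16, size=3))
            r = QpcrRecord("s", cts, (25, 25, 25))
            assert mtdna_density(r) == pytest.approx(
                2 ** np.mean(cts) * 1e-12, rel=1e-12)


class TestFeatureTable:
    def test_cohort_centering_and_indices(self, rng):
        records = []
        n = 8
        truth = {}
        for assay in ASSAYS:
            for i in range(n):
                v = float(rng.uniform(5, 15))
                truth[(f"a{i}", assay)] = v
                records.append(rec(f"a{i}", "P1", assay, v + 1, v + 1, 1.0))
            for j in range(5):
                records.append(rec(f"r{j}{assay}", "P1", assay, 11, 11, 1.0,
                                   ref=True))
        qpcr = [QpcrRecord(f"a{i}", tuple(rng.uniform(14, 15, 3)),
                           tuple(rng.uniform(24, 25, 3))) for i in range(n)]
        table = build_feature_table(records, qpcr)
        assert len(table) == n
        for feat in ("ci", "cii", "civ", "cs", "mtdna_density"):
            assert table[f"{feat}_centered"].mean() == pytest.approx(1.0, abs=1e-12)
        # MHI recomputed from the centered columns
        row = table.iloc[0]
        assert row["mhi"] == pytest.approx(
            mhi(row["ci_centered"], row["cii_centered"], row["civ_centered"],
                row["cs_centered"], row["mtdna_density_centered"]), abs=1e-12)
        assert table.attrs["mrc_cohort"] > 0

    def test_all_average_cohort_scores_100_everywhere(self):
        records = []
        for assay in ASSAYS:
            for i in range(4):
                records.append(rec(f"a{i}", "P1", assay, 11, 11, 1.0))
            records.append(rec(f"r{assay}", "P1", assay, 11, 11, 1.0, ref=True))
        qpcr = [QpcrRecord(f"a{i}", (15, 15, 15), (25, 25, 25)) for i in range(4)]
        table = build_feature_table(records, qpcr)
        np.testing.assert_allclose(table["mhi"], 100.0, atol=1e-9)
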