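"""Summary-statistics IO and allele-aware harmonization."""

import numpy as np
import pytest

from mrbma import (
    ConfigurationError,
    ExposurePanel,
    InputError,
    OutcomePanel,
    TableSpec,
    VariantKey,
    harmonize,
    read_exposure_table,
    read_harmonized,
    read_outcome_table,
    write_harmonized,
)
from mrbma.data_model import ABSENT_IN_OUTCOME
from mrbma.synthetic_data import scenario_library, simulate


def _vk(ident, chrom="1", pos=1000, ea="A", oa="G"):
    return VariantKey(ident, chrom, pos, ea, oa)


WIDE_HEADER = "variant\tchrom\tpos\tea\toa\tbeta_LDL\tbeta_HDL\n"


class TestVariantKey:
    def test_invariants_enforced(self):
        with pytest.raises(InputError):
            VariantKey("rs1", "1", 0, "A", "G")
        with pytest.raises(InputError):
            VariantKey("rs1", "1", 10, "A", "A")
        with pytest.raises(InputError):
            VariantKey("rs1", "1", 10, "A", "N")

    @pytest.mark.parametrize("ea,oa,expected", [
        ("A", "T", True), ("C", "G", True), ("A", "G", False), ("C", "T", False),
    ])
    def test_palindromic_detection(self, ea, oa, expected):
        assert _vk("rs1", ea=ea, oa=oa).is_palindromic is expected


class TestExposureReader:
    def test_wide_layout_shape_and_order(self, tmp_path):
        path = tmp_path / "exp.tsv"
        path.write_text(WIDE_HEADER
                        + "rs1\t1\t100\tA\tG\t0.1\t-0.2\n"
                        + "rs2\t1\t200\tC\tT\t0.3\t0.4\n"
                        + "rs3\t2\t300\tG\tA\t-0.5\t0.6\n")
        panel = read_exposure_table(path)
        assert panel.beta_x.shape == (3, 2)
        assert panel.factors == ["LDL", "HDL"]
        assert [v.identifier for v in panel.variants] == ["rs1", "rs2", "rs3"]
        np.testing.assert_allclose(panel.beta_x[2], [-0.5, 0.6])

    def test_long_layout_missing_cell_propagates(self, tmp_path):
        path = tmp_path / "exp_long.tsv"
        path.write_text(
            "variant\tchrom\tpos\tea\toa\tfactor\tbeta\n"
            "rs1\t1\t100\tA\tG\tLDL\t0.1\n"
            "rs1\t1\t100\tA\tG\tHDL\t0.2\n"
            "rs2\t1\t200\tC\tT\tLDL\t0.3\n")
        panel = read_exposure_table(path, TableSpec(layout="long"))
        assert panel.beta_x.shape == (2, 2)
        assert np.isnan(panel.beta_x[1, 1])  # rs2 x HDL never supplied

    def test_non_numeric_beta_names_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(WIDE_HEADER
                        + "rs1\t1\t100\tA\tG\t0.1\t0.2\n"
                        + "rs2\t1\t200\tC\tT\toops\t0.4\n")
        with pytest.raises(InputError, match="row 2"):
            read_exposure_table(path)

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "nocol.tsv"
        path.write_text("variant\tchrom\tpos\tea\tbeta_LDL\nrs1\t1\t100\tA\t0.1\n")
        with pytest.raises(ConfigurationError, match="oa"):
            read_exposure_table(path)

    def test_duplicate_variant_factor_pair_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "variant\tchrom\tpos\tea\toa\tfactor\tbeta\n"
            "rs1\t1\t100\tA\tG\tLDL\t0.1\n"
            "rs1\t1\t100\tA\tG\tLDL\t0.2\n")
        with pytest.raises(InputError, match="duplicate"):
            read_exposure_table(path, TableSpec(layout="long"))


class TestOutcomeReader:
    def test_basic_read(self, tmp_path):
        path = tmp_path / "out.tsv"
        path.write_text("variant\tchrom\tpos\tea\toa\tbeta\tse\n"
                        "rs1\t1\t100\tA\tG\t0.05\t0.01\n"
                        "rs2\t1\t200\tC\tT\t-0.02\t0.02\n"
                        "rs3\t2\t300\tG\tA\t0.10\t0.03\n")
        panel = read_outcome_table(path)
        assert len(panel.variants) == 3
        np.testing.assert_allclose(panel.beta_y, [0.05, -0.02, 0.10])

    def test_zero_se_rejected(self, tmp_path):
        path = tmp_path / "out.tsv"
        path.write_text("variant\tchrom\tpos\tea\toa\tbeta\tse\n"
                        "rs1\t1\t100\tA\tG\t0.05\t0.0\n")
        with pytest.raises(InputError, match="row 1"):
            read_outcome_table(path)

    def test_extra_columns_ignored(self, tmp_path, caplog):
        path = tmp_path / "out.tsv"
        path.write_text("variant\tchrom\tpos\tea\toa\tbeta\tse\teaf\tinfo\n"
                        "rs1\t1\t100\tA\tG\t0.05\t0.01\t0.3\t0.99\n")
        panel = read_outcome_table(path)
        assert len(panel.variants) == 1


class TestHarmonize:
    def _exposure(self, variants):
        beta = np.arange(len(variants) * 2, dtype=float).reshape(len(variants), 2) / 10
        return ExposurePanel(variants=variants, factors=["LDL", "HDL"], beta_x=beta)

    def test_matching_alleles_retained_unchanged(self):
        exp = self._exposure([_vk("rs1")])
        out = OutcomePanel([_vk("rs1")], beta_y=[0.1], se_y=[0.02])
        ds = harmonize(exp, out)
        assert ds.beta_y[0] == pytest.approx(0.1)
        assert ds.provenance == []

    def test_swapped_alleles_flip_sign(self):
        exp = self._exposure([_vk("rs1", ea="A", oa="G")])
        out = OutcomePanel([_vk("rs1", ea="G", oa="A")], beta_y=[0.1], se_y=[0.02])
        ds = harmonize(exp, out)
        assert ds.beta_y[0] == pytest.approx(-0.1)

    def test_irreconcilable_alleles_dropped_with_reason(self):
        exp = self._exposure([_vk("rs1", ea="A", oa="G"), _vk("rs2")])
        out = OutcomePanel([_vk("rs1", ea="C", oa="T"), _vk("rs2")],
                           beta_y=[0.1, 0.2], se_y=[0.02, 0.02])
        ds = harmonize(exp, out)
        assert [v.identifier for v in ds.variants] == ["rs2"]
        assert ("rs1", "allele_mismatch") in ds.provenance

    def test_missing_outcome_variants_recorded(self):
        """An exposure panel whose outcome lacks 2 of 150 variants keeps 148."""
        variants = [_vk(f"rs{i}", pos=100 + i) for i in range(150)]
        exp = self._exposure(variants)
        out = OutcomePanel(variants[:-2], beta_y=np.full(148, 0.05), se_y=np.full(148, 0.02))
        ds = harmonize(exp, out)
        assert ds.n_variants == 148
        missing = {v for v, r in ds.provenance if r == ABSENT_IN_OUTCOME}
        assert missing == {"rs148", "rs149"}

    def test_palindromic_kept_by_default_dropped_by_flag(self):
        exp = self._exposure([_vk("rs1", ea="A", oa="T"), _vk("rs2")])
        out = OutcomePanel([_vk("rs1", ea="A", oa="T"), _vk("rs2")],
                           beta_y=[0.1, 0.2], se_y=[0.02, 0.02])
        assert harmonize(exp, out).n_variants == 2
        ds = harmonize(exp, out, drop_palindromic=True)
        assert ds.n_variants == 1
        assert ("rs1", "palindromic") in ds.provenance

    def test_empty_intersection_is_input_error(self):
        exp = self._exposure([_vk("rs1")])
        out = OutcomePanel([_vk("rs9")], beta_y=[0.1], se_y=[0.02])
        with pytest.raises(InputError):
            harmonize(exp, out)

    def test_idempotent_on_harmonized_output(self):
        exposure, outcome, _ = simulate(scenario_library()["null"])
        ds = harmonize(exposure, outcome)
        again = harmonize(*ds.to_panels())
        np.testing.assert_array_equal(ds.beta_x, again.beta_x)
        np.testing.assert_array_equal(ds.beta_y, again.beta_y)
        assert [v.identifier for v in ds.variants] == [v.identifier for v in again.variants]

    def test_outcome_allele_flip_invariance(self):
        """Flipping every outcome allele pair and beta sign yields a bit-identical dataset."""
        exposure, outcome, _ = simulate(scenario_library()["null"])
        flipped = OutcomePanel(
            variants=[VariantKey(v.identifier, v.chromosome, v.position,
                                 v.other_allele, v.effect_allele)
                      for v in outcome.variants],
            beta_y=-outcome.beta_y,
            se_y=outcome.se_y,
        )
        a = harmonize(exposure, outcome)
        b = harmonize(exposure, flipped)
        np.testing.assert_array_equal(a.beta_y, b.beta_y)
        np.testing.assert_array_equal(a.beta_x, b.beta_x)

    def test_provenance_accounts_for_intersection_drops(self):
        variants = [_vk(f"rs{i}", pos=100 + i) for i in range(10)]
        exp = self._exposure(variants)
        beta_y = np.full(9, 0.05)
        beta_y[3] = np.nan  # rs3 has a missing outcome value
        out = OutcomePanel(variants[:9], beta_y=beta_y, se_y=np.full(9, 0.02))
        ds = harmonize(exp, out)
        in_intersection_drops = [p for p in ds.provenance if p[1] != ABSENT_IN_OUTCOME]
        assert len(in_intersection_drops) + ds.n_variants == 9


def test_harmonized_roundtrip_through_tsv(tmp_path, single_causal_dataset):
    ds, _ = single_causal_dataset
    path = tmp_path / "harmonized.tsv"
    write_harmonized(ds, path, tmp_path / "prov.tsv")
    back = read_harmonized(path)
    np.testing.assert_allclose(back.beta_x, ds.beta_x)
    np.testing.assert_allclose(back.beta_y, ds.beta_y)
    assert back.factors == ds.factors
    assert [v.identifier for v in back.variants] == [v.identifier for v in ds.variants]
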