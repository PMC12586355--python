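import logging

import numpy as np
import pandas as pd
import pytest

from mycolink.linkage import (
    SoilTable,
    classify_module_types,
    compare_trophic_across_types,
    module_abundance,
    module_soil_linkage,
    parse_guilds,
    trophic_composition,
    type_composition,
)
from mycolink.network import ModulePartition


def make_partition(mapping):
    return ModulePartition(assignment=dict(mapping), modularity=0.5, resolution=1.0)


def rel_table(rows, samples=4):
    arr = np.asarray(rows, dtype=float)
    arr = arr / arr.sum(axis=0)
    return pd.DataFrame(arr, index=[f"A{i}" for i in range(len(rows))],
                        columns=[f"s{j}" for j in range(samples)])


class TestModuleAbundance:
    def test_log10_identity(self):
        # one module holding the whole table: 100% x 4 samples = 400 -> log10
        t = rel_table([[5, 5, 5, 5], [5, 5, 5, 5]])
        part = make_partition({"A0": 0, "A1": 0})
        out = module_abundance(t, part)
        assert out.loc[0, "summed_abundance"] == pytest.approx(400.0)
        assert out.loc[0, "log_abundance"] == pytest.approx(np.log10(400.0))

    def test_partition_conserves_total(self):
        t = rel_table([[1, 2, 3, 1], [4, 1, 1, 1], [2, 2, 2, 2], [1, 1, 1, 3]])
        part = make_partition({"A0": 0, "A1": 0, "A2": 1, "A3": 1})
        out = module_abundance(t, part)
        assert out["summed_abundance"].sum() == pytest.approx(400.0)

    def test_toy_hand_summation(self):
        t = rel_table([[8, 0], [2, 0], [0, 5], [0, 3], [0, 2]], samples=2)
        part = make_partition({"A0": 0, "A1": 0, "A2": 1, "A3": 1, "A4": 1})
        out = module_abundance(t, part)
        assert out.loc[0, "summed_abundance"] == pytest.approx(100.0)
        assert out.loc[1, "summed_abundance"] == pytest.approx(100.0)

    def test_unknown_member_rejected(self):
        t = rel_table([[1, 1, 1, 1]])
        with pytest.raises(ValueError, match="absent"):
            module_abundance(t, make_partition({"A0": 0, "ghost": 0}))


def linked_fixture(seed=0, n=33, effect=1.0):
    """A module whose member abundances follow a soil variable exactly."""
    rng = np.random.default_rng(seed)
    driver = rng.normal(size=n)
    rows = []
    for _ in range(8):
        rows.append(np.exp(2 + effect * driver + 0.05 * rng.normal(size=n)))
    for _ in range(8):  # unlinked module
        lat = rng.normal(size=n)
        rows.append(np.exp(2 + lat + 0.05 * rng.normal(size=n)))
    t = rel_table(rows, samples=n)
    part = make_partition({f"A{i}": (0 if i < 8 else 1) for i in range(16)})
    soil = SoilTable(
        values=pd.DataFrame(
            {"EC": driver, "WSA": rng.normal(size=n)}, index=t.columns
        ),
        blocks={"EC": "chemical", "WSA": "aggregate"},
    )
    return t, part, soil


class TestModuleSoilLinkage:
    def test_planted_link_recovered(self):
        t, part, soil = linked_fixture()
        out = module_soil_linkage(t, part, soil, n_perm=199, seed=1)
        row = out[(out.module_id == 0) & (out.variable == "EC")].iloc[0]
        assert row.significant and row.r > 0.3

    def test_shuffled_soil_destroys_link(self):
        t, part, soil = linked_fixture()
        rng = np.random.default_rng(5)
        shuffled = SoilTable(
            values=soil.values.sample(frac=1.0, random_state=5).set_axis(
                soil.values.index
            ),
            blocks=soil.blocks,
        )
        out = module_soil_linkage(t, part, shuffled, n_perm=199, seed=1)
        row = out[(out.module_id == 0) & (out.variable == "EC")].iloc[0]
        assert row.r < 0.3

    def test_zero_variance_variable_flagged(self, caplog):
        t, part, soil = linked_fixture()
        soil = SoilTable(
            values=soil.values.assign(pH=5.7),
            blocks={**soil.blocks, "pH": "chemical"},
        )
        with caplog.at_level(logging.WARNING):
            out = module_soil_linkage(t, part, soil, n_perm=99, seed=0)
        flagged = out[out.variable == "pH"]
        assert (~flagged["tested"]).all()
        assert not flagged["significant"].any()

    def test_deterministic_with_seed(self):
        t, part, soil = linked_fixture()
        a = module_soil_linkage(t, part, soil, n_perm=199, seed=9)
        b = module_soil_linkage(t, part, soil, n_perm=199, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_bh_corrected_mode_adds_q(self):
        t, part, soil = linked_fixture()
        out = module_soil_linkage(t, part, soil, n_perm=99, seed=0, bh_correct=True)
        assert "q" in out.columns
        tested = out[out.tested]
        assert (tested["q"] >= tested["p"] - 1e-12).all()


class TestClassification:
    def make_linkage(self, entries):
        rows = []
        for m, var, block, sig in entries:
            rows.append({"module_id": m, "variable": var, "block": block,
                         "r": 0.3 if sig else 0.0, "p": 0.01 if sig else 0.8,
                         "significant": sig, "tested": True})
        return pd.DataFrame(rows)

    def test_chemical_only_is_mrc(self):
        link = self.make_linkage([(0, "pH", "chemical", True),
                                  (0, "WSA", "aggregate", False)])
        assert classify_module_types(link).loc[0, "module_type"] == "MRC"

    def test_both_blocks_is_mrca(self):
        link = self.make_linkage([(0, "EC", "chemical", True),
                                  (0, "MWD", "aggregate", True),
                                  (0, "GMD", "aggregate", True)])
        assert classify_module_types(link).loc[0, "module_type"] == "MRCA"

    def test_no_links_is_muca(self):
        link = self.make_linkage([(0, "EC", "chemical", False),
                                  (0, "WSA", "aggregate", False)])
        assert classify_module_types(link).loc[0, "module_type"] == "MUCA"

    def test_aggregate_only_is_flagged_mra(self, caplog):
        link = self.make_linkage([(0, "EC", "chemical", False),
                                  (0, "WSA", "aggregate", True)])
        with caplog.at_level(logging.WARNING):
            out = classify_module_types(link)
        assert out.loc[0, "module_type"] == "MRA"
        assert "MRA" in caplog.text

    def test_label_permutation_equivariance(self):
        entries = [(0, "EC", "chemical", True), (0, "WSA", "aggregate", False),
                   (1, "EC", "chemical", False), (1, "WSA", "aggregate", False)]
        base = classify_module_types(self.make_linkage(entries))
        swapped = classify_module_types(
            self.make_linkage([(1 - m, v, b, s) for m, v, b, s in entries])
        )
        assert base.loc[0, "module_type"] == swapped.loc[1, "module_type"]
        assert base.loc[1, "module_type"] == swapped.loc[0, "module_type"]


class TestParseGuilds:
    def table(self, rows):
        return pd.DataFrame(
            rows, columns=["asv_id", "trophic_mode", "confidence"]
        ).set_index("asv_id")

    def test_single_mode(self):
        w = parse_guilds(self.table([("a", "Saprotroph", "Highly Probable")]))
        assert w.loc["a", "saprotroph"] == 1.0
        assert w.loc["a"].sum() == 1.0

    def test_composite_splits_equally(self):
        w = parse_guilds(self.table([("a", "Pathotroph-Saprotroph", "Probable")]))
        assert w.loc["a", "pathotroph"] == 0.5
        assert w.loc["a", "saprotroph"] == 0.5

    def test_confidence_gate(self):
        w = parse_guilds(self.table([("a", "Saprotroph", "Possible")]))
        assert w.loc["a", "unassigned"] == 1.0

    def test_unknown_token_warns_and_unassigns(self, caplog):
        with caplog.at_level(logging.WARNING):
            w = parse_guilds(self.table([("a", "Lichenized", "Highly Probable")]))
        assert w.loc["a", "unassigned"] == 1.0
        assert "unknown trophic token" in caplog.text

    def test_nothing_dropped(self):
        t = self.table([("a", "-", "-"), ("b", "Symbiotroph", "Probable")])
        w = parse_guilds(t)
        assert set(w.index) == {"a", "b"}
        assert np.allclose(w.sum(axis=1), 1.0)


class TestTrophicComposition:
    def test_pure_module(self):
        t = rel_table([[1, 1], [1, 1]], samples=2)
        part = make_partition({"A0": 0, "A1": 0})
        w = pd.DataFrame(
            {"pathotroph": 0.0, "saprotroph": 1.0, "symbiotroph": 0.0,
             "unassigned": 0.0}, index=["A0", "A1"],
        )
        comp = trophic_composition(t, part, w)
        assert comp.loc[0, "saprotroph"] == pytest.approx(1.0)

    def test_equal_abundance_half_split(self):
        t = rel_table([[1, 1], [1, 1]], samples=2)
        part = make_partition({"A0": 0, "A1": 0})
        w = pd.DataFrame(
            [[1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 1.0]],
            columns=["pathotroph", "saprotroph", "symbiotroph", "unassigned"],
            index=["A0", "A1"],
        )
        comp = trophic_composition(t, part, w)
        assert comp.loc[0, "pathotroph"] == pytest.approx(0.5)
        assert comp.loc[0, "unassigned"] == pytest.approx(0.5)

    def test_abundance_vs_count_weighting(self):
        t = rel_table([[9, 9], [1, 1]], samples=2)
        part = make_partition({"A0": 0, "A1": 0})
        w = pd.DataFrame(
            [[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]],
            columns=["pathotroph", "saprotroph", "symbiotroph", "unassigned"],
            index=["A0", "A1"],
        )
        ab = trophic_composition(t, part, w)
        ct = trophic_composition(t, part, w, count_weighted=True)
        assert ab.loc[0, "pathotroph"] == pytest.approx(0.9)
        assert ct.loc[0, "pathotroph"] == pytest.approx(0.5)

    def test_type_level_is_abundance_weighted(self):
        comp = pd.DataFrame(
            {"pathotroph": [0.8, 0.2], "saprotroph": [0.1, 0.7],
             "symbiotroph": [0.05, 0.05], "unassigned": [0.05, 0.05]},
            index=pd.Index([0, 1], name="module_id"),
        )
        types = pd.DataFrame({"module_type": ["MRCA", "MRCA"]}, index=comp.index)
        abund = pd.DataFrame({"summed_abundance": [300.0, 100.0]}, index=comp.index)
        out = type_composition(comp, types, abund)
        assert out.loc["MRCA", "pathotroph"] == pytest.approx(
            (0.8 * 300 + 0.2 * 100) / 400
        )


class TestCompareAcrossTypes:
    def comp(self, shares_by_module, types):
        comp = pd.DataFrame(shares_by_module,
                            columns=["pathotroph", "saprotroph", "symbiotroph",
                                     "unassigned"])
        comp.index.name = "module_id"
        t = pd.DataFrame({"module_type": types}, index=comp.index)
        return comp, t

    def test_extreme_contrast_gets_distinct_letter(self):
        comp, types = self.comp(
            [[0.8, 0.1, 0.05, 0.05], [0.82, 0.1, 0.04, 0.04],
             [0.1, 0.8, 0.05, 0.05], [0.12, 0.78, 0.05, 0.05]],
            ["MRCA", "MRCA", "MUCA", "MUCA"],
        )
        out = compare_trophic_across_types(comp, types)
        letters = out["pathotroph"]["tukey"].letters
        assert letters["MRCA"] != letters["MUCA"]

    def test_identical_compositions_share_letters(self):
        comp, types = self.comp(
            [[0.5, 0.3, 0.1, 0.1], [0.501, 0.299, 0.1, 0.1],
             [0.4995, 0.3005, 0.1, 0.1], [0.5005, 0.2995, 0.1, 0.1]],
            ["MRC", "MRC", "MUCA", "MUCA"],
        )
        out = compare_trophic_across_types(comp, types)
        for mode in out:
            letters = out[mode]["tukey"].letters
            assert letters["MRC"] == letters["MUCA"]

    def test_small_type_excluded_with_warning(self, caplog):
        comp, types = self.comp(
            [[0.5, 0.3, 0.1, 0.1], [0.4, 0.4, 0.1, 0.1],
             [0.3, 0.5, 0.1, 0.1], [0.2, 0.6, 0.1, 0.1], [0.6, 0.2, 0.1, 0.1]],
            ["MRC", "MRC", "MUCA", "MUCA", "MRCA"],
        )
        with caplog.at_level(logging.WARNING):
            out = compare_trophic_across_types(comp, types)
        assert "MRCA" in caplog.text
        assert set(out["pathotroph"]["tukey"].letters) == {"MRC", "MUCA"}

    def test_fewer_than_two_types_rejected(self):
        comp, types = self.comp(
            [[0.5, 0.3, 0.1, 0.1], [0.4, 0.4, 0.1, 0.1]], ["MRC", "MRC"]
        )
        with pytest.raises(ValueError, match="2 module types"):
            compare_trophic_across_types(comp, types)
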