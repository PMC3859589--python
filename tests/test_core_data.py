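import numpy as np
import pandas as pd
import pytest

from metasucc import data, simulate


class TestLoadStemTable:
    def test_minimal_well_formed_rows(self, tmp_path):
        p = tmp_path / "stems.csv"
        pd.DataFrame([
            dict(site_id="A", plot_id="upper", species_code="X",
                 stratum="sapling", life_form="tree", diameter_cm=2.0),
            dict(site_id="A", plot_id="upper", species_code="Y",
                 stratum="tree", life_form="tree", diameter_cm=7.1),
            dict(site_id="A", plot_id="lower", species_code="Z",
                 stratum="liana", life_form="liana", diameter_cm=1.3),
        ]).to_csv(p, index=False)
        df, rep = data.load_stem_table(p)
        assert rep.n_valid == 3 and rep.n_rejected == 0

    @pytest.mark.parametrize("stratum,life_form,d,why", [
        ("tree", "tree", 3.0, "tree below 5 cm"),
        ("sapling", "tree", 0.5, "sapling below 1 cm"),
        ("sapling", "tree", 5.0, "sapling at 5 cm is a tree"),
        ("liana", "tree", 2.0, "liana stratum needs climbing life form"),
        ("tree", "liana", 7.0, "climber cannot be in tree stratum"),
        ("seedling", "tree", 2.0, "seedling with large diameter"),
    ])
    def test_invariant_violations_rejected(self, tmp_path, stratum, life_form, d, why):
        p = tmp_path / "stems.csv"
        pd.DataFrame([dict(site_id="A", plot_id="upper", species_code="X",
                           stratum=stratum, life_form=life_form,
                           diameter_cm=d)]).to_csv(p, index=False)
        _, rep = data.load_stem_table(p)
        assert rep.n_rejected == 1, why

    def test_missing_column_is_configuration_error(self, tmp_path):
        p = tmp_path / "stems.csv"
        pd.DataFrame({"site_id": ["A"], "plot_id": ["upper"]}).to_csv(p, index=False)
        with pytest.raises(data.ConfigurationError):
            data.load_stem_table(p)

    def test_dialect_column_mapping(self, tmp_path):
        p = tmp_path / "stems.csv"
        pd.DataFrame([dict(Site="A", Plot="upper", Species="X", Layer="sapling",
                           Form="tree", DBH=2.0)]).to_csv(p, index=False)
        df, rep = data.load_stem_table(p, dialect={
            "site_id": "Site", "plot_id": "Plot", "species_code": "Species",
            "stratum": "Layer", "life_form": "Form", "diameter_cm": "DBH"})
        assert rep.n_valid == 1

    def test_generator_output_round_trips_losslessly(self, paper_like, tmp_path):
        stems, _, _ = paper_like
        p = tmp_path / "stems.csv"
        data.write_stem_table(stems, p)
        back, rep = data.load_stem_table(p)
        assert rep.n_rejected == 0
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True),
            stems[list(data.STEM_COLUMNS)].reset_index(drop=True),
            check_dtype=False)


class TestAssignClasses:
    def test_sba_membership(self, toy_sites):
        sites = toy_sites.copy()
        sites.loc["A", "sba_m2ha"] = 15.0
        scheme = data.assign_classes(sites, "sba", (0, 11, 20, 30))
        assert scheme.membership["A"] == "SBA-2"

    def test_sba_boundary_is_lower_inclusive(self, toy_sites):
        sites = toy_sites.copy()
        sites.loc["A", "sba_m2ha"] = 11.0
        scheme = data.assign_classes(sites, "sba")
        assert scheme.membership["A"] == "SBA-2"

    def test_age_class_upper_inclusive(self, toy_sites):
        sites = toy_sites.copy()
        sites.loc["A", "age_y"] = 7
        scheme = data.assign_classes(sites, "age")
        assert scheme.membership["A"] == "2-7 y"

    def test_out_of_range_names_the_site(self, toy_sites):
        sites = toy_sites.copy()
        sites.loc["B", "sba_m2ha"] = 99.0
        with pytest.raises(ValueError, match="B"):
            data.assign_classes(sites, "sba")

    def test_classes_partition_the_sites(self, paper_like):
        _, sites, _ = paper_like
        for kind in ("sba", "age"):
            scheme = data.assign_classes(sites, kind)
            assert sorted(scheme.membership) == sorted(sites.index.astype(str))
            assert set(scheme.membership.values()) <= set(scheme.labels)

    def test_generator_age_classes_balanced(self, paper_like):
        _, sites, _ = paper_like
        sizes = data.assign_classes(sites, "age").class_sizes()
        assert sizes == {"2-7 y": 15, "8-17 y": 15, "18-32 y": 15}


class TestAbundanceMatrix:
    def test_site_level_pools_the_two_plots(self, toy_stems):
        mat = data.build_abundance_matrix(toy_stems, "sapling", "site")
        assert mat.df.loc["A", "SP1"] == 5
        assert mat.df.loc["A", "SP2"] == 1

    def test_min_diameter_filter(self, toy_stems):
        mat = data.build_abundance_matrix(
            toy_stems, ("sapling", "tree"), "site", min_diameter_cm=5)
        assert mat.df.to_numpy().sum() == 1  # only the 7.1 cm tree

    def test_site_matrix_is_sum_of_plot_matrices(self, paper_like):
        stems, sites, _ = paper_like
        units = list(sites.index.astype(str))
        site_m = data.build_abundance_matrix(stems, "tree", "site", all_units=units)
        plot_m = data.build_abundance_matrix(stems, "tree", "plot")
        summed = plot_m.df.groupby(
            [u.split(":")[0] for u in plot_m.df.index]).sum()
        summed = summed.reindex(index=site_m.df.index,
                                columns=site_m.df.columns, fill_value=0)
        assert (site_m.df == summed).all().all()

    def test_row_totals_match_direct_grouping(self, paper_like):
        stems, _, _ = paper_like
        mat = data.build_abundance_matrix(stems, "sapling", "site")
        direct = stems.loc[stems.stratum == "sapling"].groupby("site_id").size()
        got = mat.df.sum(axis=1)
        assert (got == direct.reindex(got.index)).all()

    def test_filtering_idempotent(self, paper_like):
        stems, _, _ = paper_like
        once = data.build_abundance_matrix(stems, "tree", "site", min_diameter_cm=5)
        keep = stems.loc[(stems.stratum == "tree") & (stems.diameter_cm >= 5)]
        twice = data.build_abundance_matrix(keep, "tree", "site", min_diameter_cm=5)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_no_all_zero_species_columns(self, paper_like):
        stems, _, _ = paper_like
        mat = data.build_abundance_matrix(stems, "liana", "site")
        assert (mat.df.sum(axis=0) > 0).all()

    def test_empty_filter_returns_empty_matrix(self, toy_stems):
        mat = data.build_abundance_matrix(
            toy_stems, "tree", "site", min_diameter_cm=100)
        assert mat.df.size == 0

    def test_csv_round_trip_with_sidecar(self, toy_stems, tmp_path):
        mat = data.build_abundance_matrix(toy_stems, "sapling", "site")
        p = tmp_path / "m.csv"
        mat.to_csv(p)
        back = data.AbundanceMatrix.from_csv(p)
        pd.testing.assert_frame_equal(back.df, mat.df)
        assert back.stratum == ("sapling",)
        assert back.sampled_area_m2 == mat.sampled_area_m2


class TestComputeSba:
    def test_hand_computed_single_tree(self):
        stems = pd.DataFrame([dict(site_id="A", plot_id="upper", species_code="X",
                                   stratum="tree", life_form="tree",
                                   diameter_cm=20.0)])
        # one 20 cm tree in 2000 m^2: pi * 0.1^2 m^2 over 0.2 ha
        expected = np.pi * 0.1 ** 2 / 2000.0 * 1e4
        assert data.compute_sba(stems)["A"] == pytest.approx(expected)

    def test_sapling_area_scaling_doubles_contribution(self):
        base = dict(site_id="A", plot_id="upper", species_code="X",
                    life_form="tree")
        tree = pd.DataFrame([dict(base, stratum="tree", diameter_cm=5.0)])
        sap = pd.DataFrame([dict(base, stratum="sapling", diameter_cm=4.99)])
        # same basal area per stem, but saplings are censused in half the area
        ratio = data.compute_sba(sap)["A"] / data.compute_sba(tree)["A"]
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_liana_switch(self, paper_like):
        stems, _, _ = paper_like
        with_l = data.compute_sba(stems, include_lianas=True)
        without = data.compute_sba(stems, include_lianas=False)
        assert (with_l >= without - 1e-12).all()
        assert with_l.sum() > without.sum()
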