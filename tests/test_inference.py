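"""Binarization, product assignment, distributions and the Sankey graph."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_avd, random_profiles
from lipaflow.cohort import AvdVector
from lipaflow.inference import (
    acylation_distribution,
    assign_products,
    binarize_enzymes,
    build_sankey,
    final_stage_fraction,
    group_endproduct_delta,
    product_distribution,
    stage_counts,
)
from lipaflow.io import DataValidationError, EnzymeProfileSet
from lipaflow.pathway import NO_PATHWAY, PATHWAY_ENZYMES

FULL = {e: 100.0 for e in PATHWAY_ENZYMES}


def _profiles(**taxa):
    return EnzymeProfileSet({name: dict(prof) for name, prof in taxa.items()})


class TestBinarize:
    def test_threshold_is_inclusive(self):
        prof = _profiles(G1={"LpxA": 50.0}, G2={"LpxA": 49.9})
        setmap = binarize_enzymes(prof, 50)
        assert setmap["G1"] == {"LpxA"}
        assert setmap["G2"] == frozenset()

    def test_zero_availability_never_credited(self):
        setmap = binarize_enzymes(_profiles(G={"LpxA": 0.0}), 1e-9 + 1)
        assert setmap["G"] == frozenset()

    @pytest.mark.parametrize("threshold", [1.0, 50.0, 100.0])
    def test_matches_direct_comparison_grid(self, threshold):
        grid = [0.0, 25.0, 50.0, 75.0, 100.0]
        prof = _profiles(
            **{f"G{i}": {"LpxA": v, "LpxC": grid[-1 - i]} for i, v in enumerate(grid)}
        )
        setmap = binarize_enzymes(prof, threshold)
        for taxon, row in prof.profiles.items():
            expected = {e for e, v in row.items() if v >= threshold}
            assert setmap[taxon] == expected

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(DataValidationError):
            binarize_enzymes(_profiles(G={"LpxA": 10.0}), 0.0)

    def test_modifications_excluded_by_default(self):
        prof = _profiles(G={"LpxA": 100.0, "LpxE": 100.0})
        assert binarize_enzymes(prof, 50)["G"] == {"LpxA"}
        assert binarize_enzymes(prof, 50, include_modifications=True)["G"] == {
            "LpxA", "LpxE",
        }


class TestAssignProducts:
    def test_full_set_reaches_hexa_acyl_end_product(self, model):
        setmap = binarize_enzymes(_profiles(G=FULL), 50)
        asg = assign_products(setmap, model)
        assert asg["G"].token == "KDO2-lipid-A"
        state = asg.acyl_states["G"]
        assert (state.acyl_count, state.immunostimulant_class) == ("hexa", "high")

    def test_through_waaa_reaches_kdo2_lipid_iva(self, model):
        prof = _profiles(G={e: 100.0 for e in PATHWAY_ENZYMES[:7]})
        asg = assign_products(binarize_enzymes(prof, 50), model)
        assert asg["G"].token == "KDO2-lipid-IVA"

    def test_empty_profile_has_no_pathway(self, model):
        asg = assign_products(
            binarize_enzymes(_profiles(G={e: 0.0 for e in PATHWAY_ENZYMES}), 50), model
        )
        assert asg["G"].token == NO_PATHWAY
        assert "G" not in asg.acyl_states

    @pytest.mark.parametrize("thresholds", [(10.0, 50.0), (50.0, 90.0)])
    def test_lower_threshold_never_lowers_rank(self, model, thresholds):
        rng = np.random.default_rng(12)
        prof = random_profiles(rng, [f"G{i}" for i in range(100)])
        low, high = thresholds
        asg_low = assign_products(binarize_enzymes(prof, low), model)
        asg_high = assign_products(binarize_enzymes(prof, high), model)
        for taxon in prof.taxa:
            assert asg_low[taxon].rank >= asg_high[taxon].rank


class TestStageCounts:
    def test_counts_and_percentages(self, model):
        prof = _profiles(
            A=FULL, B=FULL,
            C={e: 100.0 for e in PATHWAY_ENZYMES[:6]},
            D={e: 0.0 for e in PATHWAY_ENZYMES},
        )
        asg = assign_products(binarize_enzymes(prof, 50), model)
        counts = stage_counts(asg, {"L": ["A", "B", "C", "D"]}, model)
        row = counts[(counts["list"] == "L") & (counts["product"] == "KDO2-lipid-A")]
        assert row["count"].item() == 2
        assert row["percent"].item() == pytest.approx(50.0)

    def test_empty_list_all_zero(self, model):
        asg = assign_products(binarize_enzymes(_profiles(A=FULL), 50), model)
        counts = stage_counts(asg, {"L": []}, model)
        assert (counts["count"] == 0).all()

    def test_matches_brute_force_tally(self, model):
        rng = np.random.default_rng(13)
        taxa = [f"G{i}" for i in range(30)]
        prof = random_profiles(rng, taxa)
        asg = assign_products(binarize_enzymes(prof, 50), model)
        counts = stage_counts(asg, {"L": taxa}, model)
        for product in counts["product"]:
            expected = sum(asg[t].token == product for t in taxa)
            got = counts[counts["product"] == product]["count"].item()
            assert got == expected

    def test_missing_assignment_rejected(self, model):
        asg = assign_products(binarize_enzymes(_profiles(A=FULL), 50), model)
        with pytest.raises(DataValidationError):
            stage_counts(asg, {"L": ["A", "Z"]}, model)


class TestProductDistribution:
    def test_single_taxon_all_mass(self, model):
        asg = assign_products(binarize_enzymes(_profiles(G=FULL), 50), model)
        avd = AvdVector("case", pd.Series({"G": 100.0}))
        dist = product_distribution(asg, avd, True, model)
        assert dist["KDO2-lipid-A"] == pytest.approx(100.0)

    def test_exclusion_renormalizes(self, model):
        prof = _profiles(A=FULL, B={e: 0.0 for e in PATHWAY_ENZYMES})
        asg = assign_products(binarize_enzymes(prof, 50), model)
        avd = AvdVector("case", pd.Series({"A": 30.0, "B": 30.0}))
        dist = product_distribution(asg, avd, True, model)
        assert dist["KDO2-lipid-A"] == pytest.approx(100.0)
        assert dist.included_mass == pytest.approx(50.0)

    def test_matches_brute_force_weighted_tally(self, model):
        rng = np.random.default_rng(14)
        taxa = [f"T{i:03d}" for i in range(20)]
        prof = random_profiles(rng, taxa)
        asg = assign_products(binarize_enzymes(prof, 50), model)
        avd = random_avd(rng, 20)
        dist = product_distribution(asg, avd, False, model)
        tally: dict[str, float] = {}
        for t in taxa:
            tally[asg[t].token] = tally.get(asg[t].token, 0.0) + avd[t]
        total = sum(tally.values())
        for token, mass in tally.items():
            assert dist[token] == pytest.approx(100 * mass / total, abs=1e-9)

    def test_all_mass_excluded_rejected(self, model):
        prof = _profiles(B={e: 0.0 for e in PATHWAY_ENZYMES})
        asg = assign_products(binarize_enzymes(prof, 50), model)
        avd = AvdVector("case", pd.Series({"B": 100.0}))
        with pytest.raises(DataValidationError):
            product_distribution(asg, avd, True, model)

    def test_normalization_invariant_random_fixtures(self, model):
        rng = np.random.default_rng(15)
        for _ in range(20):
            taxa = [f"T{i:03d}" for i in range(15)]
            prof = random_profiles(rng, taxa)
            asg = assign_products(binarize_enzymes(prof, 50), model)
            avd = random_avd(rng, 15)
            for excl in (True, False):
                dist = product_distribution(asg, avd, excl, model)
                assert sum(dist.percentages.values()) == pytest.approx(100.0, abs=1e-6)

    def test_exclusion_never_deflates_final_fraction(self, model):
        rng = np.random.default_rng(16)
        for _ in range(20):
            taxa = [f"T{i:03d}" for i in range(15)]
            prof = random_profiles(rng, taxa)
            asg = assign_products(binarize_enzymes(prof, 50), model)
            avd = random_avd(rng, 15)
            with_excl = final_stage_fraction(
                product_distribution(asg, avd, True, model), model
            )
            without = final_stage_fraction(
                product_distribution(asg, avd, False, model), model
            )
            assert with_excl >= without - 1e-9


class TestFinalStageAndDelta:
    def _dist(self, percentages, group="case", excl=True):
        from lipaflow.inference import ProductDistribution

        return ProductDistribution(group, percentages, 100.0, excl)

    def test_only_final_tokens_count(self, model):
        dist = self._dist({"KDO2-lipid-A": 60.0, "lipid-IVA": 40.0})
        assert final_stage_fraction(dist, model) == pytest.approx(60.0)
        assert final_stage_fraction(self._dist({"lipid-X": 100.0}), model) == 0.0

    def test_final_stage_is_additive_over_kdo2_products(self, model):
        dist = self._dist(
            {"KDO2-lipid-IVA": 30.0, "KDO2-lipid-A": 38.0, "lipid-IVA": 32.0}
        )
        assert final_stage_fraction(dist, model) == pytest.approx(68.0)

    def test_penta_token_counts_as_final_stage(self, model):
        dist = self._dist({"KDO2-lipid-A-penta": 25.0, "lipid-X": 75.0})
        assert final_stage_fraction(dist, model) == pytest.approx(25.0)

    def test_delta_is_difference_in_pp(self, model):
        case = self._dist({"KDO2-lipid-A": 68.0, "lipid-IVA": 32.0})
        control = self._dist({"KDO2-lipid-A": 62.8, "lipid-IVA": 37.2}, "control")
        assert group_endproduct_delta(case, control, model) == pytest.approx(5.2)

    def test_identical_distributions_give_zero(self, model):
        d = self._dist({"KDO2-lipid-A": 50.0, "lipid-X": 50.0})
        assert group_endproduct_delta(d, d, model) == 0.0

    def test_mismatched_exclusion_settings_rejected(self, model):
        case = self._dist({"KDO2-lipid-A": 100.0}, excl=True)
        control = self._dist({"KDO2-lipid-A": 100.0}, "control", excl=False)
        with pytest.raises(DataValidationError):
            group_endproduct_delta(case, control, model)


class TestAcylationDistribution:
    def test_full_set_unmodified_is_hexa_bis(self, model):
        prof = _profiles(S=FULL)
        setmap = binarize_enzymes(prof, 50, include_modifications=True)
        avd = AvdVector("case", pd.Series({"S": 100.0}))
        dist = acylation_distribution(setmap, avd, model)
        assert dist["hexa-acyl-bisP"] == pytest.approx(100.0)

    def test_through_lpxl_is_penta_bis(self, model):
        prof = _profiles(S={e: 100.0 for e in PATHWAY_ENZYMES[:8]})
        setmap = binarize_enzymes(prof, 50, include_modifications=True)
        avd = AvdVector("case", pd.Series({"S": 100.0}))
        dist = acylation_distribution(setmap, avd, model)
        assert dist["penta-acyl-bisP"] == pytest.approx(100.0)

    def test_phosphatase_moves_mass_to_dephosphorylated(self, model):
        prof = _profiles(S={**FULL, "LpxE": 100.0})
        setmap = binarize_enzymes(prof, 50, include_modifications=True)
        avd = AvdVector("case", pd.Series({"S": 100.0}))
        dist = acylation_distribution(setmap, avd, model)
        assert dist["dephosphorylated"] == pytest.approx(100.0)

    def test_matches_brute_force_weighted_tally(self, model):
        rng = np.random.default_rng(17)
        taxa = [f"T{i:03d}" for i in range(20)]
        prof = random_profiles(rng, taxa, include_mods=True)
        setmap = binarize_enzymes(prof, 50, include_modifications=True)
        avd = random_avd(rng, 20)
        dist = acylation_distribution(setmap, avd, model)
        from lipaflow.pathway import acyl_phospho_state, terminal_product

        tally = {cls: 0.0 for cls in dist}
        for t in taxa:
            core = {e for e in setmap[t] if e in model.enzymes}
            mods = setmap[t] - core
            stage = terminal_product(core, model)
            if stage.rank < 6:
                cls = "no-late-stage"
            else:
                st = acyl_phospho_state(core, mods, model)
                cls = (
                    "dephosphorylated"
                    if st.phosphates != "bis"
                    else f"{st.acyl_count}-acyl-bisP"
                )
            tally[cls] += avd[t]
        for cls, mass in tally.items():
            assert dist[cls] == pytest.approx(mass, abs=1e-9)
        assert sum(dist.values()) == pytest.approx(100.0, abs=1e-6)


class TestSankey:
    def test_single_taxon_single_link(self, model):
        asg = assign_products(binarize_enzymes(_profiles(Bacteroides=FULL), 50), model)
        avd = AvdVector("case", pd.Series({"Bacteroides": 44.0}))
        graph = build_sankey(asg, avd, model)
        assert len(graph.links) == 1
        link = graph.links[0]
        assert (link["source"], link["target"]) == ("KDO2-lipid-A", "Bacteroides")
        assert link["weight"] == pytest.approx(44.0)

    def test_empty_avd_gives_empty_graph(self, model):
        asg = assign_products(binarize_enzymes(_profiles(A=FULL), 50), model)
        avd = AvdVector("case", pd.Series(dtype=float))
        graph = build_sankey(asg, avd, model)
        assert graph.links == []

    def test_link_mass_equals_avd(self, model):
        rng = np.random.default_rng(18)
        taxa = [f"T{i:03d}" for i in range(25)]
        prof = random_profiles(rng, taxa)
        asg = assign_products(binarize_enzymes(prof, 50), model)
        avd = random_avd(rng, 25)
        graph = build_sankey(asg, avd, model)
        per_taxon: dict[str, float] = {}
        for link in graph.links:
            per_taxon[link["target"]] = per_taxon.get(link["target"], 0) + link["weight"]
        for t in taxa:
            assert per_taxon[t] == pytest.approx(avd[t], abs=1e-9)
        assert sum(per_taxon.values()) == pytest.approx(avd.total(), abs=1e-9)

    def test_json_export(self, model, tmp_path):
        asg = assign_products(binarize_enzymes(_profiles(A=FULL), 50), model)
        avd = AvdVector("case", pd.Series({"A": 100.0}))
        graph = build_sankey(asg, avd, model)
        graph.to_json(tmp_path / "s.json")
        import json

        doc = json.loads((tmp_path / "s.json").read_text())
        assert {n["id"] for n in doc["nodes"]} == {"KDO2-lipid-A", "A"}
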