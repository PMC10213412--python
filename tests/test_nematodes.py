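import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilfoodweb import nematodes as nem
from soilfoodweb.traits import TraitLookupError, TraitReference

from conftest import counts_frame


class TestTabulateGuilds:
    def test_single_taxon(self, simple_traits):
        counts = counts_frame({"BaOne": [50]})
        totals, functional = nem.tabulate_guilds(counts, simple_traits)
        assert totals.loc[0, "Ba"] == 50
        assert totals.loc[0, "total"] == 50
        assert functional.loc[0, "Ba1"] == 50

    def test_two_guilds(self, simple_traits):
        counts = counts_frame({"BaOne": [10], "FuTwo": [30]})
        totals, functional = nem.tabulate_guilds(counts, simple_traits)
        assert totals.loc[0, "Ba"] == 10
        assert totals.loc[0, "Fu"] == 30
        assert functional.loc[0, "Ba1"] == 10
        assert functional.loc[0, "Fu2"] == 30

    def test_totals_conserve_counts(self, dataset):
        totals, _ = nem.tabulate_guilds(
            dataset.nematode_counts, dataset.traits
        )
        guild_sum = totals[["Ba", "Fu", "Pp", "OP"]].sum(axis=1)
        assert (guild_sum == totals["total"]).all()

    def test_unknown_genus_raises(self, simple_traits):
        counts = counts_frame({"Unknownus": [5]})
        with pytest.raises(TraitLookupError, match="Unknownus"):
            nem.tabulate_guilds(counts, simple_traits)

    def test_empty_sample_allowed(self, simple_traits):
        counts = counts_frame({"BaOne": [0], "FuTwo": [0]})
        totals, _ = nem.tabulate_guilds(counts, simple_traits)
        assert totals.loc[0, "total"] == 0


class TestShannon:
    @pytest.mark.parametrize(
        "abund, expected",
        [
            ([100], 0.0),
            ([25, 25, 25, 25], math.log(4)),
            ([50, 25, 25], -(0.5 * math.log(0.5) + 0.5 * math.log(0.25))),
        ],
    )
    def test_hand_values(self, abund, expected):
        assert nem.shannon_index(abund) == pytest.approx(expected, abs=1e-12)

    def test_zero_taxa_contribute_nothing(self):
        assert nem.shannon_index([10, 0, 10]) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_all_zero_undefined(self):
        assert math.isnan(nem.shannon_index([0, 0]))


class TestMaturityIndex:
    def test_all_cp1(self, simple_traits):
        counts = counts_frame({"BaOne": [40]})
        assert nem.maturity_index(counts, simple_traits).iloc[0] == 1.0

    def test_weighted_mean(self, simple_traits):
        counts = counts_frame({"FuTwo": [50], "OmFour": [50]})
        assert nem.maturity_index(counts, simple_traits).iloc[0] == 3.0

    def test_plant_parasites_excluded(self, simple_traits):
        base = counts_frame({"FuTwo": [50], "OmFour": [50], "PpThree": [0]})
        with_pp = counts_frame(
            {"FuTwo": [50], "OmFour": [50], "PpThree": [999]}
        )
        mi0 = nem.maturity_index(base, simple_traits).iloc[0]
        mi1 = nem.maturity_index(with_pp, simple_traits).iloc[0]
        assert mi0 == mi1 == 3.0

    def test_no_free_living_undefined(self, simple_traits):
        counts = counts_frame({"PpThree": [10]})
        assert math.isnan(nem.maturity_index(counts, simple_traits).iloc[0])


class TestFaunalIndices:
    def components(self, traits, data):
        _, functional = nem.tabulate_guilds(counts_frame(data), traits)
        return nem.faunal_components(functional)

    def test_enriched_channel_example(self, simple_traits):
        comp = self.components(simple_traits, {"BaOne": [10], "FuTwo": [10]})
        assert comp.loc[0, "e"] == pytest.approx(40.0)
        assert comp.loc[0, "b"] == pytest.approx(8.0)
        idx = nem.faunal_indices(comp)
        assert idx.loc[0, "CI"] == pytest.approx(20.0)
        assert idx.loc[0, "EI"] == pytest.approx(100 * 40 / 48)
        assert idx.loc[0, "SI"] == pytest.approx(0.0)

    def test_structural_example(self, simple_traits):
        comp = self.components(simple_traits, {"BaTwo": [5], "OmFour": [5]})
        assert comp.loc[0, "e"] == 0.0
        assert comp.loc[0, "b"] == pytest.approx(4.0)
        assert comp.loc[0, "s"] == pytest.approx(16.0)
        idx = nem.faunal_indices(comp)
        assert idx.loc[0, "EI"] == pytest.approx(0.0)
        assert idx.loc[0, "SI"] == pytest.approx(80.0)

    def test_empty_channels_undefined(self, simple_traits):
        comp = self.components(simple_traits, {"PpThree": [10]})
        idx = nem.faunal_indices(comp)
        assert idx[["CI", "EI", "SI"]].isna().all().all()

    def test_ci_monotone_in_fungivores(self, simple_traits):
        ci = []
        for fu in (5, 10, 20, 40):
            comp = self.components(
                simple_traits, {"BaOne": [10], "FuTwo": [fu]}
            )
            ci.append(nem.faunal_indices(comp).loc[0, "CI"])
        assert all(a < b for a, b in zip(ci, ci[1:]))

    def test_adding_high_cp_never_decreases_si(self, simple_traits):
        lo = self.components(simple_traits, {"BaTwo": [5], "OmFour": [2]})
        hi = self.components(simple_traits, {"BaTwo": [5], "OmFour": [8]})
        si_lo = nem.faunal_indices(lo).loc[0, "SI"]
        si_hi = nem.faunal_indices(hi).loc[0, "SI"]
        assert si_hi >= si_lo


class TestFunctionalDispersion:
    def test_single_taxon_zero(self, simple_traits):
        counts = counts_frame({"BaOne": [30]})
        assert nem.functional_dispersion(counts, simple_traits).iloc[0] == 0.0

    def test_identical_traits_zero(self):
        traits = TraitReference(
            pd.DataFrame(
                {
                    "genus": ["A", "B"],
                    "guild": ["Ba", "Ba"],
                    "cp": [2, 2],
                    "body_mass": [1.0, 1.0],
                }
            )
        )
        counts = counts_frame({"A": [10], "B": [20]})
        assert nem.functional_dispersion(counts, traits).iloc[0] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_two_taxa_half_distance(self, simple_traits):
        counts = counts_frame({"BaOne": [10], "OmFour": [10]})
        d = nem.gower_distance(
            simple_traits, ["BaOne", "OmFour"]
        ).loc["BaOne", "OmFour"]
        # Gower distance must be recomputed on the 2-taxon table the
        # sample actually uses (range scaling depends on the taxa set)
        fdis = nem.functional_dispersion(
            counts[["BaOne", "OmFour"]], simple_traits
        ).iloc[0]
        assert fdis == pytest.approx(d / 2, abs=1e-12)

    def test_empty_sample_nan(self, simple_traits):
        counts = counts_frame({"BaOne": [0], "OmFour": [0]})
        assert math.isnan(
            nem.functional_dispersion(counts, simple_traits).iloc[0]
        )


class TestPredationPressureAndFootprints:
    def test_zero_bacterivores(self):
        assert nem.predation_pressure([0.0], [1e8]).iloc[0] == 0.0

    def test_direct_division_same_basis(self):
        pp = nem.predation_pressure([100.0], [1e8], counts_basis_g=1.0)
        assert pp.iloc[0] == pytest.approx(1e-6)

    def test_basis_conversion(self):
        # counts per 100 g vs copies per g: a 100x basis correction
        pp = nem.predation_pressure([100.0], [1e8])
        assert pp.iloc[0] == pytest.approx(1e-8)

    def test_zero_copies_error(self):
        with pytest.raises(ValueError):
            nem.predation_pressure([10.0], [0.0])

    def test_footprint_hand_value(self):
        traits = TraitReference(
            pd.DataFrame(
                {"genus": ["A"], "guild": ["Ba"], "cp": [2],
                 "body_mass": [1.0]}
            )
        )
        counts = counts_frame({"A": [10]})
        f = nem.metabolic_footprints(counts, traits)
        assert f.loc[0, "footprint_Ba"] == pytest.approx(
            10 * (0.1 * 1 / 2 + 0.273 * 1**0.75)
        )

    def test_footprint_linear_in_counts(self, simple_traits):
        c1 = counts_frame({"BaOne": [10], "OmFour": [4]})
        c2 = counts_frame({"BaOne": [20], "OmFour": [8]})
        f1 = nem.metabolic_footprints(c1, simple_traits)
        f2 = nem.metabolic_footprints(c2, simple_traits)
        assert np.allclose(2 * f1.to_numpy(), f2.to_numpy())

    def test_missing_mass_named(self):
        traits = TraitReference(
            pd.DataFrame({"genus": ["A"], "guild": ["Ba"], "cp": [2]})
        )
        counts = counts_frame({"A": [10]})
        with pytest.raises(ValueError, match="A"):
            nem.metabolic_footprints(counts, traits)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    counts=st.lists(st.integers(0, 60), min_size=5, max_size=5),
    k=st.floats(0.1, 50.0, allow_nan=False),
)
def test_composition_indices_scale_invariant(counts, k):
    """H, MI, CI, EI, SI, FDis depend on proportions only."""
    traits = TraitReference(
        pd.DataFrame(
            {
                "genus": ["BaOne", "BaTwo", "FuTwo", "OmFour", "PpThree"],
                "guild": ["Ba", "Ba", "Fu", "Om", "Pp"],
                "cp": [1, 2, 2, 4, 3],
                "body_mass": [0.5, 1.0, 0.4, 2.0, 0.8],
            }
        )
    )
    names = list(traits.genera)
    base = counts_frame({g: [c] for g, c in zip(names, counts)})
    scaled = base * k
    t1 = nem.compute_index_table(base, traits, footprints=False)
    t2 = nem.compute_index_table(scaled, traits, footprints=False)
    cols = ["H", "MI", "CI", "EI", "SI", "FDis"]
    a, b = t1[cols].to_numpy(), t2[cols].to_numpy()
    both = np.isfinite(a) & np.isfinite(b)
    assert (np.isfinite(a) == np.isfinite(b)).all()
    assert np.allclose(a[both], b[both], atol=1e-9)
    # bounds where defined
    for col in ("CI", "EI", "SI"):
        v = t1[col].iloc[0]
        assert math.isnan(v) or 0 <= v <= 100
    mi = t1["MI"].iloc[0]
    assert math.isnan(mi) or 1 <= mi <= 5
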