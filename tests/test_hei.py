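"""HEI-2015 component scoring and cart totals."""
import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from cfni.errors import ConfigurationError, UndefinedScoreError
from cfni.hei import (
    HEIComponentStandard,
    accumulate_constituents,
    component_score,
    load_standards,
    score_cart,
    score_totals,
)
from cfni.io import default_standards_path
from cfni.types import Cart, ConstituentTotals

from conftest import make_item


@pytest.fixture(scope="module")
def full_standards():
    return load_standards(default_standards_path())


class TestAccumulate:
    def test_energy_additivity(self):
        cart = Cart("A", (make_item("a", energy=100), make_item("b", energy=200)))
        assert accumulate_constituents(cart).energy == 300

    def test_zero_energy_is_undefined(self):
        cart = Cart("A", (make_item("a"),))
        with pytest.raises(UndefinedScoreError):
            accumulate_constituents(cart)

    def test_concatenation_equals_sum(self, rng):
        """Totals of a merged cart equal the sum of the parts' totals."""
        def random_items(prefix, n):
            return tuple(
                make_item(
                    f"{prefix}{i}",
                    totals=dict(
                        energy=rng.uniform(50, 500),
                        total_fruit=rng.uniform(0, 2),
                        sodium=rng.uniform(0, 800),
                        sfa=rng.uniform(0, 10),
                    ),
                )
                for i in range(n)
            )
        a, b = random_items("a", 4), random_items("b", 3)
        ta = accumulate_constituents(Cart("A", a))
        tb = accumulate_constituents(Cart("A", b))
        tab = accumulate_constituents(Cart("A", a + b))
        for f in ("energy", "total_fruit", "sodium", "sfa"):
            assert getattr(tab, f) == pytest.approx(getattr(ta, f) + getattr(tb, f))


class TestComponentScore:
    def test_moderation_hand_value(self, toy_standards):
        """Density 20% of energy between the 6.5/26 standards:
        10 * (26 - 20) / (26 - 6.5) = 3.0769."""
        sugar_std = toy_standards[0]
        # 50 g sugar at 4 kcal/g in 1000 kcal -> 20% of energy
        totals = ConstituentTotals(energy=1000, added_sugar=50)
        assert component_score(totals, sugar_std) == pytest.approx(10 * 6 / 19.5, abs=1e-4)
        assert component_score(totals, sugar_std) == pytest.approx(3.0769, abs=1e-4)

    def test_adequacy_hand_value(self, toy_standards):
        fruit_std = toy_standards[1]
        totals = ConstituentTotals(energy=1000, total_fruit=0.4)  # half the standard
        assert component_score(totals, fruit_std) == pytest.approx(2.5)

    def test_adequacy_endpoints(self, toy_standards):
        fruit_std = toy_standards[1]
        assert component_score(ConstituentTotals(energy=1000), fruit_std) == 0.0
        at_max = ConstituentTotals(energy=1000, total_fruit=0.8)
        assert component_score(at_max, fruit_std) == 5.0
        beyond = ConstituentTotals(energy=1000, total_fruit=5.0)
        assert component_score(beyond, fruit_std) == 5.0

    def test_moderation_endpoints(self, toy_standards):
        sugar_std = toy_standards[0]
        low = ConstituentTotals(energy=1000, added_sugar=16.25)  # exactly 6.5%
        high = ConstituentTotals(energy=1000, added_sugar=65.0)  # exactly 26%
        assert component_score(low, sugar_std) == 10.0
        assert component_score(high, sugar_std) == 0.0

    def test_fatty_acid_ratio_conventions(self):
        std = HEIComponentStandard(
            name="fatty_acids", constituent=None, max_points=10, kind="adequacy",
            basis="fatty_acid_ratio", standard_for_max=2.5, standard_for_min=1.2,
        )
        # sfa = 0 with unsaturated fat present: limit of the ratio -> full points
        assert component_score(ConstituentTotals(energy=100, mufa=1), std) == 10.0
        # no fat at all: no adequacy evidence -> zero
        assert component_score(ConstituentTotals(energy=100), std) == 0.0
        # interior: ratio 1.85 midway between 1.2 and 2.5 -> 5 points
        mid = ConstituentTotals(energy=100, mufa=1.85, sfa=1.0)
        assert component_score(mid, std) == pytest.approx(5.0)


class TestScoreCart:
    def test_toy_two_component_total(self, toy_standards):
        totals = ConstituentTotals(energy=1000, added_sugar=50, total_fruit=0.4)
        score = score_totals("A", totals, toy_standards)
        assert score.total == pytest.approx(3.0769 + 2.5, abs=1e-4)

    def test_incomplete_standards_rejected(self, toy_standards):
        cart = Cart("A", (make_item(energy=1000),))
        with pytest.raises(ConfigurationError):
            score_cart(cart, toy_standards)  # max points sum to 15, not 100

    def test_perfect_cart_scores_100(self, full_standards):
        """Meets every adequacy maximum with zero moderation intake."""
        item = make_item(
            energy=1000, total_fruit=1, whole_fruit=1, total_veg=2, greens_beans=1,
            dairy=2, whole_grain=2, total_protein=3, seafood_plant_protein=1,
            mufa=20, pufa=10, sfa=2,  # ratio 15 >= 2.5
        )
        assert score_cart(Cart("A", (item,)), full_standards).total == pytest.approx(100.0)

    def test_worst_cart_scores_0(self, full_standards):
        """No adequacy constituents, every moderation density beyond its
        minimum standard."""
        item = make_item(
            totals=dict(energy=1000, refined_grain=5, sodium=3000, added_sugar=80, sfa=20),
        )
        assert score_cart(Cart("A", (item,)), full_standards).total == pytest.approx(0.0)

    def test_default_standards_sum_to_100(self, full_standards):
        assert sum(s.max_points for s in full_standards) == 100
        assert len(full_standards) == 13

    @settings(max_examples=40, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(st.data())
    def test_bounds_and_scale_invariance(self, full_standards, data):
        """Totals in [0, 100] for arbitrary valid carts; multiplying every
        constituent (including energy) by a constant changes nothing."""
        kwargs = {
            "energy": data.draw(st.floats(10, 5000)),
            "total_fruit": data.draw(st.floats(0, 10)),
            "total_veg": data.draw(st.floats(0, 10)),
            "whole_grain": data.draw(st.floats(0, 20)),
            "refined_grain": data.draw(st.floats(0, 20)),
            "dairy": data.draw(st.floats(0, 10)),
            "mufa": data.draw(st.floats(0, 50)),
            "pufa": data.draw(st.floats(0, 50)),
            "sfa": data.draw(st.floats(0, 50)),
            "sodium": data.draw(st.floats(0, 9000)),
            "added_sugar": data.draw(st.floats(0, 200)),
        }
        cart = Cart("A", (make_item(totals=kwargs),))
        score = score_cart(cart, full_standards)
        assert 0.0 <= score.total <= 100.0
        factor = data.draw(st.floats(0.1, 25))
        scaled = Cart("A", (make_item(totals={k: v * factor for k, v in kwargs.items()}),))
        assert score_cart(scaled, full_standards).total == pytest.approx(
            score.total, abs=1e-8
        )

    @pytest.mark.parametrize(
        "field,direction",
        [("total_fruit", +1), ("whole_grain", +1), ("sodium", -1), ("added_sugar", -1)],
    )
    def test_component_monotonicity(self, full_standards, field, direction):
        """More of an adequacy constituent never lowers the total; more of a
        moderation constituent never raises it (energy held fixed)."""
        base = {"energy": 1000, "total_fruit": 0.3, "whole_grain": 0.5,
                "sodium": 1500, "added_sugar": 30}
        totals = []
        for value in np.linspace(base[field], base[field] * 4, 6):
            kwargs = dict(base, **{field: value})
            totals.append(
                score_cart(Cart("A", (make_item(totals=kwargs),)), full_standards).total
            )
        diffs = np.diff(totals) * direction
        assert np.all(diffs >= -1e-12)
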