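"""Trait-presence scoring, co-localization frequencies and chi-squared tests.

The golden test recomputes the full published co-localization table (every
trait against the Zn/Fe/Mn targets) from the packaged meta-QTL table and
checks every printed cell.
"""

from decimal import ROUND_HALF_UP, Decimal

import pytest
from scipy import stats

from ionmqtl.trait_colocalization import (
    coloc_chi2,
    coloc_frequency,
    coloc_table,
    expected_proportion,
    mqtl_summary,
    presence_matrix,
)

# printed co-localization table: trait, MQTL count, then
# (frequency, chi2, p) against each of Zn, Fe, Mn ("-" = not reported)
PRINTED_COLOC = """\
shAl 3 | 0.087 0.257 0.612 | 0.176 1.329 0.249 | 0.143 0.608 0.436
As 1 | 0.043 0.129 0.720 | 0.059 0.443 0.506 | 0.000 - -
B 10 | 0.304 0.900 0.343 | 0.353 2.658 0.103 | 0.333 1.418 0.234
Ca 20 | 0.652 1.929 0.165 | 0.588 4.431 0.035 | 0.619 2.633 0.105
rsCa 4 | 0.130 0.386 0.535 | 0.176 1.329 0.249 | 0.143 0.608 0.436
shCa 5 | 0.174 0.514 0.473 | 0.235 1.772 0.183 | 0.190 0.810 0.368
Cd 4 | 0.087 0.257 0.612 | 0.059 0.443 0.506 | 0.143 0.608 0.436
Co 7 | 0.217 0.643 0.423 | 0.235 1.772 0.183 | 0.190 0.810 0.368
Cu 15 | 0.522 1.543 0.214 | 0.353 2.658 0.103 | 0.476 2.025 0.155
shCu 3 | 0.130 0.386 0.535 | 0.118 0.886 0.347 | 0.095 0.405 0.525
Fe 17 | 0.435 1.286 0.257 | - - - | 0.571 2.430 0.119
roFe 1 | 0.043 0.129 0.720 | 0.000 - - | 0.048 0.203 0.653
rsFe 5 | 0.174 0.514 0.473 | 0.176 1.329 0.249 | 0.143 0.608 0.436
shFe 3 | 0.130 0.386 0.535 | 0.118 0.886 0.347 | 0.143 0.608 0.436
K 26 | 0.783 2.314 0.128 | 0.882 6.646 0.010 | 0.762 3.240 0.072
rsK 4 | 0.130 0.386 0.535 | 0.118 0.886 0.347 | 0.095 0.405 0.525
shK 2 | 0.043 0.129 0.720 | 0.118 0.886 0.347 | 0.095 0.405 0.525
Li 5 | 0.174 0.514 0.473 | 0.059 0.443 0.506 | 0.143 0.608 0.436
Mg 20 | 0.609 1.800 0.180 | 0.647 4.874 0.027 | 0.667 2.835 0.092
rsMg 6 | 0.261 0.771 0.380 | 0.118 0.886 0.347 | 0.238 1.013 0.314
shMg 4 | 0.174 0.514 0.473 | 0.176 1.329 0.249 | 0.095 0.405 0.525
Mn 21 | 0.652 1.929 0.165 | 0.706 5.317 0.021 | - - -
rsMn 8 | 0.217 0.643 0.423 | 0.294 2.215 0.137 | 0.286 1.215 0.270
shMn 2 | 0.043 0.129 0.720 | 0.059 0.443 0.506 | 0.095 0.405 0.525
Mo 4 | 0.174 0.514 0.473 | 0.059 0.443 0.506 | 0.143 0.608 0.436
Na 12 | 0.348 1.029 0.310 | 0.353 2.658 0.103 | 0.476 2.025 0.155
Ni 2 | 0.043 0.129 0.720 | 0.059 0.443 0.506 | 0.000 - -
P 22 | 0.783 2.314 0.128 | 0.706 5.317 0.021 | 0.762 3.240 0.072
rsP 7 | 0.217 0.643 0.423 | 0.235 1.772 0.183 | 0.238 1.013 0.314
shP 6 | 0.217 0.643 0.423 | 0.176 1.329 0.249 | 0.238 1.013 0.314
Rb 6 | 0.174 0.514 0.473 | 0.235 1.772 0.183 | 0.048 0.203 0.653
S 15 | 0.478 1.414 0.234 | 0.588 4.431 0.035 | 0.476 2.025 0.155
shS 4 | 0.130 0.386 0.535 | 0.118 0.886 0.347 | 0.095 0.405 0.525
Se 8 | 0.304 0.900 0.343 | 0.235 1.772 0.183 | 0.190 0.810 0.368
Zn 23 | - - - | 0.588 4.431 0.035 | 0.714 3.038 0.081
roZn 1 | 0.043 0.129 0.720 | 0.059 0.443 0.506 | 0.000 - -
rsZn 9 | 0.304 0.900 0.343 | 0.353 2.658 0.103 | 0.381 1.620 0.203
shZn 2 | 0.087 0.257 0.612 | 0.118 0.886 0.347 | 0.095 0.405 0.525
"""


def round3(x: float) -> float:
    # pre-round to absorb float representation noise (e.g. 0.60749999...)
    return float(Decimal(repr(round(x, 9))).quantize(Decimal("1.000"), rounding=ROUND_HALF_UP))


class TestPresenceMatrix:
    def test_published_per_trait_counts(self, table3_matrix):
        sums = table3_matrix.sum()
        assert sums["K"] == 26
        assert sums["Zn"] == 23
        assert sums["P"] == 22
        assert sums["Mn"] == 21
        assert sums["Mg"] == 20
        assert sums["Ca"] == 20
        assert sums["Fe"] == 17

    def test_every_mqtl_has_a_trait(self, table3_matrix):
        assert (table3_matrix.sum(axis=1) >= 1).all()

    def test_prefixed_variants_scored_separately(self, table3_matrix):
        # rosette-Zn occurs in 9 regions, independent of the 23 for seed Zn
        assert table3_matrix["rsZn"].sum() == 9


class TestExpectedProportion:
    @pytest.mark.parametrize("target,value,rounded", [
        ("Zn", 23 / 33, 0.70),
        ("Fe", 17 / 33, 0.52),
        ("Mn", 21 / 33, 0.64),
    ])
    def test_published_targets(self, table3_matrix, target, value, rounded):
        ep = expected_proportion(table3_matrix, target)
        assert ep.value == pytest.approx(value)
        assert ep.value_rounded == rounded

    def test_all_present_column_is_one(self, table3_matrix):
        m = table3_matrix.copy()
        m["Zn"] = 1
        assert expected_proportion(m, "Zn").value == 1.0

    def test_unknown_target_rejected(self, table3_matrix):
        with pytest.raises(KeyError):
            expected_proportion(table3_matrix, "Xx")


class TestColocFrequency:
    def test_fe_with_zn(self, table3_matrix):
        assert coloc_frequency(table3_matrix, "Fe", "Zn") == pytest.approx(10 / 23, abs=5e-4)

    def test_mn_with_fe(self, table3_matrix):
        assert coloc_frequency(table3_matrix, "Mn", "Fe") == pytest.approx(12 / 17, abs=5e-4)

    def test_trait_with_itself_is_one(self, table3_matrix):
        assert coloc_frequency(table3_matrix, "Zn", "Zn") == 1.0

    def test_cooccurrence_counts_symmetric(self, table3_matrix):
        for a in ("Zn", "Fe", "Mn", "K", "Ca"):
            for b in ("Zn", "Fe", "Mn"):
                n_ab = int((table3_matrix[a] & table3_matrix[b]).sum())
                n_ba = int((table3_matrix[b] & table3_matrix[a]).sum())
                assert n_ab == n_ba


class TestColocChi2:
    def test_k_with_fe_worked_example(self):
        chi2, p = coloc_chi2(15, 0.52)
        assert chi2 == pytest.approx(6.646, abs=5e-4)
        assert p == pytest.approx(0.010, abs=1e-3)

    def test_zero_cooccurrence(self):
        assert coloc_chi2(0, 0.64) == (0.0, 1.0)

    def test_k_with_zn_from_recomputed_table(self, table3_matrix):
        n_co = int((table3_matrix["K"] & table3_matrix["Zn"]).sum())
        assert n_co == 18
        chi2, _ = coloc_chi2(n_co, 0.70)
        assert chi2 == pytest.approx(2.314, abs=5e-4)

    def test_monotone_in_n_co(self):
        values = [coloc_chi2(n, 0.52)[0] for n in range(6)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_invalid_proportion_rejected(self):
        with pytest.raises(ValueError):
            coloc_chi2(3, 0.0)
        with pytest.raises(ValueError):
            coloc_chi2(3, 1.0)

    def test_chi2_tail_probability_sanity(self):
        assert stats.chi2.sf(3.841, df=1) == pytest.approx(0.050, abs=1e-3)


class TestFullTableGolden:
    def test_every_printed_cell_reproduced(self, table3_matrix):
        results = {(r.trait, r.target): r for r in coloc_table(table3_matrix)}
        for line in PRINTED_COLOC.strip().split("\n"):
            trait, n, rest = line.split(" ", 2)
            cells = [c.strip().split() for c in rest.lstrip("| ").split("|")]
            assert int(table3_matrix[trait].sum()) == int(n), trait
            for target, (f, chi, p) in zip(("Zn", "Fe", "Mn"), cells):
                r = results[(trait, target)]
                if trait == target:
                    assert r.frequency is None and r.chi2 is None
                    continue
                assert round3(r.frequency) == float(f), (trait, target)
                if chi == "-":
                    assert r.chi2 is None, (trait, target)
                    continue
                assert round3(r.chi2) == float(chi), (trait, target)
                assert r.p == pytest.approx(float(p), abs=1.5e-3), (trait, target)

    def test_significance_flags(self, table3_matrix):
        results = {(r.trait, r.target): r for r in coloc_table(table3_matrix)}
        significant = {(t, g) for (t, g), r in results.items() if r.significant}
        assert significant == {("Ca", "Fe"), ("K", "Fe"), ("Mg", "Fe"),
                               ("Mn", "Fe"), ("P", "Fe"), ("S", "Fe"), ("Zn", "Fe")}


class TestMQTLSummary:
    def test_published_headline_statistics(self, table3):
        summ = mqtl_summary(table3, mean_original_ci=10.88)
        assert round(summ["mean_ci_cm"], 2) == 1.30
        assert summ["n_ci_lt_1cm"] == 12
        assert summ["pct_ci_lt_1cm"] == 36.4
        assert summ["n_ge6_populations"] == 22
        assert summ["fold_reduction"] == pytest.approx(10.88 / summ["mean_ci_cm"])
        assert summ["per_chromosome"] == {"1": 8, "2": 5, "3": 6, "4": 5, "5": 9}

    def test_computed_percentage_for_population_support(self, table3):
        # 22/33 is 66.7%; the computed value is reported
        summ = mqtl_summary(table3)
        assert summ["pct_ge6_populations"] == 66.7

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            mqtl_summary([])
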