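"""Total-protein-mass estimation and housekeeping normalization."""

import numpy as np
import pandas as pd
import pytest

from amcpipe.concentration import (
    ATLAS_COLUMNS,
    EstimationParams,
    QuantInput,
    ReferenceFilters,
    compute_reference_median,
    convert_reported_units,
    estimate_study,
    normalize_to_reference,
)


def qi(gene, signal, det=1.0, mw=50_000.0):
    return QuantInput(canonical_gene=gene, signal=signal, detectability=det, mol_weight=mw)


def make_atlas(rows):
    """rows: (gene, conc, study, species, condition, age)."""
    return pd.DataFrame(
        [
            dict(zip(ATLAS_COLUMNS,
                     [g, c, False, "LFQ", s, sp, "cortex", "neuron", "cell", cond, age]))
            for g, c, s, sp, cond, age in rows
        ]
    )


class TestEstimateStudy:
    def test_single_protein_closed_form(self):
        # one protein owns the whole 200 g/L: conc = 200/MW mol/L = 4000 uM
        for signal in (1.0, 7.3, 1e9):
            res = estimate_study([qi("G", signal, mw=50_000)])
            assert res.concentrations_uM[0] == pytest.approx(4000.0, rel=1e-12)

    def test_total_volume_is_algebraic_identity(self):
        rng = np.random.default_rng(0)
        inputs = [qi(f"G{i}", rng.lognormal(0, 2), det=1 + i % 7, mw=rng.uniform(1e4, 2e5))
                  for i in range(50)]
        res = estimate_study(inputs)
        assert res.total_volume_L == pytest.approx(1.0e-12, rel=1e-12)

    def test_mass_conservation(self):
        rng = np.random.default_rng(1)
        inputs = [qi(f"G{i}", rng.lognormal(0, 2), det=1 + i % 5, mw=rng.uniform(1e4, 2e5))
                  for i in range(100)]
        res = estimate_study(inputs)
        mw = np.array([q.mol_weight for q in inputs])
        total = np.sum(res.concentrations_uM * 1e-6 * mw)
        assert total == pytest.approx(200.0, rel=1e-9)

    def test_global_scale_invariance(self):
        inputs = [qi("A", 3.0, 2, 40_000), qi("B", 5.0, 1, 90_000)]
        scaled = [qi("A", 30.0, 2, 40_000), qi("B", 50.0, 1, 90_000)]
        r1, r2 = estimate_study(inputs), estimate_study(scaled)
        np.testing.assert_allclose(r1.concentrations_uM, r2.concentrations_uM, rtol=1e-12)
        np.testing.assert_allclose(r1.copy_numbers, r2.copy_numbers, rtol=1e-12)

    def test_equal_proteins_split_evenly(self):
        res = estimate_study([qi("A", 4.0, 2, 80_000), qi("B", 2.0, 1, 80_000)])
        expected_each = (200.0 / 80_000) / 2 * 1e6  # uM
        np.testing.assert_allclose(res.concentrations_uM, expected_each, rtol=1e-12)

    def test_zero_signals_dropped_and_degenerate_rejected(self):
        res = estimate_study([qi("A", 1.0), qi("B", 0.0)])
        assert res.genes == ["A"] and res.n_dropped == 1
        with pytest.raises(ValueError, match="degenerate"):
            estimate_study([qi("A", 0.0), qi("B", 0.0)])

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            EstimationParams(total_cell_prot_conc=-1)


class TestConvertReportedUnits:
    @pytest.mark.parametrize(
        "value, unit, expected",
        [
            (2.0, "nM", 0.002),
            (1e-8, "mol_per_g_protein", 2.0),
            (0.0, "mM", 0.0),
            (3.0, "mM", 3000.0),
            (1.5, "uM", 1.5),
            (2e-6, "M", 2.0),
        ],
    )
    def test_conversions(self, value, unit, expected):
        assert convert_reported_units(value, unit) == pytest.approx(expected, rel=1e-12)

    def test_unknown_unit_named(self):
        with pytest.raises(ValueError, match="parsec"):
            convert_reported_units(1.0, "parsec")


class TestReferenceMedian:
    def test_odd_and_even_count_medians(self):
        atlas = make_atlas([("HK1", 1.0, "s1", "mouse", "healthy", "young"),
                            ("HK2", 2.0, "s1", "mouse", "healthy", "young"),
                            ("HK3", 3.0, "s1", "mouse", "healthy", "young")])
        assert compute_reference_median(atlas, {"HK1", "HK2", "HK3"}) == 2.0
        atlas2 = make_atlas([("HK1", 1.0, "s1", "mouse", "healthy", "young"),
                             ("HK2", 100.0, "s1", "mouse", "healthy", "young")])
        assert compute_reference_median(atlas2, {"HK1", "HK2"}) == 50.5

    def test_filters_exclude_non_reference_entries(self):
        atlas = make_atlas([
            ("HK1", 1.0, "s1", "mouse", "healthy", "young"),
            ("HK1", 99.0, "s2", "human", "healthy", "young"),   # wrong species
            ("HK1", 99.0, "s3", "mouse", "AD", "young"),        # diseased
            ("HK1", 99.0, "s4", "mouse", "healthy", "old"),     # wrong age class
            ("G2", 99.0, "s1", "mouse", "healthy", "young"),    # not housekeeping
        ])
        assert compute_reference_median(atlas, {"HK1"}) == 1.0

    def test_organelle_only_study_excluded_from_pool(self):
        atlas = make_atlas([("HK1", 1.0, "s1", "mouse", "healthy", "young"),
                            ("HK1", 1000.0, "mito", "mouse", "healthy", "young")])
        filters = ReferenceFilters(organelle_only_studies=("mito",))
        assert compute_reference_median(atlas, {"HK1"}, filters) == 1.0

    def test_empty_pool_raises(self):
        atlas = make_atlas([("G1", 1.0, "s1", "rat", "healthy", "young")])
        with pytest.raises(ValueError, match="no reference entries"):
            compute_reference_median(atlas, {"HK1"})


class TestNormalizeToReference:
    def test_unit_scale_when_medians_match(self):
        atlas = make_atlas([("HK1", 2.0, "s1", "mouse", "healthy", "young"),
                            ("G1", 8.0, "s1", "mouse", "healthy", "young")])
        out = normalize_to_reference(atlas, {"HK1"}, reference_median=2.0)
        assert list(out["concentration_uM"]) == [2.0, 8.0]
        assert out["normalized"].all()

    def test_double_housekeeping_median_halves_everything(self):
        atlas = make_atlas([("HK1", 4.0, "s1", "mouse", "healthy", "young"),
                            ("G1", 8.0, "s1", "mouse", "healthy", "young")])
        out = normalize_to_reference(atlas, {"HK1"}, reference_median=2.0)
        assert list(out["concentration_uM"]) == [2.0, 4.0]

    def test_idempotent(self):
        atlas = make_atlas([("HK1", 4.0, "s1", "mouse", "healthy", "young"),
                            ("G1", 8.0, "s1", "mouse", "healthy", "young"),
                            ("HK1", 1.0, "s2", "mouse", "healthy", "young"),
                            ("G2", 5.0, "s2", "mouse", "healthy", "young")])
        once = normalize_to_reference(atlas, {"HK1"}, 2.0)
        twice = normalize_to_reference(once, {"HK1"}, 2.0)
        pd.testing.assert_frame_equal(once, twice)

    def test_equalizes_housekeeping_medians_exactly(self):
        rng = np.random.default_rng(5)
        rows = []
        for s, batch in (("s1", 0.2), ("s2", 5.0)):
            for i in range(20):
                gene = f"HK{i}" if i < 10 else f"G{i}"
                rows.append((gene, batch * rng.lognormal(0, 1), s, "mouse", "healthy", "young"))
        atlas = make_atlas(rows)
        hk = {f"HK{i}" for i in range(10)}
        out = normalize_to_reference(atlas, hk, 3.7)
        for _, sub in out.groupby("study_id"):
            med = sub.loc[sub["canonical_gene"].isin(hk), "concentration_uM"].median()
            assert med == pytest.approx(3.7, rel=1e-12)

    def test_missing_housekeeping_names_study(self):
        atlas = make_atlas([("G1", 8.0, "sX", "mouse", "healthy", "young")])
        with pytest.raises(ValueError, match="sX"):
            normalize_to_reference(atlas, {"HK1"}, 2.0)
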