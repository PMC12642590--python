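"""Energy squashing, term selection, PCA compression, and variant encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import biovep as bv
from biovep.features import (
    DIM_WITH_BIOPHYSICS,
    DIM_WITHOUT_BIOPHYSICS,
    N_AAINDEX_PCS,
    ONEHOT_DIM,
    explained_variance_components,
)


class TestSquash:
    def test_identity_below_threshold(self):
        assert bv.squash_energy(10.0) == 10.0
        assert bv.squash_energy(-300.0) == -300.0

    def test_continuous_at_threshold(self):
        assert bv.squash_energy(50.0) == 50.0

    def test_closed_form_above_threshold(self):
        assert bv.squash_energy(100.0) == pytest.approx(50 + 50 * np.tanh(1.0))
        assert bv.squash_energy(100.0) == pytest.approx(88.079, abs=1e-3)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            bv.squash_energy(np.inf)

    @given(st.lists(st.floats(-500, 500), min_size=2, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, values):
        out = bv.squash_energy(np.sort(np.asarray(values)))
        assert np.all(np.diff(out) >= -1e-12)
        assert np.all(out < 100.0)


class TestTermSelection:
    @staticmethod
    def _table(term_scales):
        rng = np.random.default_rng(3)
        names = [f"t{i:02d}" for i in range(len(term_scales))]
        terms = rng.normal(size=(6, 20, len(names))) * np.asarray(term_scales)
        return bv.EnergyTable(names, terms.sum(axis=2), terms)

    def test_top_k_in_variance_order(self):
        scales = np.arange(10, 0, -1, dtype=float)  # t00 largest ... t09 smallest
        table = self._table(scales)
        got = bv.select_energy_terms(table, k=4)
        # brute-force oracle: rank by empirical variance
        var = table.terms.reshape(-1, 10).var(axis=0)
        expected = [table.term_names[i] for i in np.argsort(var)[::-1][:4]]
        assert got == expected

    def test_zero_variance_terms_excluded(self):
        table = self._table([1.0] * 8 + [0.0, 0.0])
        got = bv.select_energy_terms(table, k=8)
        assert set(got) == {f"t{i:02d}" for i in range(8)}

    def test_k_zero_and_k_too_large(self):
        table = self._table([1.0] * 5)
        assert bv.select_energy_terms(table, k=0) == []
        with pytest.raises(ValueError):
            bv.select_energy_terms(table, k=6)


class TestMinMax:
    def test_midpoint(self):
        nm = bv.MinMaxNormalizer.fit([2.0, 4.0, 6.0])
        assert nm.apply(4.0) == 0.5

    def test_clipping_outside_training_range(self):
        nm = bv.MinMaxNormalizer.fit([2.0, 6.0])
        assert nm.apply(8.0) == 1.0
        assert nm.apply(0.0) == 0.0

    def test_training_set_maps_to_unit_interval(self, rng):
        values = rng.normal(size=200)
        out = bv.MinMaxNormalizer.fit(values).apply(values)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="exclude"):
            bv.MinMaxNormalizer.fit([3.0, 3.0, 3.0])


class TestAAIndexPCA:
    def test_full_rank_matrix_gives_19_components(self, rng):
        X = rng.normal(size=(20, 566))
        assert explained_variance_components(X) == 19
        pcs = bv.compute_aaindex_pcs(X)
        assert pcs.components.shape == (20, 19)
        # each component min-max normalized to span [0, 1] exactly
        np.testing.assert_allclose(pcs.components.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(pcs.components.max(axis=0), 1.0, atol=1e-12)

    def test_identical_rows_rejected(self):
        X = np.ones((20, 30))
        with pytest.raises(ValueError, match="0 components"):
            bv.compute_aaindex_pcs(X)

    def test_two_factor_structure_detected(self, rng):
        latent = rng.normal(size=(20, 2))
        loadings = rng.normal(size=(2, 25))
        X = latent @ loadings + 1e-4 * rng.normal(size=(20, 25))
        from sklearn.decomposition import PCA

        ratios = PCA(svd_solver="full").fit(X).explained_variance_ratio_
        assert ratios[:2].sum() > 0.99


class TestEncoding:
    def test_dimensions(self, world, resources):
        wt = bv.Variant()
        assert bv.encode_variant(wt, resources, True).shape == (30, DIM_WITH_BIOPHYSICS)
        assert bv.encode_variant(wt, resources, False).shape == (30, DIM_WITHOUT_BIOPHYSICS)
        assert DIM_WITH_BIOPHYSICS == 49 and DIM_WITHOUT_BIOPHYSICS == 40

    def test_onehot_rows_sum_to_one(self, dms, resources):
        X = bv.encode_variant(dms.variants[3], resources, True)
        onehot = X[:, :ONEHOT_DIM]
        np.testing.assert_array_equal(onehot.sum(axis=1), 1.0)
        assert np.all((onehot == 0) | (onehot == 1))

    def test_feature_blocks_in_unit_interval(self, dms, resources):
        X = bv.encode_variant(dms.variants[5], resources, True)
        assert X[:, ONEHOT_DIM:].min() >= 0.0
        assert X[:, ONEHOT_DIM:].max() <= 1.0

    def test_mutations_are_local(self, world, resources):
        ref = world.reference
        v = bv.parse_variant(f"{ref[2]}3{'K' if ref[2] != 'K' else 'R'}", ref)
        wt_enc = bv.encode_variant(bv.Variant(), resources, True)
        mut_enc = bv.encode_variant(v, resources, True)
        changed = np.nonzero(np.any(wt_enc != mut_enc, axis=1))[0]
        np.testing.assert_array_equal(changed, [2])

    def test_encoding_invariant_to_mutation_order(self, world, resources):
        ref = world.reference
        m1 = bv.Mutation(3, ref[2], "K" if ref[2] != "K" else "R")
        m2 = bv.Mutation(10, ref[9], "P" if ref[9] != "P" else "G")
        a = bv.encode_variant(bv.Variant((m1, m2)), resources, True)
        b = bv.encode_variant(bv.Variant((m2, m1)), resources, True)
        np.testing.assert_array_equal(a, b)

    def test_biophysics_off_ignores_energy_resources(self, dms, resources, resources_plain):
        v = dms.variants[7]
        a = bv.encode_variant(v, resources, False)
        b = bv.encode_variant(v, resources_plain, False)
        np.testing.assert_array_equal(a, b)

    def test_stop_rows_use_energy_ceiling(self, world, resources):
        ref = world.reference
        v = bv.Variant((bv.Mutation(5, ref[4], "*"),))
        X = bv.encode_variant(v, resources, True)
        e0 = ONEHOT_DIM + N_AAINDEX_PCS
        np.testing.assert_array_equal(X[4, e0:-1], 1.0)

    def test_plain_resources_reject_biophysics_encoding(self, dms, resources_plain):
        with pytest.raises(ValueError):
            bv.encode_variant(dms.variants[0], resources_plain, True)


class TestEnergyTableIO:
    def test_roundtrip_with_protocol(self, world, tmp_path):
        path = tmp_path / "energy.tsv"
        bv.write_energy_table(world.energy_table, path, world.reference)
        back = bv.read_energy_table(path)
        assert back.term_names == world.energy_table.term_names
        assert back.protocol == {"repack_radius": 12, "nloop": 1}
        np.testing.assert_allclose(back.totals, world.energy_table.totals)
        np.testing.assert_allclose(back.terms, world.energy_table.terms)

    def test_missing_entries_rejected(self, world, tmp_path):
        path = tmp_path / "energy.tsv"
        bv.write_energy_table(world.energy_table, path, world.reference)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # drop one entry
        with pytest.raises(ValueError, match="missing"):
            bv.read_energy_table(path)
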