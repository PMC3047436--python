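"""Rate laws, stoichiometry and the linear-in-parameters decomposition.

The reference oracle below is an independent, literal transcription of the 25
flux expressions and 9 balance equations of the C16 model, kept deliberately
separate from the package's vectorised kernels.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sphingokin as sk
from sphingokin.network import InputVector, Reaction


def oracle_rhs(x, lip, gene, k):
    """Hand-coded fluxes and balances (x: 9 states, lip: 4, gene: 9, k: dict)."""
    DHCer, DHSph1P, DHGlcCer, DHSM, DHCerP, Cer, CerP, SM, GlcCer = x
    DHSph, CoA16, DG, GPCho = lip
    CerS6, Sphk1, Sphk2, Ugcg, Sms1, Sms2, Smpd1, Cerk, Degs1 = gene
    v = np.empty(25)
    v[0] = k["kf1"] * DHSph * CoA16 * CerS6
    v[1] = k["kf2"] * DHSph * CoA16
    v[2] = k["kf3"] * DHCer
    v[3] = k["kf4"] * DHSph * Sphk1
    v[4] = k["kf5"] * DHSph * Sphk2
    v[5] = k["kf6"] * DHSph1P
    v[6] = k["kf7"] * DHCer * Ugcg
    v[7] = k["kf8"] * DHGlcCer
    v[8] = k["kf9"] * DHCer * Sms1 * GPCho - k["kb9"] * DHSM * Sms1 * DG
    v[9] = k["kf10"] * DHCer * Sms2 * GPCho - k["kb10"] * DHSM * Sms2 * DG
    v[10] = k["kf11"] * DHSM * Smpd1
    v[11] = k["kf12"] * DHSM
    v[12] = k["kf13"] * DHCer * Cerk
    v[13] = k["kf14"] * DHCerP
    v[14] = k["kf15"] * DHCer * Degs1
    v[15] = k["kf16"] * DHCer
    v[16] = k["kf17"] * Cer * Cerk
    v[17] = k["kf18"] * CerP
    v[18] = k["kf19"] * Cer * Sms1 * GPCho - k["kb19"] * SM * Sms1 * DG
    v[19] = k["kf20"] * Cer * Sms2 * GPCho - k["kb20"] * SM * Sms2 * DG
    v[20] = k["kf21"] * SM * Smpd1
    v[21] = k["kf22"] * SM
    v[22] = k["kf23"] * Cer
    v[23] = k["kf24"] * Cer * Ugcg
    v[24] = k["kf25"] * GlcCer
    dx = np.array([
        v[0] + v[1] - v[2] - v[6] - v[8] - v[9] + v[10] - v[12] - v[14] - v[15],
        v[3] + v[4] - v[5],
        v[6] - v[7],
        v[8] + v[9] - v[10] - v[11],
        v[12] - v[13],
        v[14] + v[15] - v[16] - v[18] - v[19] + v[20] - v[22] - v[23],
        v[16] - v[17],
        v[18] + v[19] - v[20] - v[21],
        v[23] - v[24],
    ])
    return v, dx


def random_point(rng, scale=5.0):
    x = scale * rng.random(9)
    lip = scale * rng.random(4)
    gene = 0.5 + 2.0 * rng.random(9)
    return x, lip, gene


class TestFluxAndRhs:
    def test_single_flux_value(self, network, ref_params):
        """v6 = kf6 [DHSph1P]: the reference kf6 = 0.528 at unit substrate."""
        x = np.zeros(9)
        x[1] = 1.0  # DHSph1P
        inp = InputVector(np.zeros(4), np.zeros(9))
        v = network.flux_vector(x, inp, ref_params)
        assert v[5] == pytest.approx(0.528)

    def test_zero_state_zero_fluxes(self, network, ref_params):
        v = network.flux_vector(np.zeros(9), InputVector(np.zeros(4), np.zeros(9)), ref_params)
        assert np.all(v == 0)

    def test_detailed_balance_symmetric_point(self, network, ref_params):
        """kf9 = kb9 at the all-ones point makes the reversible flux vanish."""
        p = ref_params.replace(kb9=ref_params["kf9"])
        v = network.flux_vector(np.ones(9), InputVector(np.ones(4), np.ones(9)), p)
        assert v[8] == pytest.approx(0.0, abs=1e-15)

    def test_single_term_rhs(self, network):
        """Only kf4: d[DHSph1P]/dt = kf4 [DHSph][Sphk1] = 1 * 2 * 1.5."""
        p = network.make_params(dict.fromkeys(network.param_names, 0.0) | {"kf4": 1.0})
        gene = np.ones(9)
        gene[1] = 1.5  # Sphk1
        lip = np.zeros(4)
        lip[0] = 2.0  # DHSph
        dx = network.rhs(np.ones(9), InputVector(lip, gene), p)
        assert dx[1] == pytest.approx(3.0)
        assert np.all(dx[np.arange(9) != 1] == 0)

    def test_rhs_matches_transcribed_oracle(self, network, ref_params, rng):
        for _ in range(100):
            x, lip, gene = random_point(rng)
            v_pkg = network.flux_vector(x, InputVector(lip, gene), ref_params)
            dx_pkg = network.rhs(x, InputVector(lip, gene), ref_params)
            v_ora, dx_ora = oracle_rhs(x, lip, gene, ref_params.to_dict())
            np.testing.assert_allclose(v_pkg, v_ora, rtol=1e-13)
            # balances sum ~10 fluxes; allow a few ulps of cancellation noise
            np.testing.assert_allclose(dx_pkg, dx_ora, rtol=1e-12,
                                       atol=1e-13 * np.abs(v_ora).max())

    def test_irreversible_fluxes_nonnegative(self, network, rng):
        for _ in range(50):
            x, lip, gene = random_point(rng)
            p = network.make_params(rng.random(29))
            v = network.flux_vector(x, InputVector(lip, gene), p)
            assert np.all(v[network.irreversible_mask] >= 0)

    @given(c=st.floats(0.0, 10.0), seed=st.integers(0, 10_000))
    def test_linearity_in_parameters(self, network, c, seed):
        rng = np.random.default_rng(seed)
        x, lip, gene = random_point(rng)
        inp = InputVector(lip, gene)
        b1 = network.make_params(rng.random(29))
        b2 = network.make_params(rng.random(29))
        r1 = network.rhs(x, inp, b1)
        r2 = network.rhs(x, inp, b2)
        rs = network.rhs(x, inp, network.make_params(b1.values + c * b2.values))
        np.testing.assert_allclose(rs, r1 + c * r2, rtol=1e-11, atol=1e-12)


class TestStoichiometry:
    def test_degradation_column(self, network):
        S = network.stoichiometry_matrix()
        col = S[:, 5]  # reaction 6: DHSph1P ->
        assert col[1] == -1 and np.count_nonzero(col) == 1

    def test_desaturation_column(self, network):
        """Reaction 16 converts C16 DHCer (row 0) into C16 Cer (row 5)."""
        col = network.stoichiometry_matrix()[:, 15]
        assert col[0] == -1 and col[5] == 1 and np.count_nonzero(col) == 2

    def test_S_times_flux_equals_rhs(self, network, ref_params, rng):
        S = network.stoichiometry_matrix()
        for _ in range(100):
            x, lip, gene = random_point(rng)
            inp = InputVector(lip, gene)
            v = network.flux_vector(x, inp, ref_params)
            np.testing.assert_array_equal(S @ v, network.rhs(x, inp, ref_params))


class TestBasisDecomposition:
    def test_single_factor_entry(self, network):
        x = np.zeros(9)
        x[1] = 2.0  # DHSph1P
        basis = network.basis_fluxes(x, InputVector(np.zeros(4), np.zeros(9)))
        # kf6's regressor is the substrate concentration itself
        assert basis[list(network.param_names).index("kf6")] == pytest.approx(2.0)

    def test_zero_state_zero_basis(self, network):
        basis = network.basis_fluxes(np.zeros(9), InputVector(np.zeros(4), np.zeros(9)))
        assert np.all(basis == 0)

    def test_design_block_linearity(self, network, rng):
        """design_block @ b reproduces rhs for arbitrary parameter vectors."""
        for _ in range(50):
            x, lip, gene = random_point(rng)
            inp = InputVector(lip, gene)
            b = rng.random(29)
            D = network.design_block(x, inp)
            np.testing.assert_allclose(
                D @ b, network.rhs(x, inp, network.make_params(b)), rtol=1e-12, atol=1e-14
            )


class TestGeneKnockout:
    def test_zero_fold_silences_exactly_its_reactions(self, network, ref_params, rng):
        """Setting one gene fold to 0 zeroes exactly the fluxes carrying it."""
        x, lip, _ = random_point(rng)
        gene_list = network.catalog.gene_inputs
        for gi, gname in enumerate(gene_list):
            gene = 0.5 + rng.random(9)
            ref = network.flux_vector(x, InputVector(lip, gene), ref_params)
            gene0 = gene.copy()
            gene0[gi] = 0.0
            v = network.flux_vector(x, InputVector(lip, gene0), ref_params)
            for j, rxn in enumerate(network.reactions):
                if rxn.enzyme == gname:
                    assert v[j] == 0.0
                else:
                    assert v[j] == ref[j]


class TestValidation:
    def test_negative_concentration_names_offender(self, network, ref_params):
        x = np.zeros(9)
        x[3] = -1.0
        with pytest.raises(ValueError, match="C16DHSM"):
            network.rhs(x, InputVector(np.zeros(4), np.zeros(9)), ref_params)

    def test_negative_gene_fold_rejected(self, network, ref_params):
        gene = np.zeros(9)
        gene[7] = -0.1
        with pytest.raises(ValueError, match="Cerk"):
            network.rhs(np.zeros(9), InputVector(np.zeros(4), gene), ref_params)

    def test_negative_rate_constant_rejected(self, network):
        with pytest.raises(ValueError, match="kf2"):
            network.make_params(dict.fromkeys(network.param_names, 0.0) | {"kf2": -1.0})

    def test_unknown_species_name_rejected(self):
        cat = sk.SpeciesCatalog(("A",), ("U",), ("G",))
        with pytest.raises(KeyError, match="Bogus"):
            sk.ReactionNetwork(cat, [
                Reaction(id=1, reactants=("Bogus",), products=("A",), forward_param="kf1")
            ])

    def test_duplicate_catalog_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sk.SpeciesCatalog(("A", "B"), ("A",), ("G",))


class TestCatalogAndStructure:
    def test_reversible_reactions(self, network):
        rev = [r.id for r in network.reactions if r.reversible]
        assert rev == [9, 10, 19, 20]
        for r in network.reactions:
            if r.reversible:
                assert r.backward_param is not None

    def test_enzyme_free_reactions(self, network):
        """Reactions 2 and 16 carry no gene factor (constant-activity enzymes)."""
        by_id = {r.id: r for r in network.reactions}
        assert by_id[2].enzyme is None and by_id[16].enzyme is None
        # all other synthesis/conversion reactions carry their enzyme
        others = [r for r in network.reactions if r.products and r.id not in (2, 16)]
        assert all(r.enzyme is not None for r in others)

    def test_param_count_and_order(self, network, ref_params):
        assert network.n_params == 29
        assert len(ref_params) == 29
        assert network.param_names[:2] == ("kf1", "kf2")
        assert set(network.param_names[-4:]) == {"kb9", "kb10", "kb19", "kb20"}
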