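"""Structure dynamics: ensemble I/O, RMSF, interaction and GNM networks."""

import numpy as np
import pytest

from coevopath.structure import (
    EnsembleShapeError,
    InteractionParams,
    StructureEnsemble,
    ensemble_similarity,
    gnm_correlation_network,
    gnm_correlations,
    hydropathy_profile,
    interaction_network,
    read_structure,
    rmsf,
)
from coevopath.synthetic import SyntheticSpec, make_ensemble, write_pdb
from oracles import gnm_correlation_oracle, rmsf_oracle


def _mini_ensemble(ca_models, names=None):
    ca = np.asarray(ca_models, dtype=float)
    n = ca.shape[1]
    names = names or tuple(["ALA"] * n)
    side = [[ca[m, r][None, :] for r in range(n)] for m in range(ca.shape[0])]
    return StructureEnsemble(
        residue_names=tuple(names),
        residue_ids=tuple(range(1, n + 1)),
        ca=ca,
        sidechains=side,
    )


class TestReadStructure:
    def test_two_model_roundtrip(self, tmp_path, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        path = tmp_path / "ens.pdb"
        write_pdb(ens, path)
        back = read_structure(path)
        assert back.n_models == ens.n_models
        assert back.n_residues == ens.n_residues
        assert np.abs(back.ca - ens.ca).max() < 1e-3  # PDB prints 3 decimals

    def test_single_model_file(self, tmp_path):
        spec = SyntheticSpec(seed=3, n_models=1, n_residues=5)
        ens, _ = make_ensemble(spec)
        path = tmp_path / "one.pdb"
        write_pdb(ens, path)
        assert read_structure(path).n_models == 1

    def test_mismatched_models_rejected(self, tmp_path):
        spec = SyntheticSpec(seed=3, n_models=2, n_residues=5)
        ens, _ = make_ensemble(spec)
        path = tmp_path / "bad.pdb"
        write_pdb(ens, path)
        lines = path.read_text().splitlines()
        # drop residue 3 of model 2
        out, in_model2 = [], False
        for ln in lines:
            if ln.startswith("MODEL") and "2" in ln:
                in_model2 = True
            if in_model2 and ln.startswith("ATOM") and ln[22:26].strip() == "3":
                continue
            out.append(ln)
        path.write_text("\n".join(out) + "\n")
        with pytest.raises(EnsembleShapeError):
            read_structure(path)


class TestRMSF:
    def test_identical_models_zero(self):
        base = np.random.default_rng(0).normal(size=(6, 3))
        ens = _mini_ensemble([base, base, base])
        assert np.allclose(rmsf(ens).values, 0.0)

    def test_displacement_gives_half_offset(self):
        base = np.zeros((4, 3))
        moved = base.copy()
        moved[2, 0] = 2.0  # displace residue 3 by 2d along x, d = 1
        ens = _mini_ensemble([base, moved])
        prof = rmsf(ens)
        assert prof.values[2] == pytest.approx(1.0)
        assert prof.values[[0, 1, 3]] == pytest.approx([0, 0, 0])

    def test_matches_direct_summation_oracle(self, rng):
        ca = rng.normal(scale=2.0, size=(3, 10, 3))
        ens = _mini_ensemble(ca)
        assert np.abs(rmsf(ens).values - rmsf_oracle(ca)).max() < 1e-12

    def test_translation_invariance_with_superposition(self, rng):
        ca = rng.normal(size=(4, 8, 3))
        shifted = ca + np.array([5.0, -3.0, 12.0])[None, None, :]
        a = rmsf(_mini_ensemble(ca), superpose=True).values
        b = rmsf(_mini_ensemble(shifted), superpose=True).values
        assert np.allclose(a, b, atol=1e-10)


class TestInteractionNetwork:
    def _geom(self, spread):
        # three residues, one pseudo side-chain atom each
        pts = np.array([[0.0, 0, 0], [spread, 0, 0], [0, spread, 0]])
        return _mini_ensemble([pts])

    def test_no_contacts_no_edge(self):
        g = interaction_network(self._geom(50.0))
        assert g.number_of_edges() == 0

    def test_full_strength_kept_at_any_threshold(self):
        ens = self._geom(2.0)
        params = InteractionParams(
            e_c=100.0, contact_distance=4.5,
            normalization={"ALA": 1.0},
        )
        g = interaction_network(ens, params=params)
        # sc_ab = 1 = sqrt(sc_a*sc_b) -> strength exactly 100
        assert all(d["weight"] == pytest.approx(100.0) for _, _, d in g.edges(data=True))
        assert g.number_of_edges() == 3

    def test_hand_evaluated_strength(self):
        # residue 1 carries one side-chain atom, residue 2 carries two, all
        # within contact range: sc_ab = 2, sc_a = 25, sc_b = 16 -> E = 10.0
        ca = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        side = [[np.array([[0.0, 0, 0]]), np.array([[2.0, 0, 0], [2.5, 0, 0]])]]
        ens = StructureEnsemble(
            residue_names=("ARG", "LYS"), residue_ids=(1, 2),
            ca=ca[None, :, :], sidechains=side,
        )
        params = InteractionParams(
            e_c=4.0, contact_distance=4.5, normalization={"ARG": 25.0, "LYS": 16.0}
        )
        g = interaction_network(ens, params=params)
        assert g[1][2]["weight"] == pytest.approx(10.0)
        assert g.number_of_edges() == 1

    def test_raising_threshold_only_removes_edges(self, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        params_lo = InteractionParams(e_c=0.0, contact_distance=7.0)
        params_hi = InteractionParams(e_c=2.0, contact_distance=7.0)
        lo = interaction_network(ens, params=params_lo)
        hi = interaction_network(ens, params=params_hi)
        assert set(hi.edges) <= set(lo.edges)

    def test_unknown_residue_type_is_config_error(self):
        ens = _mini_ensemble([np.zeros((2, 3))], names=("ALA", "XXX"))
        with pytest.raises(KeyError, match="XXX"):
            interaction_network(ens)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        pts = rng.normal(scale=3.0, size=(6, 3))
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = pts @ R.T + np.array([4.0, 5.0, -6.0])
        params = InteractionParams(e_c=0.0, contact_distance=4.0,
                                   normalization={"ALA": 1.0})
        g1 = interaction_network(_mini_ensemble([pts]), params=params)
        g2 = interaction_network(_mini_ensemble([moved]), params=params)
        assert set(g1.edges) == set(g2.edges)


class TestGNM:
    def test_unit_self_correlation_and_symmetry(self, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        C = gnm_correlations(ens.ca[0])
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C, C.T)
        assert C.min() >= -1.0 - 1e-9 and C.max() <= 1.0 + 1e-9

    @pytest.mark.parametrize("n", [4, 7, 10])
    def test_chain_matches_eigendecomposition_oracle(self, n):
        coords = np.column_stack([np.arange(n) * 3.8, np.zeros(n), np.zeros(n)])
        C = gnm_correlations(coords, cutoff=4.0)
        assert np.abs(C - gnm_correlation_oracle(coords, 4.0)).max() < 1e-8

    def test_disconnected_contact_graph_rejected(self):
        coords = np.array([[0.0, 0, 0], [3, 0, 0], [100, 0, 0], [103, 0, 0]])
        with pytest.raises(ValueError, match="cutoff"):
            gnm_correlations(coords, cutoff=5.0)

    def test_network_edges_respect_threshold(self, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        g = gnm_correlation_network(ens, corr_threshold=0.7)
        C = gnm_correlations(ens.ca[0])
        expected = int((np.abs(np.triu(C, 1)) >= 0.7).sum())
        assert g.number_of_edges() == expected
        assert all(d["weight"] >= 0.7 for _, _, d in g.edges(data=True))


class TestEnsembleSimilarity:
    def test_duplicate_models_fully_similar(self):
        spec = SyntheticSpec(seed=9, n_models=1, n_residues=20, sigma=0.0)
        ens, _ = make_ensemble(spec)
        dup = _mini_ensemble([ens.ca[0], ens.ca[0]])
        S, _ = ensemble_similarity(dup)
        assert S[0, 1] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self, synthetic_ensemble):
        ens, _ = synthetic_ensemble
        S, _ = ensemble_similarity(ens)
        assert np.allclose(np.diag(S), 1.0)
        assert np.allclose(S, S.T, equal_nan=True)

    def test_planted_outlier_excluded_from_representative(self):
        spec = SyntheticSpec(seed=31, n_models=3, n_residues=40,
                             outlier_model=2, outlier_scale=8.0)
        ens, truth = make_ensemble(spec)
        S, rep = ensemble_similarity(ens)
        assert rep != truth.outlier_model
        off = np.where(np.eye(3, dtype=bool), np.nan, S)
        assert np.nanargmin(np.nanmean(off, axis=1)) == truth.outlier_model


class TestHydropathy:
    def test_scale_extremes(self):
        assert hydropathy_profile("I" * 20, 8, 12, 9).eq(4.5).all()
        assert hydropathy_profile("R" * 20, 8, 12, 9).eq(-4.5).all()

    def test_window_one_is_identity(self):
        seq = "MKWVFAG"
        prof = hydropathy_profile(seq, 1, len(seq), window=1)
        from coevopath.structure import KYTE_DOOLITTLE

        assert list(prof) == [KYTE_DOOLITTLE[a] for a in seq]

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            hydropathy_profile("MKWVFAG", 1, 5, window=4)

    def test_edge_truncation(self):
        prof = hydropathy_profile("IR", 1, 2, window=9)
        assert prof[1] == pytest.approx((4.5 - 4.5) / 2)
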