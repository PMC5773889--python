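"""Interaction propensity, pair potential, four-body potential, site
vectors and structural-neighbourhood aggregation."""

import math
from collections import Counter

import numpy as np
import pytest

from rnabind.features import (FEATURE_NAMES, GROUP_SIZES, IPTable,
                              N_FEATURES, N_SITE_FEATURES,
                              SITE_FEATURE_NAMES, PipelineConfig,
                              TetrahedronFrequencyModel, assemble_dataset,
                              build_ip_table, chain_geometry, fbs2p_scores,
                              ip_features, pair_potential, site_matrix,
                              snf_ed, snf_vd, triplet, TopographyModel)
from rnabind.geometry import euclidean_neighbors
from rnabind.providers import ProviderBundle
from rnabind.structures import Atom, Complex, Residue, label_binding
from rnabind.synthetic import SynthConfig, generate_complex
from conftest import make_residue, single_atom_chain


def spaced_chain(aa_codes, spacing=8.0):
    pts = [(i * spacing, 0.0, 0.0) for i in range(len(aa_codes))]
    return single_atom_chain(pts, aa_codes=list(aa_codes))


def handcount_complex():
    """Five spaced residues ACDEF; RNA 'AA' with exactly one binding event:
    nucleotide 1 sits 4 Å from the residue whose triplet is ACD."""
    protein = spaced_chain("ACDEF")
    rna = [Residue("R", 1, "A", [Atom("P", "P", (8.0, 4.0, 0.0))]),
           Residue("R", 2, "A", [Atom("P", "P", (300.0, 300.0, 300.0))])]
    return Complex("hand", [protein], [rna])


class TestInteractionPropensity:
    def test_table_is_always_32000_addressable(self):
        cx = handcount_complex()
        table = build_ip_table([(cx, label_binding(cx))])
        assert len(table) == 32000

    def test_unseen_triplet_is_zero(self):
        cx = handcount_complex()
        table = build_ip_table([(cx, label_binding(cx))])
        assert table.get("WWW", "G") == 0.0

    def test_hand_counted_single_event(self):
        # f_(P,R)=1, f_P(ACD)=1/3 (3 interior triplets), f_R(A)=1
        # ⇒ IP(ACD, A) = log2(3)
        cx = handcount_complex()
        table = build_ip_table([(cx, label_binding(cx))])
        assert table.get("ACD", "A") == pytest.approx(math.log2(3))
        assert sum(1 for v in table.values.values() if v != 0.0) == 1

    def test_ip_feature_vector_continues_hand_count(self):
        cx = handcount_complex()
        chain = cx.protein_chains[0]
        table = build_ip_table([(cx, label_binding(cx))])
        np.testing.assert_allclose(ip_features(1, chain, table),
                                   [math.log2(3), 0, 0, 0])

    def test_terminus_uses_padded_triplet_and_zero(self):
        cx = handcount_complex()
        chain = cx.protein_chains[0]
        assert triplet(chain, 0) == "XAC"
        table = build_ip_table([(cx, label_binding(cx))])
        np.testing.assert_allclose(ip_features(0, chain, table), [0, 0, 0, 0])

    def test_duplicated_dataset_doubles_the_pair_sum(self):
        # IP is a sum over protein-RNA pairs; per-pair frequencies are scale
        # invariant, so a duplicated dataset doubles every entry exactly
        cx = handcount_complex()
        items = [(cx, label_binding(cx))]
        t1 = build_ip_table(items)
        t2 = build_ip_table(items + items)
        for key, v in t1.values.items():
            assert t2.values[key] == pytest.approx(2 * v)

    def test_no_binding_events_warns_and_zeroes(self):
        protein = spaced_chain("ACDEF")
        rna = [Residue("R", 1, "A", [Atom("P", "P", (500., 500., 500.))])]
        cx = Complex("far", [protein], [rna])
        with pytest.warns(UserWarning, match="no binding events"):
            table = build_ip_table([(cx, label_binding(cx))])
        assert not table.values


class TestPairPotential:
    def chain_and_centers(self):
        chain = spaced_chain("ACDEFGHIKLMN", spacing=2.0)
        centers = np.array([[i * 2.0, 0.0, 0.0] for i in range(len(chain))])
        return chain, centers

    def test_close_sequence_neighbors_contribute_zero(self):
        chain, centers = self.chain_and_centers()
        table = {frozenset(p): -1.0 for p in
                 [(a, b) for a in "ACDEFGHIKLMN" for b in "ACDEFGHIKLMN"]}
        # residue 0: residues 1..3 are within 7 Å but |i-j| < 4; residue 4 is
        # 8 Å away. With min separation 4 nothing qualifies.
        assert pair_potential(0, chain, table, centers) == 0.0

    def test_single_qualifying_neighbor_absolute_value(self):
        chain = spaced_chain("ACDEF", spacing=1.5)
        centers = np.array([[i * 1.5, 0.0, 0.0] for i in range(5)])
        table = {frozenset((a, b)): 0.0 for a in "ACDEF" for b in "ACDEF"}
        table[frozenset(("A", "F"))] = -1.2
        # only j=4 has |i-j| ≥ 4; centre distance 6 Å ≤ 7 Å
        assert pair_potential(0, chain, table, centers) == pytest.approx(1.2)

    def test_matches_exhaustive_double_loop(self):
        rng = np.random.default_rng(4)
        cfg = SynthConfig(n_residues=12, n_nucleotides=4, seed=12)
        cx, _ = generate_complex(cfg)
        chain = cx.protein_chains[0]
        from rnabind.geometry import sidechain_center
        centers = np.array([sidechain_center(r) for r in chain])
        table = {frozenset((a, b)): float(rng.normal())
                 for a in "ACDEFGHIKLMNPQRSTVWY"
                 for b in "ACDEFGHIKLMNPQRSTVWY"}
        for i in range(len(chain)):
            expected = sum(
                table[frozenset((chain[i].aa_code, chain[j].aa_code))]
                for j in range(len(chain))
                if abs(i - j) >= 4
                and np.linalg.norm(centers[i] - centers[j]) <= 7.0)
            got = pair_potential(i, chain, table, centers)
            assert got == pytest.approx(abs(expected))


class TestFourBodyPotential:
    def test_observed_equals_expected_gives_zero_scores(self):
        chain = single_atom_chain(
            [(0, 0, 0), (3, 0, 0), (1.5, 3, 0), (1.5, 1, 3)],
            aa_codes=list("ACDE"))
        tets = [(0, 1, 2, 3)]
        comp = TetrahedronFrequencyModel.composition(chain, tets[0])
        model = TetrahedronFrequencyModel(observed={comp: 0.25},
                                          expected={comp: 0.25})
        np.testing.assert_allclose(fbs2p_scores(chain, tets, model), 0.0)

    def test_e_fold_enrichment_contributes_one_nat(self):
        chain = single_atom_chain(
            [(0, 0, 0), (3, 0, 0), (1.5, 3, 0), (1.5, 1, 3)],
            aa_codes=list("ACDE"))
        tets = [(0, 1, 2, 3)]
        comp = TetrahedronFrequencyModel.composition(chain, tets[0])
        model = TetrahedronFrequencyModel(observed={comp: math.e * 0.1},
                                          expected={comp: 0.1})
        np.testing.assert_allclose(fbs2p_scores(chain, tets, model), 1.0)

    def test_zero_expected_for_observed_composition_raises(self):
        chain = single_atom_chain([(0, 0, 0)] * 4, aa_codes=list("ACDE"))
        comp = ("A", "C", "D", "E")
        model = TetrahedronFrequencyModel(observed={comp: 0.5},
                                          expected={comp: 0.0})
        with pytest.raises(ValueError, match="zero expected"):
            model.log_ratio(comp)

    def test_counted_compositions_match_hand_model(self):
        cfg = SynthConfig(n_residues=8, n_nucleotides=3, seed=21)
        cx, _ = generate_complex(cfg)
        chain = cx.protein_chains[0]
        from rnabind.geometry import delaunay_tetrahedra
        tets = delaunay_tetrahedra(chain)
        model = TetrahedronFrequencyModel.from_chains([chain], [tets])
        # independent hand count of observed/expected frequencies
        comps = [tuple(sorted(chain[v].aa_code for v in t)) for t in tets]
        counts = Counter(comps)
        aa_freq = Counter(r.aa_code for r in chain)
        total_aa = sum(aa_freq.values())
        for comp, k in counts.items():
            f = k / len(tets)
            mult = Counter(comp)
            coeff = math.factorial(4)
            for m in mult.values():
                coeff //= math.factorial(m)
            p = coeff * math.prod((aa_freq[a] / total_aa) for a in comp)
            assert model.observed[comp] == pytest.approx(f)
            assert model.expected[comp] == pytest.approx(p)
            assert model.log_ratio(comp) == pytest.approx(math.log(f / p))
        # per-residue score is the sum over containing tetrahedra
        scores = fbs2p_scores(chain, tets, model)
        for i in range(len(chain)):
            expected = sum(model.log_ratio(c)
                           for t, c in zip(tets, comps) if i in t)
            assert scores[i] == pytest.approx(expected)


@pytest.fixture(scope="module")
def assembled():
    cfg = SynthConfig(n_residues=25, n_nucleotides=8, seed=31)
    cx, annot = generate_complex(cfg)
    items = [(cx, annot)]
    table = build_ip_table(items)
    ds = assemble_dataset(items, ProviderBundle(), table)
    return cx, annot, ds


class TestSiteVector:
    def _site(self, providers=None):
        cfg = SynthConfig(n_residues=10, n_nucleotides=4, seed=41)
        cx, annot = generate_complex(cfg)
        chain = cx.protein_chains[0]
        pcfg = PipelineConfig()
        geom = chain_geometry(chain, pcfg)
        table = build_ip_table([(cx, annot)])
        topo = TopographyModel.from_chains([chain], [geom.graph])
        freq = TetrahedronFrequencyModel.from_chains([chain],
                                                     [geom.tetrahedra])
        providers = providers or ProviderBundle()
        return chain, site_matrix(chain, geom, providers, table, topo, freq,
                                  pcfg)

    def test_width_is_63_and_groups_sum(self):
        _, site = self._site()
        assert site.shape[1] == N_SITE_FEATURES == 63
        assert sum(GROUP_SIZES.values()) == 63
        assert np.all(np.isfinite(site))

    def test_helix_class_one_hot(self):
        providers = ProviderBundle()
        chain, _ = self._site()
        for res in chain:
            providers.secondary_structure[res.key] = "H"
        _, site = self._site(providers)
        cols = [SITE_FEATURE_NAMES.index(c)
                for c in ("SS_HELIX", "SS_SHEET", "SS_COIL")]
        np.testing.assert_allclose(site[:, cols],
                                   np.tile([1.0, 0.0, 0.0], (len(site), 1)))

    def test_blank_class_is_coil(self):
        _, site = self._site()  # fallback provider: blank SS
        cols = [SITE_FEATURE_NAMES.index(c)
                for c in ("SS_HELIX", "SS_SHEET", "SS_COIL")]
        np.testing.assert_allclose(site[:, cols],
                                   np.tile([0.0, 0.0, 1.0], (len(site), 1)))

    def test_rsa_is_asa_over_max_asa(self):
        from rnabind.tables import MAX_ASA
        chain, site = self._site()
        asa = site[:, SITE_FEATURE_NAMES.index("ASA")]
        rsa = site[:, SITE_FEATURE_NAMES.index("RSA")]
        for i, res in enumerate(chain):
            assert rsa[i] == pytest.approx(asa[i] / MAX_ASA[res.aa_code])


class TestNeighborhoodAggregation:
    def test_no_neighbors_gives_zeros(self):
        site = np.arange(63, dtype=float)[None, :]
        graph = euclidean_neighbors(single_atom_chain([(0, 0, 0)]))
        np.testing.assert_allclose(snf_ed(site, graph), 0.0)
        np.testing.assert_allclose(snf_vd(site, None), 0.0)

    def test_single_neighbor_copies_its_values(self):
        chain = single_atom_chain([(0, 0, 0), (5.0, 0, 0)])
        graph = euclidean_neighbors(chain)
        site = np.vstack([np.full(63, 2.0), np.full(63, 7.0)])
        ed = snf_ed(site, graph)
        np.testing.assert_allclose(ed[0], 7.0)
        np.testing.assert_allclose(ed[1], 2.0)

    def test_brute_force_equality(self, medium_chain):
        rng = np.random.default_rng(6)
        site = rng.normal(size=(len(medium_chain), 63))
        graph = euclidean_neighbors(medium_chain)
        from rnabind.geometry import voronoi_adjacency
        adj = voronoi_adjacency(medium_chain)
        ed = snf_ed(site, graph)
        vd = snf_vd(site, adj)
        for r in range(len(medium_chain)):
            expected_ed = sum((site[n] for n in graph.neighbors(r)),
                              np.zeros(63))
            expected_vd = sum((site[n] for n in adj.neighbors(r)),
                              np.zeros(63))
            np.testing.assert_allclose(ed[r], expected_ed)
            np.testing.assert_allclose(vd[r], expected_vd)


class TestAssembleDataset:
    def test_width_is_189(self, assembled):
        _, _, ds = assembled
        assert ds.X.shape[1] == N_FEATURES == 189
        assert list(ds.X.columns) == FEATURE_NAMES

    def test_row_count_equals_total_residues(self):
        items = []
        for s in (51, 52, 53):
            cx, annot = generate_complex(
                SynthConfig(n_residues=12, n_nucleotides=4, seed=s))
            cx.id = f"c{s}"
            items.append((cx, annot))
        table = build_ip_table(items)
        ds = assemble_dataset(items, ProviderBundle(), table)
        assert len(ds.X) == sum(len(cx.protein_residues())
                                for cx, _ in items)
        assert set(ds.y) <= {-1, 1}

    def test_single_residue_protein_has_zero_snf_blocks(self):
        protein = [make_residue("A", 1, "A", [(0, 0, 0)], names=["CA"])]
        rna = [Residue("R", 1, "A", [Atom("P", "P", (3.0, 0, 0))])]
        cx = Complex("one", [protein], [rna])
        items = [(cx, label_binding(cx))]
        ds = assemble_dataset(items, ProviderBundle(), IPTable())
        assert len(ds.X) == 1
        np.testing.assert_allclose(ds.X.iloc[0, 63:].to_numpy(), 0.0)

    def test_complex_order_permutes_rows_only(self):
        items = []
        for s in (61, 62):
            cx, annot = generate_complex(
                SynthConfig(n_residues=10, n_nucleotides=4, seed=s))
            cx.id = f"c{s}"
            items.append((cx, annot))
        table = build_ip_table(items)
        ds_ab = assemble_dataset(items, ProviderBundle(), table)
        ds_ba = assemble_dataset(items[::-1], ProviderBundle(), table)
        order = [ds_ba.index.index(k) for k in ds_ab.index]
        np.testing.assert_allclose(ds_ab.X.to_numpy(),
                                   ds_ba.X.to_numpy()[order])

    def test_tsv_round_trip(self, assembled):
        _, _, ds = assembled
        from rnabind.features import FeatureDataset
        back = FeatureDataset.from_tsv(ds.to_tsv())
        np.testing.assert_allclose(back.X.to_numpy(), ds.X.to_numpy(),
                                   rtol=0, atol=5e-11)
        np.testing.assert_array_equal(back.y, ds.y)
        assert back.index == ds.index


class TestRigidInvariance:
    def test_site_features_invariant_under_rigid_transform(self):
        from conftest import rigid_transform, transform_complex
        cfg = SynthConfig(n_residues=15, n_nucleotides=5, seed=71)
        cx, annot = generate_complex(cfg)
        rng = np.random.default_rng(2)
        moved = transform_complex(cx, rigid_transform(rng))
        items_a = [(cx, annot)]
        items_b = [(moved, label_binding(moved))]
        ds_a = assemble_dataset(items_a, ProviderBundle(),
                                build_ip_table(items_a))
        ds_b = assemble_dataset(items_b, ProviderBundle(),
                                build_ip_table(items_b))
        asa_like = [j for j, name in enumerate(FEATURE_NAMES)
                    if "ASA" in name or "RSA" in name]
        exact = [j for j in range(189) if j not in asa_like]
        np.testing.assert_allclose(ds_a.X.to_numpy()[:, exact],
                                   ds_b.X.to_numpy()[:, exact],
                                   rtol=1e-6, atol=1e-8)
        # sphere-sampled accessibility is orientation-dependent only through
        # the finite point set: agreement to a few percent
        a = ds_a.X.to_numpy()[:, asa_like]
        b = ds_b.X.to_numpy()[:, asa_like]
        np.testing.assert_allclose(a, b, rtol=0.12, atol=1.0)
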