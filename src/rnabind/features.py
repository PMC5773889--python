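"""The 189-dimensional per-residue feature pipeline.

Each protein residue is described by 63 site features (SiteFs) computed on
the residue itself, plus two structural-neighbourhood blocks that sum the
neighbours' site features over (i) the 10 Å Euclidean sphere (SNF-ED) and
(ii) the Voronoi-facet adjacency (SNF-VD) — 63 × 3 = 189 values in total.

Site feature groups, in fixed column order (group sizes sum to 63):
physicochemical (10), side-chain pKa (2), PSSM (20), conservation (1),
ASA/RSA (2), secondary structure one-hot (3), interaction propensity (4),
disorder (6), atom/residue contacts (2), pair potential (1), topographical
index (1), local structural entropy (2), four-body pseudo-potential (1),
side-chain energy terms (6), Voronoi contacts (2).
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tables
from .geometry import (NeighborGraph, VoronoiAdjacency, contact_counts,
                       delaunay_tetrahedra, euclidean_neighbors,
                       sidechain_center, voronoi_adjacency)
from .providers import ProviderBundle
from .structures import (BindingAnnotation, Chain, Complex, binding_events)

PAD = "X"
N_SITE_FEATURES = 63
N_FEATURES = 189
NUCLEOTIDES = ("A", "U", "G", "C")
PP_RADIUS = 7.0
PP_MIN_SEPARATION = 4

PHYS_NAMES = ["N_ATOMS", "CHARGE", "H_BONDS", "MASS", "HYDROPATHY",
              "HYDROPHILICITY", "POLARITY", "POLARIZABILITY",
              "HELIX_PROPENSITY", "AVG_ASA"]

SITE_FEATURE_NAMES: list[str] = (
    PHYS_NAMES
    + ["PKA1", "PKA2"]
    + [f"PSSM_{aa}" for aa in tables.PSSM_ORDER]
    + ["CSCORE"]
    + ["ASA", "RSA"]
    + ["SS_HELIX", "SS_SHEET", "SS_COIL"]
    + [f"IP_{n}" for n in NUCLEOTIDES]
    + [f"DISORDER_{i}" for i in range(1, 7)]
    + ["NC_ATOM", "NC_RES"]
    + ["PP"]
    + ["TOPO"]
    + ["LSE", "DLSE"]
    + ["FBS2P"]
    + [f"SCE_{i}" for i in range(1, 7)]
    + ["VOR_NEIGHBORS", "VOR_FACETS"]
)
assert len(SITE_FEATURE_NAMES) == N_SITE_FEATURES

FEATURE_NAMES: list[str] = (SITE_FEATURE_NAMES
                            + [f"ED_{n}" for n in SITE_FEATURE_NAMES]
                            + [f"VD_{n}" for n in SITE_FEATURE_NAMES])

GROUP_SIZES = {"physicochemical": 10, "pka": 2, "pssm": 20, "cscore": 1,
               "asa": 2, "ss": 3, "ip": 4, "disorder": 6, "contacts": 2,
               "pp": 1, "topographical": 1, "lse": 2, "fbs2p": 1, "sce": 6,
               "voronoi_contacts": 2}


# ---------------------------------------------------------------------------
# Interaction propensity (triplet × nucleotide log-odds)
# ---------------------------------------------------------------------------

def triplet(chain: Chain, i: int) -> str:
    """Sequence triplet (i−1, i, i+1) around position ``i`` (0-based);
    chain termini are padded with 'X'."""
    aas = [chain[j].aa_code if 0 <= j < len(chain) else PAD
           for j in (i - 1, i, i + 1)]
    return "".join(aas)


@dataclass
class IPTable:
    """Interaction propensities IP(t, n): a log₂-odds enrichment of residue
    triplet t binding nucleotide n over the training complexes.  All
    20³ × 4 = 32,000 (triplet, nucleotide) cells are addressable; cells with
    no observed co-occurrence are 0.
    """

    values: dict[tuple[str, str], float] = field(default_factory=dict)

    N_ADDRESSABLE = 20 ** 3 * 4

    def get(self, t: str, n: str) -> float:
        return self.values.get((t, n), 0.0)

    def ip_vector(self, t: str) -> np.ndarray:
        return np.array([self.get(t, n) for n in NUCLEOTIDES])

    def __len__(self) -> int:  # addressable size, not stored non-zeros
        return self.N_ADDRESSABLE


def _chain_triplets(chain: Chain) -> list[str]:
    """Interior (unpadded) triplets of a chain."""
    return [triplet(chain, i) for i in range(1, len(chain) - 1)]


def build_ip_table(training: list[tuple[Complex, BindingAnnotation]],
                   cutoff: float = 5.0) -> IPTable:
    """Estimate the interaction-propensity table from annotated complexes.

    For each protein–RNA pair the joint frequency f_(P,R)(t, n) counts
    (triplet of a binding residue, contacted nucleotide) events; f_P(t) is
    the triplet frequency within the protein and f_R(n) the nucleotide
    frequency within the RNA.  Each pair contributes
    f_(P,R) · log₂(f_(P,R) / (f_P · f_R)), and zero-frequency terms
    contribute 0.
    """
    if not training:
        raise ValueError("no training complexes")
    table: dict[tuple[str, str], float] = {}
    any_event = False
    for complex_, _annot in training:
        events = binding_events(complex_, cutoff=cutoff)
        if not events:
            continue
        any_event = True
        # joint counts N_(P,R)(t, n)
        joint: Counter = Counter()
        pos_of = {r.key: i for chain in complex_.protein_chains
                  for i, r in enumerate(chain)}
        chain_of = {r.key: chain for chain in complex_.protein_chains
                    for r in chain}
        for res, nuc in events:
            t = triplet(chain_of[res.key], pos_of[res.key])
            if PAD in t:
                continue
            joint[(t, nuc)] += 1
        total_joint = sum(joint.values())
        if total_joint == 0:
            continue
        trip_counts = Counter(itertools.chain.from_iterable(
            _chain_triplets(c) for c in complex_.protein_chains))
        total_trip = sum(trip_counts.values())
        nuc_counts = Counter(r.aa_code for r in complex_.rna_residues())
        total_nuc = sum(nuc_counts.values())
        for (t, n), cnt in joint.items():
            f_pr = cnt / total_joint
            f_p = trip_counts[t] / total_trip if total_trip else 0.0
            f_r = nuc_counts[n] / total_nuc if total_nuc else 0.0
            if f_pr > 0 and f_p > 0 and f_r > 0:
                table[(t, n)] = table.get((t, n), 0.0) + \
                    f_pr * math.log2(f_pr / (f_p * f_r))
    if not any_event:
        warnings.warn("no binding events in training set: "
                      "interaction-propensity table is all zeros")
    return IPTable(values=table)


def ip_features(residue_index: int, chain: Chain, table: IPTable) -> np.ndarray:
    """(IP_A, IP_U, IP_G, IP_C) for the residue's sequence triplet.  Padded
    (terminal) or unobserved triplets look up as 0."""
    return table.ip_vector(triplet(chain, residue_index))


# ---------------------------------------------------------------------------
# Pair potential
# ---------------------------------------------------------------------------

def pair_potential(i: int, chain: Chain,
                   potential_table: dict[frozenset, float],
                   centers: np.ndarray,
                   radius: float = PP_RADIUS,
                   min_separation: int = PP_MIN_SEPARATION) -> float:
    """PP_i = |Σ_j P(aa_i, aa_j)| over residues j with sequence separation
    |i−j| ≥ 4 and side-chain-centre distance ≤ 7 Å."""
    total = 0.0
    for j in range(len(chain)):
        if abs(i - j) < min_separation:
            continue
        if np.linalg.norm(centers[i] - centers[j]) <= radius:
            total += potential_table[frozenset((chain[i].aa_code,
                                                chain[j].aa_code))]
    return abs(total)


# ---------------------------------------------------------------------------
# Four-body statistical pseudo-potential over Delaunay tetrahedra
# ---------------------------------------------------------------------------

Composition = tuple[str, str, str, str]  # sorted 4-tuple of amino acids


@dataclass
class TetrahedronFrequencyModel:
    """Observed vs expected frequencies of amino-acid compositions of
    Delaunay tetrahedra.  The expected frequency of an (order-free)
    composition is multinomial in the background amino-acid frequencies with
    the multiplicity correction 4!/∏ mₖ!."""

    observed: dict[Composition, float]
    expected: dict[Composition, float]
    log_base: float = math.e

    @classmethod
    def from_chains(cls, chains: list[Chain],
                    tetrahedra_per_chain: list[list[tuple[int, int, int, int]]],
                    log_base: float = math.e) -> "TetrahedronFrequencyModel":
        comp_counts: Counter = Counter()
        aa_counts: Counter = Counter()
        for chain, tets in zip(chains, tetrahedra_per_chain):
            aa_counts.update(r.aa_code for r in chain)
            for tet in tets:
                comp_counts[cls.composition(chain, tet)] += 1
        total = sum(comp_counts.values())
        observed = {c: k / total for c, k in comp_counts.items()} if total else {}
        total_aa = sum(aa_counts.values())
        freqs = {aa: c / total_aa for aa, c in aa_counts.items()}
        expected = {}
        for comp in observed:
            mult = Counter(comp)
            coeff = math.factorial(4)
            for m in mult.values():
                coeff //= math.factorial(m)
            p = coeff * math.prod(freqs.get(aa, 0.0) for aa in comp)
            expected[comp] = p
        return cls(observed=observed, expected=expected, log_base=log_base)

    @staticmethod
    def composition(chain: Chain, tet: tuple[int, int, int, int]) -> Composition:
        return tuple(sorted(chain[v].aa_code for v in tet))  # type: ignore

    def log_ratio(self, comp: Composition) -> float:
        f = self.observed.get(comp, 0.0)
        if f == 0.0:
            return 0.0  # unseen composition: no evidence either way
        p = self.expected.get(comp, 0.0)
        if p == 0.0:
            raise ValueError(
                f"inconsistent frequency model: observed composition {comp} "
                f"has zero expected frequency")
        return math.log(f / p) / math.log(self.log_base)


def fbs2p_scores(chain: Chain,
                 tetrahedra: list[tuple[int, int, int, int]],
                 model: TetrahedronFrequencyModel) -> np.ndarray:
    """Per-residue four-body pseudo-potential: the sum, over Delaunay
    tetrahedra containing the residue, of log(f/p) for the tetrahedron's
    amino-acid composition."""
    scores = np.zeros(len(chain))
    for tet in tetrahedra:
        r = model.log_ratio(model.composition(chain, tet))
        for v in tet:
            scores[v] += r
    return scores


# ---------------------------------------------------------------------------
# Topographical index and local structural entropy
# ---------------------------------------------------------------------------

@dataclass
class TopographyModel:
    """Mean Euclidean-neighbour count per amino-acid type over a training
    set; the topographical index of a residue is its own neighbour count
    divided by the mean for its type."""

    mean_counts: dict[str, float]
    global_mean: float

    @classmethod
    def from_chains(cls, chains: list[Chain],
                    graphs: list[NeighborGraph]) -> "TopographyModel":
        sums: Counter = Counter()
        counts: Counter = Counter()
        total, n = 0.0, 0
        for chain, graph in zip(chains, graphs):
            for i, res in enumerate(chain):
                deg = graph.degree(i)
                sums[res.aa_code] += deg
                counts[res.aa_code] += 1
                total += deg
                n += 1
        mean_counts = {aa: sums[aa] / counts[aa] for aa in counts}
        return cls(mean_counts=mean_counts, global_mean=(total / n) if n else 1.0)

    def index(self, aa: str, degree: int) -> float:
        mean = self.mean_counts.get(aa, self.global_mean)
        if mean <= 0:
            mean = max(self.global_mean, 1.0)
        return degree / mean


def local_structural_entropy(chain: Chain, window: int = 5) -> np.ndarray:
    """Sequence-window entropy over 8-state secondary-structure propensities.

    For each length-5 window the per-state propensities of its residues are
    averaged into a distribution whose Shannon entropy (bits) scores the
    window; a residue's LSE averages the up-to-4 preceding-and-covering
    windows (clamped at the termini).  Short chains use the whole sequence
    as a single window.
    """
    n = len(chain)
    props = np.array([tables.LSE_PROPENSITY[r.aa_code] for r in chain])

    def window_entropy(start: int) -> float:
        seg = props[max(0, start):min(n, start + window)]
        p = seg.mean(axis=0)
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    if n <= window:
        return np.full(n, window_entropy(0))
    lse = np.zeros(n)
    for i in range(n):
        starts = [s for s in range(i - window + 2, i + 1)
                  if 0 <= s <= n - window]
        if not starts:
            starts = [min(max(i - window // 2, 0), n - window)]
        lse[i] = float(np.mean([window_entropy(s) for s in starts]))
    return lse


# ---------------------------------------------------------------------------
# Site vectors and neighbourhood aggregation
# ---------------------------------------------------------------------------

SS_HELIX = set("GHI")
SS_SHEET = set("BE")


def ss_onehot(ss_class: str) -> np.ndarray:
    """DSSP 8-state class → 3-vector (helix, sheet, coil)."""
    c = (ss_class or " ").strip()
    if c in SS_HELIX:
        return np.array([1.0, 0.0, 0.0])
    if c in SS_SHEET:
        return np.array([0.0, 1.0, 0.0])
    return np.array([0.0, 0.0, 1.0])


@dataclass
class PipelineConfig:
    binding_cutoff: float = 5.0
    neighbor_radius: float = 10.0
    contact_cutoff: float = 5.0
    pp_radius: float = PP_RADIUS
    pp_min_separation: int = PP_MIN_SEPARATION
    pair_potentials: dict[frozenset, float] | None = None

    def resolved_pair_potentials(self) -> dict[frozenset, float]:
        return (self.pair_potentials if self.pair_potentials is not None
                else tables.synthetic_pair_potentials())


@dataclass
class ChainGeometry:
    """Geometry products computed once per protein chain."""

    graph: NeighborGraph
    adjacency: VoronoiAdjacency | None
    tetrahedra: list[tuple[int, int, int, int]]
    centers: np.ndarray
    nc_atom: np.ndarray
    nc_res: np.ndarray


def chain_geometry(chain: Chain, config: PipelineConfig) -> ChainGeometry:
    graph = euclidean_neighbors(chain, radius=config.neighbor_radius)
    n_atoms = sum(len(r.atoms) for r in chain)
    adjacency = None
    if n_atoms >= 4 and len(chain) >= 2:
        try:
            adjacency = voronoi_adjacency(chain)
        except Exception:
            adjacency = None
    try:
        tets = delaunay_tetrahedra(chain)
    except Exception:
        tets = []
    centers = np.array([sidechain_center(r) for r in chain])
    nc_a, nc_r = contact_counts(chain, contact_cutoff=config.contact_cutoff)
    return ChainGeometry(graph=graph, adjacency=adjacency, tetrahedra=tets,
                         centers=centers, nc_atom=nc_a, nc_res=nc_r)


def site_matrix(chain: Chain, geom: ChainGeometry,
                providers: ProviderBundle, ip_table: IPTable,
                topo_model: TopographyModel,
                freq_model: TetrahedronFrequencyModel,
                config: PipelineConfig) -> np.ndarray:
    """All 63 site features for every residue of a chain, as an (n, 63)
    array in the fixed :data:`SITE_FEATURE_NAMES` order."""
    n = len(chain)
    pot = config.resolved_pair_potentials()
    asa_abs = providers.get_asa_array(chain)
    lse = local_structural_entropy(chain)
    fbs = fbs2p_scores(chain, geom.tetrahedra, freq_model)

    out = np.zeros((n, N_SITE_FEATURES))
    for i, res in enumerate(chain):
        aa = res.aa_code
        if aa not in tables.PHYSICOCHEMICAL:
            raise ValueError(f"unknown amino acid {aa!r} at residue {res.key}")
        key = res.key
        row: list[float] = []
        row.extend(tables.PHYSICOCHEMICAL[aa])
        row.extend(tables.PKA[aa])
        row.extend(providers.get_pssm(key, aa))
        row.append(providers.get_conservation(key))
        rsa = asa_abs[i] / tables.MAX_ASA[aa]
        row.extend((asa_abs[i], rsa))
        row.extend(ss_onehot(providers.get_ss(key)))
        row.extend(ip_features(i, chain, ip_table))
        row.extend(providers.get_disorder(key))
        row.extend((geom.nc_atom[i], geom.nc_res[i]))
        row.append(pair_potential(i, chain, pot, geom.centers,
                                  radius=config.pp_radius,
                                  min_separation=config.pp_min_separation))
        row.append(topo_model.index(aa, geom.graph.degree(i)))
        row.extend((lse[i], 0.0))  # ΔLSE: 0 in prediction mode (no mutant)
        row.append(fbs[i])
        row.extend(providers.get_sce(key))
        if geom.adjacency is not None:
            vor_n = len(geom.adjacency.neighbors(i))
            vor_f = sum(c for (a, b), c in geom.adjacency.facet_counts.items()
                        if i in (a, b))
        else:
            vor_n = vor_f = 0
        row.extend((float(vor_n), float(vor_f)))
        out[i] = row
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite site feature values")
    return out


def snf_ed(site: np.ndarray, graph: NeighborGraph) -> np.ndarray:
    """Euclidean structural-neighbourhood block: for each residue, the sum
    of the site-feature vectors of its Euclidean neighbours (empty
    neighbourhood → zeros)."""
    out = np.zeros_like(site)
    for r in range(site.shape[0]):
        for n in graph.neighbors(r):
            out[r] += site[n]
    return out


def snf_vd(site: np.ndarray, adjacency: VoronoiAdjacency | None) -> np.ndarray:
    """Voronoi structural-neighbourhood block: sum of the Voronoi
    neighbours' site-feature vectors."""
    out = np.zeros_like(site)
    if adjacency is None:
        return out
    for a, b in adjacency.facet_counts:
        out[a] += site[b]
        out[b] += site[a]
    return out


@dataclass
class FeatureDataset:
    """Assembled dataset: X is (N, 189) in :data:`FEATURE_NAMES` order."""

    X: pd.DataFrame
    y: np.ndarray  # ±1
    index: list[tuple[str, str, int]]  # (complex id, chain id, seq index)

    def to_tsv(self) -> str:
        df = self.X.copy()
        df.insert(0, "residue", [f"{c}/{ch}:{i}" for c, ch, i in self.index])
        df["label"] = self.y
        return df.to_csv(sep="\t", index=False)

    @classmethod
    def from_tsv(cls, text: str) -> "FeatureDataset":
        import io as _io
        df = pd.read_csv(_io.StringIO(text), sep="\t")
        index = []
        for key in df["residue"]:
            cid, rest = key.split("/", 1)
            ch, idx = rest.rsplit(":", 1)
            index.append((cid, ch, int(idx)))
        y = df["label"].to_numpy(dtype=int)
        X = df.drop(columns=["residue", "label"])
        return cls(X=X, y=y, index=index)


def assemble_dataset(items: list[tuple[Complex, BindingAnnotation]],
                     providers: ProviderBundle,
                     ip_table: IPTable,
                     config: PipelineConfig | None = None,
                     site_perturbation=None) -> FeatureDataset:
    """Run the full pipeline over annotated complexes.

    The topographical and four-body frequency models are fitted on the input
    set itself (training semantics).  ``site_perturbation``, if given, is
    called as ``site_perturbation(site, chain, complex_)`` after site-feature
    extraction and before neighbourhood aggregation and may return a modified
    site matrix — the synthetic generator uses this hook to plant signal that
    then propagates through the neighbourhood sums.
    """
    config = config or PipelineConfig()
    chains = [ch for cx, _ in items for ch in cx.protein_chains]
    geoms = {}
    for cx, _ in items:
        for ch in cx.protein_chains:
            geoms[id(ch)] = chain_geometry(ch, config)
    topo = TopographyModel.from_chains(
        chains, [geoms[id(c)].graph for c in chains])
    freq = TetrahedronFrequencyModel.from_chains(
        chains, [geoms[id(c)].tetrahedra for c in chains])

    blocks, labels, index = [], [], []
    for cx, annot in items:
        for ch in cx.protein_chains:
            geom = geoms[id(ch)]
            site = site_matrix(ch, geom, providers, ip_table, topo, freq,
                               config)
            if site_perturbation is not None:
                site = site_perturbation(site, ch, cx)
            ed = snf_ed(site, geom.graph)
            vd = snf_vd(site, geom.adjacency)
            blocks.append(np.hstack([site, ed, vd]))
            labels.extend(annot.labels[r.key] for r in ch)
            index.extend((cx.id, r.chain_id, r.seq_index) for r in ch)
    X = pd.DataFrame(np.vstack(blocks), columns=FEATURE_NAMES)
    return FeatureDataset(X=X, y=np.asarray(labels, dtype=int), index=index)
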