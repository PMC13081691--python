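"""Superposition-free interface similarity between predicted complexes.

Residues of homologous complexes are mapped by global sequence alignment
(BLOSUM62, gap open 11, extend 1); the interface local distance difference
test (lDDT) then measures, without any superposition, what fraction of
interchain atom distances found in one model (within a 15 Å inclusion
radius) are preserved in the other at thresholds {0.5, 1, 2, 4} Å.  Atoms
considered are backbone N/CA/C/O plus CB.  The reported edge value is the
mean of both directions; edges at or above the 0.80 threshold define the
similarity network whose connected components are the interface clusters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .config import ScoringConfig
from .model import ComplexModel

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueMapping",
    "SimilarityEdge",
    "InteractionNetwork",
    "map_chains",
    "identity_mapping",
    "interface_lddt",
    "build_network",
    "cluster_network",
]

LDDT_ATOMS = ("N", "CA", "C", "O", "CB")
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
LDDT_RADIUS = 15.0  # Å inclusion radius in the reference model


@dataclass
class ResidueMapping:
    """One-to-one aligned residue correspondence between two models.

    ``chain_pairs`` maps chain ids of model A to chain ids of model B;
    ``pairs[(cid_a, cid_b)]`` lists aligned (1-based) residue index pairs;
    ``percent_identity`` is per chain pair, identical positions over
    alignment length × 100.
    """

    chain_pairs: dict[str, str]
    pairs: dict[tuple[str, str], list[tuple[int, int]]]
    percent_identity: dict[tuple[str, str], float]

    def residue_map(self) -> dict[tuple[str, int], tuple[str, int]]:
        out: dict[tuple[str, int], tuple[str, int]] = {}
        for (ca, cb), plist in self.pairs.items():
            for ia, ib in plist:
                out[(ca, ia)] = (cb, ib)
        return out


@dataclass(frozen=True)
class SimilarityEdge:
    model_a: str
    model_b: str
    interface_lddt: float
    n_mapped_interface_pairs: int
    coverage: float = 1.0  # fraction of reference interface pairs mapped


@dataclass
class InteractionNetwork:
    graph: nx.Graph
    threshold: float
    clusters: list[set[str]] = field(default_factory=list)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _align_chain(seq_a: str, seq_b: str):
    aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    n_ident = 0
    blocks_a, blocks_b = aln.aligned
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i + 1, j + 1))
            if seq_a[i] == seq_b[j]:
                n_ident += 1
    aln_len = aln.length
    pid = 100.0 * n_ident / aln_len if aln_len else 0.0
    return float(aln.score), pairs, pid


def map_chains(model_a: ComplexModel, model_b: ComplexModel) -> ResidueMapping:
    """Map residues of model A onto model B chain by chain.

    Chains are paired by the assignment maximising the summed global
    alignment score (exhaustive over permutations; models have few chains).
    Only aligned, non-gap positions enter the mapping.  Raises
    ``ValueError`` when no chain pairing achieves a positive score.
    """
    ids_a = model_a.chain_ids
    ids_b = model_b.chain_ids
    cache: dict[tuple[str, str], tuple[float, list, float]] = {}
    for ca in ids_a:
        for cb in ids_b:
            cache[(ca, cb)] = _align_chain(
                model_a.chain(ca).sequence, model_b.chain(cb).sequence
            )
    k = min(len(ids_a), len(ids_b))
    best_total, best_assign = -np.inf, None
    for subset_a in itertools.permutations(ids_a, k):
        for subset_b in itertools.permutations(ids_b, k):
            total = sum(cache[(a, b)][0]
                        for a, b in zip(subset_a, subset_b))
            if total > best_total:
                best_total = total
                best_assign = list(zip(subset_a, subset_b))
    if best_assign is None or best_total <= 0:
        raise ValueError(
            f"no chain pairing with positive alignment score between "
            f"{model_a.model_id} and {model_b.model_id}"
        )
    chain_pairs = dict(best_assign)
    pairs = {}
    pid = {}
    for ca, cb in best_assign:
        _, plist, p = cache[(ca, cb)]
        pairs[(ca, cb)] = plist
        pid[(ca, cb)] = p
    return ResidueMapping(chain_pairs=chain_pairs, pairs=pairs,
                          percent_identity=pid)


def identity_mapping(model: ComplexModel) -> ResidueMapping:
    """Self-mapping of a model (used when comparing replicate poses)."""
    chain_pairs = {c.chain_id: c.chain_id for c in model.chains}
    pairs = {
        (c.chain_id, c.chain_id): [(r.index, r.index) for r in c.residues]
        for c in model.chains
    }
    pid = {k: 100.0 for k in pairs}
    return ResidueMapping(chain_pairs=chain_pairs, pairs=pairs,
                          percent_identity=pid)


def _atom_table(model: ComplexModel):
    """Coordinates of backbone+CB atoms: dict (chain, resi, atom) → xyz."""
    table: dict[tuple[str, int, str], np.ndarray] = {}
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                if atom.name in LDDT_ATOMS:
                    table[(chain.chain_id, res.index, atom.name)] = np.array(
                        [atom.x, atom.y, atom.z]
                    )
    return table


def _directional_lddt(ref: ComplexModel, other_table: dict,
                      res_map: dict[tuple[str, int], tuple[str, int]],
                      ) -> tuple[float, int, int]:
    """lDDT of ``other`` against reference ``ref``.

    Returns (score, n_mapped_pairs, n_reference_pairs).  Score is the mean
    over thresholds of the fraction of mapped interchain reference pairs
    (d_ref < 15 Å) whose distance is preserved within the threshold.
    """
    keys: list[tuple[str, int, str]] = []
    coords: list[np.ndarray] = []
    for chain in ref.chains:
        for res in chain.residues:
            for atom in res.atoms:
                if atom.name in LDDT_ATOMS:
                    keys.append((chain.chain_id, res.index, atom.name))
                    coords.append(np.array([atom.x, atom.y, atom.z]))
    xyz = np.vstack(coords)
    cid_index = {c.chain_id: i for i, c in enumerate(ref.chains)}
    chain_of = np.array([cid_index[k[0]] for k in keys])
    d_ref = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    iu, ju = np.triu_indices(len(keys), k=1)
    sel = (chain_of[iu] != chain_of[ju]) & (d_ref[iu, ju] < LDDT_RADIUS)
    iu, ju = iu[sel], ju[sel]
    n_ref_pairs = len(iu)
    if n_ref_pairs == 0:
        raise ValueError(
            f"model {ref.model_id}: no interchain atom pairs within "
            f"{LDDT_RADIUS} Å — interface undefined"
        )

    mapped_xyz = np.full((len(keys), 3), np.nan)
    for idx, (cid, resi, aname) in enumerate(keys):
        tgt = res_map.get((cid, resi))
        if tgt is None:
            continue
        coord = other_table.get((tgt[0], tgt[1], aname))
        if coord is not None:
            mapped_xyz[idx] = coord
    ok = np.isfinite(mapped_xyz[iu, 0]) & np.isfinite(mapped_xyz[ju, 0])
    iu_m, ju_m = iu[ok], ju[ok]
    n_mapped = len(iu_m)
    if n_mapped == 0:
        return 0.0, 0, n_ref_pairs
    d_other = np.linalg.norm(mapped_xyz[iu_m] - mapped_xyz[ju_m], axis=-1)
    delta = np.abs(d_ref[iu_m, ju_m] - d_other)
    score = float(np.mean([
        (delta < t).mean() for t in LDDT_THRESHOLDS
    ]))
    return score, n_mapped, n_ref_pairs


def interface_lddt(model_a: ComplexModel, model_b: ComplexModel,
                   mapping: ResidueMapping | None = None,
                   config: ScoringConfig | None = None) -> SimilarityEdge:
    """Symmetrised superposition-free interface lDDT between two models.

    The A→B direction takes model A's interchain backbone+CB atom pairs
    within 15 Å as reference distances and scores their preservation in
    model B at thresholds {0.5, 1, 2, 4} Å; the edge value is the mean of
    both directions.  Reference pairs whose atoms are unmapped are skipped
    and reported via ``coverage``.
    """
    if mapping is None:
        mapping = map_chains(model_a, model_b)
    fwd = mapping.residue_map()
    rev = {v: k for k, v in fwd.items()}
    table_a = _atom_table(model_a)
    table_b = _atom_table(model_b)
    s_ab, n_ab, tot_ab = _directional_lddt(model_a, table_b, fwd)
    s_ba, n_ba, tot_ba = _directional_lddt(model_b, table_a, rev)
    coverage = (n_ab + n_ba) / (tot_ab + tot_ba)
    return SimilarityEdge(
        model_a=model_a.model_id,
        model_b=model_b.model_id,
        interface_lddt=(s_ab + s_ba) / 2.0,
        n_mapped_interface_pairs=n_ab + n_ba,
        coverage=coverage,
    )


def build_network(edges: list[SimilarityEdge],
                  node_metadata: dict[str, dict] | None = None,
                  config: ScoringConfig | None = None,
                  threshold: float | None = None) -> InteractionNetwork:
    """Threshold the edge list into a similarity network.

    Edges with interface_lddt ≥ threshold (default 0.80) are retained;
    every node mentioned in the edge list or metadata is kept even if it
    ends up isolated.
    """
    config = config or ScoringConfig()
    thr = config.lddt_edge_threshold if threshold is None else threshold
    g = nx.Graph()
    for model_id, meta in (node_metadata or {}).items():
        g.add_node(model_id, **meta)
    for e in edges:
        for m in (e.model_a, e.model_b):
            if m not in g:
                g.add_node(m)
        if e.interface_lddt >= thr:
            g.add_edge(e.model_a, e.model_b,
                       interface_lddt=float(e.interface_lddt),
                       n_pairs=int(e.n_mapped_interface_pairs))
    return InteractionNetwork(graph=g, threshold=thr)


def cluster_network(net: InteractionNetwork,
                    method: str = "components") -> list[set[str]]:
    """Partition the thresholded network into interface clusters.

    ``components`` (default) takes connected components; ``greedy``
    repeatedly seeds a cluster at the highest-degree remaining node and
    absorbs its neighbours.  Clusters are ordered by their smallest member
    id and stored on the network.
    """
    g = net.graph
    if method == "components":
        clusters = [set(c) for c in nx.connected_components(g)]
    elif method == "greedy":
        remaining = g.copy()
        clusters = []
        while remaining.number_of_nodes():
            seed = max(remaining.nodes,
                       key=lambda n: (remaining.degree(n), str(n)))
            members = {seed} | set(remaining.neighbors(seed))
            clusters.append(members)
            remaining.remove_nodes_from(members)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    clusters.sort(key=lambda c: min(str(m) for m in c))
    net.clusters = clusters
    return clusters
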