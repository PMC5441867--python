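"""Molecular network construction, family extraction and library dereplication.

Features become nodes; an edge between two features requires (i) modified
cosine strictly above the edge threshold, (ii) at least the minimum number
of matched peaks, and (iii) reciprocal rank: each node must appear in the
other's top-K most similar neighbors.  Connected components of the retained
edge set with two or more nodes are the molecular families — groups of
features interpreted as structural analogs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import LibraryEntry
from .processing import ConsensusFeature, NetworkingParams, modified_cosine, apply_standard_filters

logger = logging.getLogger(__name__)


@dataclass
class Edge:
    feature_a: str
    feature_b: str
    cosine: float
    matched_peaks: int
    precursor_delta: float


@dataclass
class LibraryMatch:
    feature_id: str
    compound_name: str
    cosine: float
    matched_peaks: int
    source_library: str


@dataclass
class MolecularNetwork:
    """Thresholded similarity network over consensus features."""

    features: list[ConsensusFeature]
    edges: list[Edge]
    params: NetworkingParams
    #: family_id -> sorted node ids; families are components with >= 2 nodes,
    #: numbered by decreasing size (FAM001 is the largest).
    families: dict[str, list[str]] = field(default_factory=dict)
    singletons: list[str] = field(default_factory=list)
    library_matches: dict[str, LibraryMatch] = field(default_factory=dict)
    #: optional sample_id -> site code mapping used for node site-presence
    #: attributes; samples without an entry fall back to their id prefix
    sample_sites: dict[str, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.features)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def family_of(self, feature_id: str) -> str | None:
        for fam, members in self.families.items():
            if feature_id in members:
                return fam
        return None

    def to_graph(self) -> nx.Graph:
        """Materialize as a networkx graph with serializable attributes."""
        g = nx.Graph()
        membership = {fid: fam for fam, members in self.families.items() for fid in members}
        for f in self.features:
            site_counts = {}
            for sample_id, ab in f.per_sample_abundance.items():
                if ab > 0:
                    site = self.sample_sites.get(sample_id, sample_id.split("_")[0])
                    site_counts[site] = site_counts.get(site, 0) + 1
            match = self.library_matches.get(f.feature_id)
            g.add_node(
                f.feature_id,
                precursor_mz=float(f.consensus_precursor_mz),
                member_count=int(f.member_count),
                family_id=membership.get(f.feature_id, ""),
                library_match=(match.compound_name if match else ""),
                site_presence=";".join(f"{k}:{v}" for k, v in sorted(site_counts.items())),
            )
        for e in self.edges:
            g.add_edge(
                e.feature_a,
                e.feature_b,
                cosine=float(e.cosine),
                matched_peaks=int(e.matched_peaks),
                precursor_delta=float(e.precursor_delta),
            )
        return g


def build_network(
    features: list[ConsensusFeature], params: NetworkingParams | None = None
) -> MolecularNetwork:
    """Score all feature pairs with the modified cosine and keep the edges
    passing the cosine/matched-peak thresholds and the reciprocal top-K rule.

    Neighbor ranking for the top-K rule orders candidates by descending
    cosine, then more matched peaks, then smaller |precursor delta|, then
    lexicographic id — so rank-K ties resolve deterministically.
    """
    params = params or NetworkingParams()
    n = len(features)
    ids = [f.feature_id for f in features]
    candidate: dict[tuple[int, int], tuple[float, int, float]] = {}
    spectra = [f.as_spectrum() for f in features]
    for i in range(n):
        for j in range(i + 1, n):
            cos, matched = modified_cosine(
                spectra[i], spectra[j], params.fragment_tolerance, params.intensity_transform
            )
            if cos > params.edge_cosine_threshold and matched >= params.min_matched_peaks:
                delta = spectra[i].precursor_mz - spectra[j].precursor_mz
                candidate[(i, j)] = (cos, matched, delta)

    # reciprocal top-K: rank each node's candidate neighbors
    neighbor_rank: list[set[int]] = [set() for _ in range(n)]
    per_node: list[list[tuple[float, int, float, str, int]]] = [[] for _ in range(n)]
    for (i, j), (cos, matched, delta) in candidate.items():
        per_node[i].append((-cos, -matched, abs(delta), ids[j], j))
        per_node[j].append((-cos, -matched, abs(delta), ids[i], i))
    for i in range(n):
        ranked = sorted(per_node[i])
        neighbor_rank[i] = {entry[4] for entry in ranked[: params.top_k_neighbors]}

    edges = [
        Edge(ids[i], ids[j], cos, matched, delta)
        for (i, j), (cos, matched, delta) in sorted(candidate.items())
        if j in neighbor_rank[i] and i in neighbor_rank[j]
    ]
    network = MolecularNetwork(features=features, edges=edges, params=params)
    _assign_families(network)
    logger.info(
        "build_network: %d nodes, %d candidate edges, %d retained, %d families",
        n, len(candidate), len(edges), len(network.families),
    )
    return network


def _assign_families(network: MolecularNetwork) -> None:
    g = nx.Graph()
    g.add_nodes_from(f.feature_id for f in network.features)
    g.add_edges_from((e.feature_a, e.feature_b) for e in network.edges)
    components = [sorted(c) for c in nx.connected_components(g)]
    multi = [c for c in components if len(c) >= 2]
    multi.sort(key=lambda c: (-len(c), c[0]))
    width = max(3, len(str(len(multi))))
    network.families = {f"FAM{i + 1:0{width}d}": c for i, c in enumerate(multi)}
    network.singletons = sorted(n for c in components if len(c) == 1 for n in c)


def extract_families(network: MolecularNetwork) -> pd.DataFrame:
    """Family table: id, node ids, feature count and summed spectrum count,
    in decreasing-size rank order (the number-of-features / number-of-spectra
    pairing used to rank molecular families by abundance)."""
    members = {f.feature_id: f for f in network.features}
    rows = []
    for fam_id, node_ids in network.families.items():
        rows.append(
            {
                "family_id": fam_id,
                "n_features": len(node_ids),
                "n_spectra": int(sum(members[nid].member_count for nid in node_ids)),
                "feature_ids": ";".join(node_ids),
            }
        )
    df = pd.DataFrame(rows, columns=["family_id", "n_features", "n_spectra", "feature_ids"])
    return df.sort_values("family_id", ignore_index=True)


def dereplicate(
    features: list[ConsensusFeature],
    library: list[LibraryEntry],
    params: NetworkingParams | None = None,
    prefiltered: bool = False,
    all_hits: bool = False,
) -> tuple[list[LibraryMatch], dict]:
    """Match features against a reference spectral library.

    Library spectra are passed through the same two filters as the input
    data (unless ``prefiltered``), scored with the modified cosine, and hits
    are kept under the same cosine/matched-peak thresholds as network edges.
    By default only the best hit per feature is reported; ``all_hits``
    returns every passing hit.  The report carries the match rate
    (matched features / total features) and matched spectrum counts.
    """
    params = params or NetworkingParams()
    if not library:
        warnings.warn("dereplicate: empty library", stacklevel=2)
        return [], {"n_features": len(features), "n_matched_features": 0, "match_rate": 0.0, "n_matched_spectra": 0}
    lib_spectra = [
        (entry, entry.spectrum if prefiltered else apply_standard_filters(entry.spectrum, params))
        for entry in library
    ]
    matches: list[LibraryMatch] = []
    matched_features: set[str] = set()
    for f in features:
        fs = f.as_spectrum()
        hits: list[LibraryMatch] = []
        for entry, ls in lib_spectra:
            if ls.n_peaks == 0:
                continue
            cos, matched = modified_cosine(fs, ls, params.fragment_tolerance, params.intensity_transform)
            if cos > params.edge_cosine_threshold and matched >= params.min_matched_peaks:
                hits.append(LibraryMatch(f.feature_id, entry.compound_name, cos, matched, entry.source_library))
        if not hits:
            continue
        hits.sort(key=lambda h: (-h.cosine, -h.matched_peaks, h.compound_name))
        matched_features.add(f.feature_id)
        matches.extend(hits if all_hits else hits[:1])
    by_id = {f.feature_id: f for f in features}
    report = {
        "n_features": len(features),
        "n_matched_features": len(matched_features),
        "match_rate": len(matched_features) / len(features) if features else 0.0,
        "n_matched_spectra": int(sum(by_id[fid].member_count for fid in matched_features)),
    }
    return matches, report
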