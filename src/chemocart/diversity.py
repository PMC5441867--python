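"""Chemodiversity statistics: feature tables, dissimilarity, PCoA,
rarefaction, cross-dataset overlap and per-site uniqueness.

The feature table is a features x samples abundance matrix joined to sample
metadata.  Sample-to-sample dissimilarity uses Bray-Curtis on abundances
(the default for ordination figures) or binary Jaccard on presence sets;
principal coordinate analysis embeds the distance matrix by
eigendecomposition of the Gower-centered squared distances.  Rarefaction
draws samples without replacement and tracks unique-feature richness.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis, jaccard as _jaccard

from .io import SampleMetadata, ValidationError, provenance_record, write_tsv
from .processing import ConsensusFeature, NetworkingParams, modified_cosine

logger = logging.getLogger(__name__)


@dataclass
class DiversityParams:
    metric: str = "bray_curtis"  # bray_curtis | binary_jaccard
    rarefaction_iterations: int = 20
    rarefaction_depths: list[int] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.metric not in ("bray_curtis", "binary_jaccard"):
            raise ValidationError("metric must be 'bray_curtis' or 'binary_jaccard'")
        if self.rarefaction_iterations < 1:
            raise ValidationError("rarefaction_iterations must be >= 1")
        if list(self.rarefaction_depths) != sorted(self.rarefaction_depths):
            raise ValidationError("rarefaction_depths must be ascending")


@dataclass
class FeatureTable:
    """Features x samples abundance matrix with joined sample metadata."""

    matrix: pd.DataFrame  # index = feature ids, columns = sample ids
    metadata: dict[str, SampleMetadata] = field(default_factory=dict)
    dataset_label: str = ""

    def __post_init__(self) -> None:
        if (self.matrix.values < 0).any():
            raise ValidationError("feature table contains negative abundances")
        if self.matrix.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in feature table")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_features(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.matrix.shape[1])

    def presence(self) -> pd.DataFrame:
        """Boolean presence matrix (abundance strictly greater than zero)."""
        return self.matrix > 0

    def site_of(self, sample_id: str) -> str:
        meta = self.metadata.get(sample_id)
        if meta is None:
            raise ValidationError(f"sample {sample_id} has no metadata record")
        return meta.site_code

    def to_tsv(self, path: str | Path, seed: int | None = None, params: object = None) -> Path:
        df = self.matrix.copy()
        df.insert(0, "feature_id", df.index)
        return write_tsv(df, path, seed=seed, params=params)

    def to_biom_json(self, path: str | Path, seed: int | None = None, params: object = None) -> Path:
        """Write a BIOM v1.0 (sparse, JSON) table."""
        mat = self.matrix.values
        rows, cols = np.nonzero(mat)
        payload = {
            "id": self.dataset_label or "chemocart-feature-table",
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "Metabolite table",
            "generated_by": "chemocart",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "float",
            "shape": [int(mat.shape[0]), int(mat.shape[1])],
            "rows": [{"id": fid, "metadata": None} for fid in self.feature_ids],
            "columns": [
                {
                    "id": sid,
                    "metadata": (
                        {"site_code": self.metadata[sid].site_code} if sid in self.metadata else None
                    ),
                }
                for sid in self.sample_ids
            ],
            "data": [[int(r), int(c), float(mat[r, c])] for r, c in zip(rows, cols)],
            "_provenance": provenance_record(seed, params),
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
        return path

    @classmethod
    def from_biom_json(cls, path: str | Path) -> "FeatureTable":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        shape = payload["shape"]
        mat = np.zeros(shape)
        for r, c, v in payload["data"]:
            mat[r, c] = v
        return cls(
            matrix=pd.DataFrame(
                mat,
                index=[r["id"] for r in payload["rows"]],
                columns=[c["id"] for c in payload["columns"]],
            ),
            dataset_label=str(payload.get("id", "")),
        )


@dataclass
class OrdinationResult:
    """PCoA embedding: samples x axes, eigenvalues and variance explained."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def to_tsv(self, path: str | Path, seed: int | None = None, params: object = None) -> Path:
        df = self.coordinates.copy()
        df.insert(0, "sample_id", df.index)
        return write_tsv(df, path, seed=seed, params=params)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_feature_table(
    features: list[ConsensusFeature],
    metadata: list[SampleMetadata],
    dataset_label: str = "",
) -> FeatureTable:
    """Assemble the features x samples abundance matrix, zero-filled where a
    feature is absent from a sample.  Every sample referenced by a feature
    must have a metadata record."""
    meta = {m.sample_id: m for m in metadata}
    referenced = {sid for f in features for sid in f.per_sample_abundance}
    orphans = sorted(referenced - set(meta))
    if orphans:
        raise ValidationError(f"features reference samples missing from metadata: {orphans}")
    sample_ids = sorted(meta)
    mat = pd.DataFrame(
        0.0, index=[f.feature_id for f in features], columns=sample_ids
    )
    for f in features:
        for sid, ab in f.per_sample_abundance.items():
            mat.loc[f.feature_id, sid] = ab
    return FeatureTable(matrix=mat, metadata=meta, dataset_label=dataset_label)


def distance_matrix(table: FeatureTable, metric: str = "bray_curtis") -> pd.DataFrame:
    """Symmetric sample-sample dissimilarity matrix with zero diagonal.

    bray_curtis(x, y) = sum|x - y| / sum(x + y) on abundances;
    binary_jaccard(x, y) = 1 - |A & B| / |A | B| on presence sets.
    All-zero samples are at distance 1 from non-empty samples and 0 from
    other all-zero samples (logged).
    """
    if table.n_samples < 2:
        raise ValidationError("distance matrix requires at least 2 samples")
    if metric not in ("bray_curtis", "binary_jaccard"):
        raise ValidationError(f"unknown metric {metric!r}")
    samples = table.sample_ids
    data = table.matrix.values.T  # samples x features
    empty = data.sum(axis=1) == 0
    if empty.any():
        logger.info("distance_matrix: %d all-zero samples", int(empty.sum()))
    n = len(samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if empty[i] and empty[j]:
                d = 0.0
            elif empty[i] or empty[j]:
                d = 1.0
            elif metric == "bray_curtis":
                d = float(_braycurtis(data[i], data[j]))
            else:
                d = float(_jaccard(data[i] > 0, data[j] > 0))
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=samples, columns=samples)


def pcoa(dist: pd.DataFrame | np.ndarray) -> OrdinationResult:
    """Principal coordinate analysis of a distance matrix.

    Gower double-centering of -0.5 * d^2 followed by eigendecomposition.
    Axes are ordered by decreasing eigenvalue; axes with negative
    eigenvalues are reported in ``eigenvalues`` but excluded from the
    coordinates (no correction applied), and proportion explained is taken
    over the positive eigenvalues.  The sign of each axis is fixed so its
    first non-zero loading is positive.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        d = dist.values.astype(float)
    else:
        d = np.asarray(dist, dtype=float)
        labels = [f"s{i}" for i in range(d.shape[0])]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    n = d.shape[0]
    a = -0.5 * d**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-9 * max(abs(eigvals[0]), 1.0))
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    # sign convention: first non-zero loading of each axis positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    pos_sum = eigvals[positive].sum()
    prop = eigvals[positive] / pos_sum if pos_sum > 0 else np.zeros(int(positive.sum()))
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=labels, columns=[f"PC{k + 1}" for k in range(coords.shape[1])]
        ),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def rarefaction_curve(
    table: FeatureTable, params: DiversityParams | None = None
) -> pd.DataFrame:
    """Mean and SD of unique-feature richness at each sampling depth.

    For each depth, ``rarefaction_iterations`` random draws of that many
    samples without replacement; richness is the size of the union of
    features present in the drawn samples.  Seeded and reproducible.
    """
    params = params or DiversityParams()
    depths = list(params.rarefaction_depths) or list(range(1, table.n_samples + 1))
    if max(depths) > table.n_samples:
        raise ValidationError(
            f"rarefaction depth {max(depths)} exceeds sample count {table.n_samples}"
        )
    rng = np.random.default_rng(params.rng_seed)
    presence = table.presence().values  # features x samples
    n_samples = table.n_samples
    rows = []
    for depth in depths:
        richness = np.empty(params.rarefaction_iterations)
        for it in range(params.rarefaction_iterations):
            chosen = rng.choice(n_samples, size=depth, replace=False)
            richness[it] = int(presence[:, chosen].any(axis=1).sum())
        rows.append(
            {
                "depth": depth,
                "mean_richness": float(richness.mean()),
                "sd_richness": float(richness.std(ddof=0)),
            }
        )
    return pd.DataFrame(rows)


def dataset_overlap(
    tables: list[FeatureTable],
    features_by_table: list[list[ConsensusFeature]],
    params: NetworkingParams | None = None,
    focal: int = 0,
) -> dict:
    """Cross-dataset feature overlap via spectral matching.

    Because datasets are clustered independently, feature identity across
    datasets is defined spectrally: two features match when their precursors
    agree within ``parent_mass_tolerance`` and their modified cosine clears
    ``edge_cosine_threshold``.  Matching features across datasets are pooled
    into identity groups (connected components of the match graph); a group
    spanning multiple datasets is a shared feature.  Returns per-dataset
    unique/shared counts, pairwise overlap counts, and the focal dataset's
    percent-unique.
    """
    params = params or NetworkingParams()
    if len(tables) < 2:
        raise ValidationError("dataset_overlap requires >= 2 datasets")
    labels = [t.dataset_label or f"dataset{i}" for i, t in enumerate(tables)]
    entries = []  # (dataset index, feature)
    for di, feats in enumerate(features_by_table):
        entries.extend((di, f) for f in feats)
    spectra = [f.as_spectrum() for _, f in entries]
    precursors = np.array([s.precursor_mz for s in spectra])
    order = np.argsort(precursors)

    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(entries)))
    for pos, oi in enumerate(order):
        for oj in order[pos + 1 :]:
            if precursors[oj] - precursors[oi] > params.parent_mass_tolerance:
                break
            if entries[oi][0] == entries[oj][0]:
                continue  # same dataset: identity is feature id, not matching
            cos, _ = modified_cosine(
                spectra[oi], spectra[oj], params.fragment_tolerance, params.intensity_transform
            )
            if cos >= params.edge_cosine_threshold:
                g.add_edge(int(oi), int(oj))

    n_datasets = len(tables)
    unique = np.zeros(n_datasets, dtype=int)
    shared_groups = 0
    pairwise = np.zeros((n_datasets, n_datasets), dtype=int)
    focal_shared = 0
    for comp in nx.connected_components(g):
        datasets = {entries[i][0] for i in comp}
        if len(datasets) == 1:
            unique[next(iter(datasets))] += len(comp)
        else:
            shared_groups += 1
            for di in datasets:
                for dj in datasets:
                    if di < dj:
                        pairwise[di, dj] += 1
            if focal in datasets:
                focal_shared += sum(1 for i in comp if entries[i][0] == focal)
    focal_total = len(features_by_table[focal])
    pct_unique = 100.0 * unique[focal] / focal_total if focal_total else 0.0
    return {
        "labels": labels,
        "unique_counts": {labels[i]: int(unique[i]) for i in range(n_datasets)},
        "shared_groups": int(shared_groups),
        "pairwise_shared": {
            f"{labels[i]}|{labels[j]}": int(pairwise[i, j])
            for i in range(n_datasets)
            for j in range(i + 1, n_datasets)
        },
        "focal": labels[focal],
        "focal_total_features": int(focal_total),
        "focal_unique_features": int(unique[focal]),
        "focal_percent_unique": float(pct_unique),
    }


def location_uniqueness(table: FeatureTable) -> pd.DataFrame:
    """Per-site unique-feature counts and percentages.

    A feature's site set is the set of sites where its abundance exceeds
    zero in any sample.  Features found at exactly one site are attributed
    to that site; the remainder is the shared (multi-site) pool.  Two
    normalizations are emitted: percent of all features, and percent of
    single-site features only.  The final row reports the shared pool; the
    ``percent_of_all`` column sums to 100.
    """
    presence = table.presence()
    sites = pd.Series({sid: table.site_of(sid) for sid in table.sample_ids})
    site_presence = presence.T.groupby(sites).any()  # sites x features
    n_sites_per_feature = site_presence.sum(axis=0)
    detected = n_sites_per_feature > 0
    total = int(detected.sum())
    single = n_sites_per_feature == 1
    n_single = int(single.sum())
    rows = []
    for site in site_presence.index:
        count = int((site_presence.loc[site] & single).sum())
        rows.append(
            {
                "site": site,
                "unique_features": count,
                "percent_of_all": 100.0 * count / total if total else 0.0,
                "percent_of_single_site": 100.0 * count / n_single if n_single else 0.0,
            }
        )
    shared = total - n_single
    rows.append(
        {
            "site": "__shared__",
            "unique_features": shared,
            "percent_of_all": 100.0 * shared / total if total else 0.0,
            "percent_of_single_site": 0.0,
        }
    )
    return pd.DataFrame(rows)
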