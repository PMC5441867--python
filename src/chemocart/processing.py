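"""Spectrum filtering, consensus clustering and the shift-aware modified cosine.

The processing chain mirrors the standard molecular-networking workflow for
untargeted MS/MS data: de-noise each spectrum by removing fragment peaks
near the precursor and keeping only locally intense peaks, merge replicate
scans of the same molecule into consensus features, and score pairs of
spectra with a modified cosine in which a fragment may match either at the
same m/z or offset by the difference of the two precursor masses (so that
structural analogs sharing a substructure still align).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Spectrum, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NetworkingParams:
    """Spectral-processing and networking parameters.

    Defaults are the workflow's standard settings: fragment peaks within
    +/-17 Da of the precursor removed; top 6 peaks kept per +/-50 Da window;
    clustering at 1.0 Da parent / 0.5 Da fragment tolerance with consensus
    spectra of fewer than ``min_cluster_size`` = 3 members discarded; network
    edges require cosine > 0.6, >= 4 matched peaks and mutual membership in
    each other's top 10 neighbor lists.
    """

    precursor_exclusion_window: float = 17.0
    window_size: float = 50.0
    window_top_k: int = 6
    parent_mass_tolerance: float = 1.0
    fragment_tolerance: float = 0.5
    min_cluster_size: int = 3
    cluster_merge_cosine: float = 0.7
    edge_cosine_threshold: float = 0.6
    min_matched_peaks: int = 4
    top_k_neighbors: int = 10
    intensity_transform: str = "sqrt"  # sqrt | none

    def __post_init__(self) -> None:
        for name in ("precursor_exclusion_window", "window_size", "parent_mass_tolerance", "fragment_tolerance"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 <= self.cluster_merge_cosine <= 1:
            raise ValidationError("cluster_merge_cosine must be in [0, 1]")
        if not 0 <= self.edge_cosine_threshold <= 1:
            raise ValidationError("edge_cosine_threshold must be in [0, 1]")
        if self.intensity_transform not in ("sqrt", "none"):
            raise ValidationError("intensity_transform must be 'sqrt' or 'none'")


@dataclass
class ConsensusFeature:
    """A clustered molecular feature: consensus spectrum plus membership."""

    feature_id: str
    consensus_precursor_mz: float
    representative_peaks: np.ndarray
    member_spectrum_ids: list[str] = field(default_factory=list)
    per_sample_abundance: dict[str, float] = field(default_factory=dict)

    @property
    def member_count(self) -> int:
        return len(self.member_spectrum_ids)

    def as_spectrum(self) -> Spectrum:
        return Spectrum(
            spectrum_id=self.feature_id,
            sample_id="",
            precursor_mz=self.consensus_precursor_mz,
            peaks=self.representative_peaks,
        )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_precursor_window(s: Spectrum, window: float = 17.0) -> Spectrum:
    """Remove all fragment peaks within +/-``window`` Da of the precursor m/z.

    The interval is closed: a peak exactly at precursor +/- window is removed.
    Idempotent; an empty result is allowed.
    """
    if s.n_peaks == 0:
        return s
    keep = np.abs(s.peaks[:, 0] - s.precursor_mz) > window
    return s.replace_peaks(s.peaks[keep])


def filter_window_top_k(s: Spectrum, window: float = 50.0, k: int = 6) -> Spectrum:
    """Keep a peak iff it ranks among the ``k`` most intense within +/-``window``
    Da of its own m/z (closed interval).  Rank ties are broken in favor of the
    lower-m/z peak so the result is deterministic.  Idempotent.
    """
    n = s.n_peaks
    if n <= k:
        return s
    mz = s.peaks[:, 0]
    inten = s.peaks[:, 1]
    lo = np.searchsorted(mz, mz - window, side="left")
    hi = np.searchsorted(mz, mz + window, side="right")
    keep = np.empty(n, dtype=bool)
    for i in range(n):
        win_i = slice(lo[i], hi[i])
        stronger = (inten[win_i] > inten[i]) | ((inten[win_i] == inten[i]) & (mz[win_i] < mz[i]))
        keep[i] = int(stronger.sum()) < k
    return s.replace_peaks(s.peaks[keep])


def apply_standard_filters(s: Spectrum, params: NetworkingParams) -> Spectrum:
    """Precursor-window exclusion followed by windowed top-k selection."""
    out = filter_precursor_window(s, params.precursor_exclusion_window)
    return filter_window_top_k(out, params.window_size, params.window_top_k)


# ---------------------------------------------------------------------------
# modified cosine
# ---------------------------------------------------------------------------


def _transform_normalize(intensities: np.ndarray, transform: str) -> np.ndarray:
    v = np.sqrt(intensities) if transform == "sqrt" else intensities.astype(float)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    fragment_tolerance: float = 0.5,
    transform: str = "sqrt",
) -> tuple[float, int]:
    """Shift-aware spectral similarity in [0, 1] plus the matched peak count.

    Candidate peak pairs are those matching directly (|mz_a - mz_b| <= tol)
    or offset by the precursor mass difference
    (|mz_a - mz_b - (prec_a - prec_b)| <= tol).  Intensities are transformed
    (square root by default) and L2-normalized per spectrum; a one-to-one
    matching is then chosen greedily by descending intensity product, ties
    broken by smaller m/z deviation then lower m/z.  The score is the sum of
    matched products; symmetric in its arguments.
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        return 0.0, 0
    mza, mzb = a.peaks[:, 0], b.peaks[:, 0]
    va = _transform_normalize(a.peaks[:, 1], transform)
    vb = _transform_normalize(b.peaks[:, 1], transform)
    shift = a.precursor_mz - b.precursor_mz

    diff = mza[:, None] - mzb[None, :]
    dev = np.abs(diff)
    dev_shift = np.abs(diff - shift)
    candidate = (dev <= fragment_tolerance) | (dev_shift <= fragment_tolerance)
    ii, jj = np.nonzero(candidate)
    if ii.size == 0:
        return 0.0, 0
    products = va[ii] * vb[jj]
    deviation = np.minimum(dev[ii, jj], dev_shift[ii, jj])
    # deterministic greedy order: product desc, deviation asc, lower m/z first
    order = np.lexsort((mzb[jj], mza[ii], deviation, -products))
    used_a = np.zeros(a.n_peaks, dtype=bool)
    used_b = np.zeros(b.n_peaks, dtype=bool)
    score = 0.0
    matched = 0
    for idx in order:
        i, j = ii[idx], jj[idx]
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        score += products[idx]
        matched += 1
    return float(min(score, 1.0)), matched


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------


def _merge_peaks(peak_lists: list[np.ndarray], fragment_tolerance: float) -> np.ndarray:
    """Merge member peak lists: peaks within tolerance collapse to their
    intensity-weighted mean m/z with summed intensity."""
    allpeaks = np.vstack([p for p in peak_lists if p.size]) if peak_lists else np.empty((0, 2))
    if allpeaks.size == 0:
        return np.empty((0, 2))
    allpeaks = allpeaks[np.argsort(allpeaks[:, 0], kind="stable")]
    merged: list[list[float]] = []
    group_mz: list[float] = []
    group_int: list[float] = []

    def _flush() -> None:
        w = np.asarray(group_int)
        m = np.asarray(group_mz)
        total = w.sum()
        center = float((m * w).sum() / total) if total > 0 else float(m.mean())
        merged.append([center, float(total)])

    for mz, inten in allpeaks:
        if group_mz and mz - group_mz[-1] > fragment_tolerance:
            _flush()
            group_mz, group_int = [], []
        group_mz.append(float(mz))
        group_int.append(float(inten))
    if group_mz:
        _flush()
    return np.asarray(merged)


class _OpenCluster:
    __slots__ = ("members", "precursor_sum", "consensus")

    def __init__(self, seed_spectrum: Spectrum):
        self.members: list[Spectrum] = [seed_spectrum]
        self.precursor_sum = seed_spectrum.precursor_mz
        self.consensus = seed_spectrum

    @property
    def consensus_precursor(self) -> float:
        return self.precursor_sum / len(self.members)

    def add(self, s: Spectrum, params: NetworkingParams) -> None:
        self.members.append(s)
        self.precursor_sum += s.precursor_mz
        peaks = _merge_peaks([m.peaks for m in self.members], params.fragment_tolerance)
        consensus = Spectrum(
            spectrum_id=self.consensus.spectrum_id,
            sample_id="",
            precursor_mz=self.consensus_precursor,
            peaks=peaks,
        )
        self.consensus = filter_window_top_k(consensus, params.window_size, params.window_top_k)


def cluster_spectra(
    spectra: list[Spectrum], params: NetworkingParams | None = None
) -> tuple[list[ConsensusFeature], dict]:
    """Greedy single-pass consensus clustering of filtered spectra.

    Spectra are visited in ascending precursor-m/z order.  A spectrum joins
    the open cluster with the highest modified cosine among those whose
    consensus precursor lies within ``parent_mass_tolerance`` and whose
    cosine clears ``cluster_merge_cosine``; otherwise it seeds a new cluster.
    Consensus peak lists are intensity-weighted merges of the members,
    re-filtered with the windowed top-k rule.  Clusters smaller than
    ``min_cluster_size`` are discarded and counted in the report.

    Per-sample abundance of a feature is the sum of member precursor
    intensities per sample, falling back to member spectral counts for
    members lacking a precursor intensity.

    Returns (features, report) where report counts input, clustered and
    discarded spectra.
    """
    params = params or NetworkingParams()
    if not spectra:
        warnings.warn("cluster_spectra: empty input", stacklevel=2)
        return [], {"n_input_spectra": 0, "n_clustered_spectra": 0, "n_discarded_spectra": 0, "n_discarded_clusters": 0}

    order = sorted(range(len(spectra)), key=lambda i: (spectra[i].precursor_mz, spectra[i].spectrum_id))
    open_clusters: list[_OpenCluster] = []
    closed: list[_OpenCluster] = []

    for idx in order:
        s = spectra[idx]
        # clusters that can no longer match anything (sorted precursors) are closed
        still_open: list[_OpenCluster] = []
        for c in open_clusters:
            if s.precursor_mz - c.consensus_precursor > params.parent_mass_tolerance:
                closed.append(c)
            else:
                still_open.append(c)
        open_clusters = still_open

        best: _OpenCluster | None = None
        best_key: tuple[float, float] | None = None
        for c in open_clusters:
            delta = abs(s.precursor_mz - c.consensus_precursor)
            if delta > params.parent_mass_tolerance:
                continue
            cos, _ = modified_cosine(
                s, c.consensus, params.fragment_tolerance, params.intensity_transform
            )
            if cos < params.cluster_merge_cosine:
                continue
            key = (-cos, delta)
            if best_key is None or key < best_key:
                best, best_key = c, key
        if best is None:
            open_clusters.append(_OpenCluster(s))
        else:
            best.add(s, params)

    closed.extend(open_clusters)
    closed.sort(key=lambda c: c.consensus_precursor)

    features: list[ConsensusFeature] = []
    n_discarded_spectra = 0
    n_discarded_clusters = 0
    width = max(4, len(str(len(closed))))
    for c in closed:
        if len(c.members) < params.min_cluster_size:
            n_discarded_spectra += len(c.members)
            n_discarded_clusters += 1
            continue
        abundance: dict[str, float] = {}
        for m in c.members:
            contrib = m.precursor_intensity if m.precursor_intensity is not None else 1.0
            abundance[m.sample_id] = abundance.get(m.sample_id, 0.0) + float(contrib)
        feature_id = f"F{len(features) + 1:0{width}d}"
        features.append(
            ConsensusFeature(
                feature_id=feature_id,
                consensus_precursor_mz=c.consensus_precursor,
                representative_peaks=c.consensus.peaks,
                member_spectrum_ids=[m.spectrum_id for m in c.members],
                per_sample_abundance=abundance,
            )
        )
    report = {
        "n_input_spectra": len(spectra),
        "n_clustered_spectra": sum(f.member_count for f in features),
        "n_discarded_spectra": n_discarded_spectra,
        "n_discarded_clusters": n_discarded_clusters,
    }
    logger.info(
        "cluster_spectra: %d spectra -> %d features (%d spectra in %d undersized clusters discarded)",
        report["n_input_spectra"], len(features), n_discarded_spectra, n_discarded_clusters,
    )
    return features, report
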