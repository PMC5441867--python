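"""Synthetic MS/MS collections with known ground truth.

The generator emulates the statistical structure of a field-collection
metabolomics survey: molecular *scaffolds* each spawn a family of
structural analogs (precursor and a random subset of fragment peaks shifted
by an exact substituent mass delta, so analog pairs share both direct and
precursor-shifted fragment matches); every planted feature carries a
presence/absence pattern over the collection sites; and each occupied
sample emits several replicate noisy scans of the feature (m/z jitter,
multiplicative intensity noise, spurious low-intensity peaks).  Multiple
labeled datasets with a controlled fraction of shared scaffolds emulate
cross-repository overlap comparisons.

Scaffold base precursors sit on a 70 Da grid so that no two planted
features from different scaffolds fall within the 1 Da parent-mass
tolerance even after the largest analog shift; fragment peaks sit on a
2 Da grid within each spectrum so direct and shifted matches never
collide at the 0.5 Da fragment tolerance.  With all noise terms at zero the
pipeline must therefore recover the planted feature set exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    STUDY_SITES,
    LibraryEntry,
    SampleMetadata,
    Spectrum,
    ValidationError,
    write_mgf,
    write_sample_metadata,
)

#: Approximate regional anchor coordinates per site (decimal degrees);
#: placeholders for map geometry, not survey records.
SITE_ANCHORS: dict[str, tuple[float, float]] = {
    "HI": (21.3, -157.8),
    "NAC": (12.2, -69.0),
    "PAB": (9.3, -82.2),
    "PAC": (7.5, -81.8),
    "PAG": (8.0, -82.0),
    "PAP": (9.55, -79.65),
    "PAL": (5.9, -162.1),
    "PNG": (-5.2, 145.8),
}

_BASE_PRECURSOR_START = 300.0
_BASE_PRECURSOR_SPACING = 70.0  # > 2 * max |analog delta| + parent tolerance
_PEAK_GRID = 2.0  # > 2 * fragment tolerance + analog-shift residue


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_scaffolds: int = 20
    analogs_per_scaffold_mean: float = 3.0
    peaks_per_spectrum: tuple[int, int] = (20, 60)
    analog_delta_menu: tuple[float, ...] = (
        14.01565, -14.01565, 2.01565, -2.01565, 15.99491, 33.98435, -33.98435,
    )
    site_list: tuple[str, ...] = STUDY_SITES
    samples_per_site: int = 2
    site_assignment: list[tuple[int, ...]] | None = None
    site_inclusion_prob: float = 0.2
    replicates_per_feature_per_sample: tuple[int, int] = (3, 8)
    mz_jitter_sd: float = 0.01
    intensity_noise_cv: float = 0.2
    noise_peak_rate: float = 2.0
    library_coverage: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scaffolds < 0 or self.samples_per_site < 0:
            raise ValidationError("counts must be >= 0")
        if self.mz_jitter_sd < 0 or self.intensity_noise_cv < 0 or self.noise_peak_rate < 0:
            raise ValidationError("noise levels must be >= 0")
        if self.mz_jitter_sd >= 0.25:
            raise ValidationError("mz_jitter_sd must stay below half the fragment tolerance")
        if not 0 <= self.library_coverage <= 1:
            raise ValidationError("library_coverage must be in [0, 1]")

    def noise_free(self) -> "GeneratorConfig":
        """Copy of this config with every noise term zeroed."""
        from dataclasses import replace

        return replace(self, mz_jitter_sd=0.0, intensity_noise_cv=0.0, noise_peak_rate=0.0)


@dataclass
class PlantedFeature:
    feature_id: str
    scaffold_id: str
    analog_delta: float  # 0.0 for the scaffold base compound
    precursor_mz: float
    template: np.ndarray  # noise-free peak list
    pattern: tuple[int, ...] | None = None
    per_sample_abundance: dict[str, float] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Complete planted truth: every generated spectrum maps to exactly one
    planted feature or to noise."""

    features: dict[str, PlantedFeature] = field(default_factory=dict)
    spectrum_to_feature: dict[str, str] = field(default_factory=dict)
    library_to_scaffold: dict[str, str] = field(default_factory=dict)
    n_noise_spectra: int = 0

    @property
    def scaffold_of(self) -> dict[str, str]:
        return {fid: f.scaffold_id for fid, f in self.features.items()}

    @property
    def planted_patterns(self) -> dict[str, tuple[int, ...]]:
        return {fid: f.pattern for fid, f in self.features.items() if f.pattern is not None}


# ---------------------------------------------------------------------------
# families of analog spectra
# ---------------------------------------------------------------------------


def _scaffold_template(rng: np.random.Generator, precursor: float, n_peaks: int) -> np.ndarray:
    lo, hi = 100.0, precursor - 25.0
    grid = np.arange(lo, hi, _PEAK_GRID)
    n = min(n_peaks, len(grid))
    mz = np.sort(rng.choice(grid, size=n, replace=False)) + rng.uniform(0.0, 0.4, size=n)
    intensity = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    return np.column_stack([mz, intensity])


def generate_spectral_families(
    config: GeneratorConfig | None = None,
    slot_offset: int = 0,
    slot_stride: int = 1,
) -> tuple[list[Spectrum], GroundTruth]:
    """Generate planted feature spectra grouped into analog families.

    Each scaffold receives a base peak set (grid-spaced m/z, log-normal
    intensities) and a Poisson number of analogs; an analog shifts the
    precursor and an independent Bernoulli(0.5) subset of peaks by its exact
    mass delta, leaving the remainder unshifted, so analog pairs align
    through both matching modes of the modified cosine.  Deterministic for a
    fixed seed.

    ``slot_offset``/``slot_stride`` place scaffold base precursors on the
    70 Da grid at slots offset + s * stride; the multi-dataset generator
    uses them to interleave private scaffolds of different datasets onto
    disjoint slots.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.rng_seed)
    spectra: list[Spectrum] = []
    truth = GroundTruth()
    for s in range(config.n_scaffolds):
        scaffold_id = f"S{s + 1:03d}"
        slot = slot_offset + s * slot_stride
        base_precursor = _BASE_PRECURSOR_START + _BASE_PRECURSOR_SPACING * slot + rng.uniform(0.0, 0.4)
        n_peaks = int(rng.integers(config.peaks_per_spectrum[0], config.peaks_per_spectrum[1] + 1))
        template = _scaffold_template(rng, base_precursor, n_peaks)
        n_analogs = min(int(rng.poisson(config.analogs_per_scaffold_mean)), len(config.analog_delta_menu))
        deltas = [0.0] + list(
            rng.choice(np.asarray(config.analog_delta_menu), size=n_analogs, replace=False)
        )
        for a, delta in enumerate(deltas):
            feature_id = f"{scaffold_id}.A{a}"
            peaks = template.copy()
            if delta != 0.0:
                shifted = rng.random(len(peaks)) < 0.5
                if not shifted.any():
                    shifted[int(rng.integers(len(peaks)))] = True
                peaks[shifted, 0] += delta
            precursor = base_precursor + delta
            planted = PlantedFeature(
                feature_id=feature_id,
                scaffold_id=scaffold_id,
                analog_delta=float(delta),
                precursor_mz=float(precursor),
                template=peaks[np.argsort(peaks[:, 0])],
            )
            truth.features[feature_id] = planted
            spectra.append(
                Spectrum(
                    spectrum_id=feature_id,
                    sample_id="",
                    precursor_mz=planted.precursor_mz,
                    peaks=planted.template,
                )
            )
    return spectra, truth


# ---------------------------------------------------------------------------
# sampled collections
# ---------------------------------------------------------------------------


def _draw_pattern(rng: np.random.Generator, n_sites: int, p: float) -> tuple[int, ...]:
    while True:
        pattern = tuple(int(x) for x in (rng.random(n_sites) < p))
        if any(pattern):
            return pattern


def make_sample_metadata(config: GeneratorConfig, rng: np.random.Generator) -> list[SampleMetadata]:
    records = []
    for site in config.site_list:
        anchor = SITE_ANCHORS.get(site, (0.0, 0.0))
        for k in range(config.samples_per_site):
            records.append(
                SampleMetadata(
                    sample_id=f"{site}_{k + 1:02d}",
                    collection_id=f"C-{site}-{k + 1:02d}",
                    material="crude",
                    site_code=site,
                    raw_site_code=site,
                    latitude=float(np.clip(anchor[0] + rng.normal(0, 0.05), -90, 90)),
                    longitude=float(np.clip(anchor[1] + rng.normal(0, 0.05), -180, 180)),
                    field_taxon=str(rng.choice(["cyanobacterium", "alga"])),
                )
            )
    return records


def generate_collection(
    planted: list[Spectrum],
    truth: GroundTruth,
    config: GeneratorConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[Spectrum], list[SampleMetadata], GroundTruth]:
    """Emit replicate noisy scans of every planted feature across samples.

    Each feature gets a planted site pattern (from ``config.site_assignment``
    cycled over features, or random with ``site_inclusion_prob`` per site);
    each sample at an occupied site emits a random number of replicates with
    m/z jitter, multiplicative log-normal intensity noise and Poisson-many
    spurious low-intensity peaks.  Replicate precursor intensities split the
    planted per-sample abundance exactly, so feature-table column sums
    reconstruct the planted totals when clustering is perfect.  When
    ``out_dir`` is given, spectra and metadata are also written as
    ``collection.mgf`` / ``metadata.tsv``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.rng_seed + 1)
    metadata = make_sample_metadata(config, rng)
    samples_by_site: dict[str, list[str]] = {}
    for m in metadata:
        samples_by_site.setdefault(m.site_code, []).append(m.sample_id)

    n_sites = len(config.site_list)
    sigma_int = (
        math.sqrt(math.log(1.0 + config.intensity_noise_cv**2)) if config.intensity_noise_cv > 0 else 0.0
    )
    spectra: list[Spectrum] = []
    feature_ids = [s.spectrum_id for s in planted]
    for fi, base in enumerate(planted):
        feature = truth.features[base.spectrum_id]
        if config.site_assignment:
            pattern = tuple(config.site_assignment[fi % len(config.site_assignment)])
        else:
            pattern = _draw_pattern(rng, n_sites, config.site_inclusion_prob)
        feature.pattern = pattern
        for site, present in zip(config.site_list, pattern):
            if not present:
                continue
            for sample_id in samples_by_site.get(site, []):
                abundance = float(rng.lognormal(mean=9.0, sigma=1.0))
                feature.per_sample_abundance[sample_id] = abundance
                n_rep = int(
                    rng.integers(
                        config.replicates_per_feature_per_sample[0],
                        config.replicates_per_feature_per_sample[1] + 1,
                    )
                )
                for rep in range(n_rep):
                    peaks = feature.template.copy()
                    if config.mz_jitter_sd > 0:
                        peaks[:, 0] += rng.normal(0.0, config.mz_jitter_sd, size=len(peaks))
                    if sigma_int > 0:
                        peaks[:, 1] *= rng.lognormal(mean=0.0, sigma=sigma_int, size=len(peaks))
                    if config.noise_peak_rate > 0:
                        n_noise = int(rng.poisson(config.noise_peak_rate))
                        if n_noise:
                            noise_mz = rng.uniform(100.0, feature.precursor_mz - 25.0, size=n_noise)
                            noise_int = rng.lognormal(mean=-2.5, sigma=0.5, size=n_noise)
                            peaks = np.vstack([peaks, np.column_stack([noise_mz, noise_int])])
                    spectrum_id = f"{feature.feature_id}.{sample_id}.r{rep + 1}"
                    truth.spectrum_to_feature[spectrum_id] = feature.feature_id
                    spectra.append(
                        Spectrum(
                            spectrum_id=spectrum_id,
                            sample_id=sample_id,
                            precursor_mz=feature.precursor_mz
                            + (rng.normal(0.0, config.mz_jitter_sd) if config.mz_jitter_sd > 0 else 0.0),
                            retention_time=float(rng.uniform(30.0, 600.0)),
                            peaks=peaks,
                            precursor_intensity=abundance / n_rep,
                        )
                    )
    assert set(feature_ids) == set(truth.features)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_mgf(spectra, out_dir / "collection.mgf", seed=config.rng_seed, params=config)
        write_sample_metadata(metadata, out_dir / "metadata.tsv", seed=config.rng_seed, params=config)
    return spectra, metadata, truth


def generate_library(
    planted: list[Spectrum], truth: GroundTruth, config: GeneratorConfig | None = None
) -> list[LibraryEntry]:
    """Named reference entries for a ``library_coverage`` fraction of
    scaffolds (base compound spectrum of each covered scaffold)."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.rng_seed + 2)
    scaffolds = sorted({f.scaffold_id for f in truth.features.values()})
    n_covered = int(round(config.library_coverage * len(scaffolds)))
    covered = sorted(rng.choice(scaffolds, size=n_covered, replace=False)) if n_covered else []
    entries: list[LibraryEntry] = []
    for scaffold_id in covered:
        base = truth.features[f"{scaffold_id}.A0"]
        name = f"compound_{scaffold_id}"
        truth.library_to_scaffold[name] = scaffold_id
        entries.append(
            LibraryEntry(
                compound_name=name,
                spectrum=Spectrum(
                    spectrum_id=f"lib_{scaffold_id}",
                    sample_id="",
                    precursor_mz=base.precursor_mz,
                    peaks=base.template,
                ),
                source_library="synthetic-reference",
            )
        )
    return entries


# ---------------------------------------------------------------------------
# multiple datasets with controlled sharing
# ---------------------------------------------------------------------------


def generate_multidataset(
    labels: list[str],
    shared_fraction: float,
    config: GeneratorConfig | None = None,
) -> tuple[dict[str, tuple[list[Spectrum], GroundTruth]], dict[str, set[str]]]:
    """Labeled datasets in which a ``shared_fraction`` of each dataset's
    scaffolds is common to all datasets (same template, re-jittered copies)
    and the rest are dataset-private.

    Returns ({label: (planted feature spectra, truth)}, truth map
    label -> set of shared feature ids in that dataset).
    """
    if len(labels) < 2:
        raise ValidationError("generate_multidataset requires >= 2 labels")
    if not 0 <= shared_fraction <= 1:
        raise ValidationError("shared_fraction must be in [0, 1]")
    config = config or GeneratorConfig()
    n_shared = int(round(shared_fraction * config.n_scaffolds))

    from dataclasses import replace

    shared_config = replace(config, n_scaffolds=n_shared, rng_seed=config.rng_seed + 101)
    shared_planted, shared_truth = generate_spectral_families(shared_config)

    datasets: dict[str, tuple[list[Spectrum], GroundTruth]] = {}
    shared_ids: dict[str, set[str]] = {}
    for li, label in enumerate(labels):
        # private scaffolds of dataset li occupy grid slots
        # n_shared + li, n_shared + li + n_labels, ... — disjoint across
        # datasets, so private features never co-elute in precursor mass
        private_config = replace(
            config, n_scaffolds=config.n_scaffolds - n_shared, rng_seed=config.rng_seed + 211 + li
        )
        private_planted, private_truth = generate_spectral_families(
            private_config, slot_offset=n_shared + li, slot_stride=len(labels)
        )
        rng = np.random.default_rng(config.rng_seed + 311 + li)
        truth = GroundTruth()
        planted: list[Spectrum] = []
        shared_here: set[str] = set()
        for s in shared_planted:
            f = shared_truth.features[s.spectrum_id]
            fid = f"{label}:{f.feature_id}"
            peaks = f.template.copy()
            if config.mz_jitter_sd > 0:
                peaks[:, 0] += rng.normal(0.0, config.mz_jitter_sd, size=len(peaks))
            truth.features[fid] = PlantedFeature(
                fid, f"shared:{f.scaffold_id}", f.analog_delta, f.precursor_mz, peaks
            )
            planted.append(Spectrum(fid, "", f.precursor_mz, peaks=peaks))
            shared_here.add(fid)
        for s in private_planted:
            f = private_truth.features[s.spectrum_id]
            fid = f"{label}:{f.feature_id}"
            truth.features[fid] = PlantedFeature(
                fid, f"{label}:{f.scaffold_id}", f.analog_delta, f.precursor_mz, f.template
            )
            planted.append(Spectrum(fid, "", f.precursor_mz, peaks=f.template))
        datasets[label] = (planted, truth)
        shared_ids[label] = shared_here
    return datasets, shared_ids
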