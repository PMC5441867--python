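"""Readers, writers and validated configuration for the pipeline's file formats.

Spectra travel as MGF (read and written through :mod:`pyteomics.mgf`),
tabular data as UTF-8 TSV with a ``#`` provenance comment header, networks
as GraphML plus a plain edge-list twin, and configuration as JSON.  Every
file the pipeline emits starts with (or, for JSON/PNG, embeds) a provenance
record: tool version, RNG seed and a short hash of the parameters that
produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

#: The eight principal collection sites of the survey, west Atlantic to
#: Indo-Pacific: Hawaii, Curacao, Panama (Bocas del Toro, Coiba, Gulf of
#: Chiriqui, Portobelo), Palmyra Atoll and Papua New Guinea.
STUDY_SITES: tuple[str, ...] = ("HI", "NAC", "PAB", "PAC", "PAG", "PAP", "PAL", "PNG")


class ChemocartError(Exception):
    """Base class for all package errors."""


class MGFParseError(ChemocartError):
    """A malformed MGF block; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message} (line {line})" if line is not None else message)


class ValidationError(ChemocartError):
    """Input data violates a documented invariant."""


class SchemaError(ChemocartError):
    """A required column or field is missing."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """One MS/MS scan.

    ``peaks`` is an (n, 2) float array of (m/z in Da, intensity in arbitrary
    units), kept sorted ascending by m/z.  ``precursor_intensity`` is the
    optional second PEPMASS value and serves as the abundance proxy when
    features are quantified.
    """

    spectrum_id: str
    sample_id: str
    precursor_mz: float
    charge: int = 1
    retention_time: float | None = None
    peaks: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    precursor_intensity: float | None = None

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if peaks.size and (np.isnan(peaks).any() or (peaks < 0).any()):
            raise ValidationError(f"spectrum {self.spectrum_id}: NaN or negative peak values")
        order = np.argsort(peaks[:, 0], kind="stable")
        self.peaks = peaks[order]
        if not (self.precursor_mz > 0):
            raise ValidationError(f"spectrum {self.spectrum_id}: precursor m/z must be positive")
        if self.charge < 1:
            raise ValidationError(f"spectrum {self.spectrum_id}: charge must be >= 1")
        if self.retention_time is not None and self.retention_time < 0:
            raise ValidationError(f"spectrum {self.spectrum_id}: negative retention time")

    @property
    def n_peaks(self) -> int:
        return int(self.peaks.shape[0])

    def replace_peaks(self, peaks: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with a new peak list (re-validated, re-sorted)."""
        return Spectrum(
            spectrum_id=self.spectrum_id,
            sample_id=self.sample_id,
            precursor_mz=self.precursor_mz,
            charge=self.charge,
            retention_time=self.retention_time,
            peaks=peaks,
            precursor_intensity=self.precursor_intensity,
        )


@dataclass
class SampleMetadata:
    """Collection metadata for one analyzed sample (crude extract or fraction)."""

    sample_id: str
    collection_id: str = ""
    material: str = "crude"  # crude | fraction
    fraction_label: str | None = None
    site_code: str = "OTHER"
    raw_site_code: str | None = None
    latitude: float = 0.0
    longitude: float = 0.0
    field_taxon: str = "other"  # cyanobacterium | alga | other
    collection_date: str | None = None

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90:
            raise ValidationError(f"sample {self.sample_id}: |latitude| > 90")
        if abs(self.longitude) > 180:
            raise ValidationError(f"sample {self.sample_id}: |longitude| > 180")


@dataclass
class LibraryEntry:
    """A named reference spectrum used for dereplication."""

    compound_name: str
    spectrum: Spectrum
    adduct: str = "[M+H]+"
    source_library: str = "reference"

    def __post_init__(self) -> None:
        if not self.compound_name:
            raise ValidationError("library entry with empty compound name")


@dataclass
class PipelineConfig:
    """Aggregated run configuration: one section per pipeline stage plus the seed."""

    networking: "object" = None
    diversity: "object" = None
    geo: "object" = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        from .processing import NetworkingParams
        from .diversity import DiversityParams
        from .geography import GeoParams

        if self.networking is None:
            self.networking = NetworkingParams()
        if self.diversity is None:
            self.diversity = DiversityParams(rng_seed=self.rng_seed)
        if self.geo is None:
            self.geo = GeoParams()

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        from .processing import NetworkingParams
        from .diversity import DiversityParams
        from .geography import GeoParams

        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        raw.pop("_provenance", None)
        return cls(
            networking=NetworkingParams(**raw.get("networking", {})),
            diversity=DiversityParams(**raw.get("diversity", {})),
            geo=GeoParams(**raw.get("geo", {})),
            rng_seed=int(raw.get("rng_seed", 0)),
        )

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "networking": asdict(self.networking),
            "diversity": asdict(self.diversity),
            "geo": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self.geo).items()},
            "rng_seed": self.rng_seed,
            "_provenance": provenance_record(self.rng_seed, self),
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        return path


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------


def params_hash(params: object) -> str:
    """Short stable hash of any (nested) dataclass/dict/sequence parameter bundle."""

    def _plain(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            return {k: _plain(v) for k, v in asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): _plain(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    blob = json.dumps(_plain(params), sort_keys=True).encode()
    return hashlib.md5(blob).hexdigest()[:8]


def provenance_line(seed: int | None = None, params: object = None) -> str:
    from . import __version__

    return f"chemocart {__version__} | seed={seed} | params={params_hash(params)}"


def provenance_record(seed: int | None = None, params: object = None) -> dict:
    from . import __version__

    return {"tool": "chemocart", "version": __version__, "seed": seed, "params_hash": params_hash(params)}


def read_provenance(path: str | Path) -> str | None:
    """Return the provenance string embedded in a chemocart output file, if any."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        rec = json.loads(path.read_text(encoding="utf-8")).get("_provenance")
        if rec is None:
            return None
        return f"{rec['tool']} {rec['version']} | seed={rec['seed']} | params={rec['params_hash']}"
    if suffix == ".png":
        from PIL import Image

        with Image.open(path) as img:
            return img.text.get("provenance")
    if suffix == ".graphml":
        text = path.read_text(encoding="utf-8")
        start = text.find("<!--")
        if start == -1:
            return None
        return text[start + 4 : text.find("-->")].strip()
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        return first.lstrip("# ").strip()
    return None


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------


def _validate_mgf_lines(path: Path) -> None:
    """Pre-flight scan catching the malformations pyteomics reports opaquely."""
    in_block = False
    has_pepmass = False
    block_start = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped[0] in "#;!/":
                continue
            if stripped == "BEGIN IONS":
                in_block, has_pepmass, block_start = True, False, lineno
            elif stripped == "END IONS":
                if not has_pepmass:
                    raise MGFParseError("ion block without PEPMASS", line=block_start)
                in_block = False
            elif in_block:
                if "=" in stripped:
                    if stripped.upper().startswith("PEPMASS="):
                        has_pepmass = True
                else:
                    fields = stripped.split()
                    try:
                        [float(x) for x in fields[:2]]
                    except ValueError:
                        raise MGFParseError("non-numeric peak line", line=lineno) from None
        if in_block:
            raise MGFParseError("unterminated ion block", line=block_start)


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    One spectrum per BEGIN IONS/END IONS block.  Charge defaults to 1+ when
    absent (the pipeline assumes singly protonated/sodiated species
    throughout) and the assumption is logged.  The optional SAMPLE= key
    carries the sample of origin; TITLE carries the spectrum id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_mgf_lines(path)
    spectra: list[Spectrum] = []
    n_defaulted = 0
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise MGFParseError(f"block {i}: missing PEPMASS")
            precursor_mz = float(pepmass[0])
            precursor_intensity = (
                float(pepmass[1]) if len(pepmass) > 1 and pepmass[1] is not None else None
            )
            charge_field = params.get("charge")
            if charge_field:
                charge = abs(int(charge_field[0]))
            else:
                charge = 1
                n_defaulted += 1
            rt = params.get("rtinseconds")
            peaks = np.column_stack([entry["m/z array"], entry["intensity array"]])
            spectra.append(
                Spectrum(
                    spectrum_id=str(params.get("title", f"scan_{i}")),
                    sample_id=str(params.get("sample", "")),
                    precursor_mz=precursor_mz,
                    charge=charge,
                    retention_time=float(rt) if rt is not None else None,
                    peaks=peaks,
                    precursor_intensity=precursor_intensity,
                )
            )
    if n_defaulted:
        logger.info("read_mgf(%s): %d spectra without CHARGE, assumed 1+", path, n_defaulted)
    if not spectra:
        warnings.warn(f"{path}: no ion blocks found", stacklevel=2)
    return spectra


def write_mgf(
    spectra: Iterable[Spectrum], path: str | Path, seed: int | None = None, params: object = None
) -> Path:
    """Write spectra to MGF deterministically: input order, peaks ascending,
    fixed 6-decimal formatting, a provenance comment line first."""
    path = Path(path)
    entries = []
    for s in spectra:
        block_params: dict = {"title": s.spectrum_id}
        if s.precursor_intensity is not None:
            block_params["pepmass"] = f"{s.precursor_mz:.6f} {s.precursor_intensity:.6f}"
        else:
            block_params["pepmass"] = f"{s.precursor_mz:.6f}"
        if s.retention_time is not None:
            block_params["rtinseconds"] = f"{s.retention_time:.3f}"
        block_params["charge"] = f"{s.charge}+"
        if s.sample_id:
            block_params["sample"] = s.sample_id
        entries.append(
            {
                "params": block_params,
                "m/z array": s.peaks[:, 0],
                "intensity array": s.peaks[:, 1],
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {provenance_line(seed, params)}\n")
        _mgf.write(
            entries,
            output=fh,
            key_order=["title", "pepmass", "rtinseconds", "charge", "sample"],
            fragment_format="%.6f %.6f",
            write_charges=False,
        )
    return path


def read_library_mgf(path: str | Path, source_library: str = "reference") -> list[LibraryEntry]:
    """Read a reference spectral library from MGF; the NAME= (falling back to
    TITLE=) key of each block carries the compound name."""
    path = Path(path)
    _validate_mgf_lines(path)
    entries: list[LibraryEntry] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for i, raw in enumerate(reader):
            params = raw["params"]
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise MGFParseError(f"library block {i}: missing PEPMASS")
            name = str(params.get("name", params.get("title", "")))
            spectrum = Spectrum(
                spectrum_id=str(params.get("title", f"lib_{i}")),
                sample_id="",
                precursor_mz=float(pepmass[0]),
                charge=abs(int(params["charge"][0])) if params.get("charge") else 1,
                peaks=np.column_stack([raw["m/z array"], raw["intensity array"]]),
            )
            entries.append(
                LibraryEntry(
                    compound_name=name,
                    spectrum=spectrum,
                    adduct=str(params.get("adduct", "[M+H]+")),
                    source_library=source_library,
                )
            )
    return entries


def write_library_mgf(
    entries: Iterable[LibraryEntry], path: str | Path, seed: int | None = None, params: object = None
) -> Path:
    path = Path(path)
    blocks = []
    for e in entries:
        s = e.spectrum
        blocks.append(
            {
                "params": {
                    "title": s.spectrum_id,
                    "pepmass": f"{s.precursor_mz:.6f}",
                    "charge": f"{s.charge}+",
                    "name": e.compound_name,
                    "adduct": e.adduct,
                },
                "m/z array": s.peaks[:, 0],
                "intensity array": s.peaks[:, 1],
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {provenance_line(seed, params)}\n")
        _mgf.write(
            blocks,
            output=fh,
            key_order=["title", "pepmass", "charge", "name", "adduct"],
            fragment_format="%.6f %.6f",
            write_charges=False,
        )
    return path


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

_REQUIRED_METADATA_COLUMNS = ("sample_id", "site_code", "latitude", "longitude")


def read_sample_metadata(
    path: str | Path, sites: Sequence[str] = STUDY_SITES
) -> list[SampleMetadata]:
    """Read the tab-separated sample metadata table.

    Site codes are uppercased on read; codes outside ``sites`` are folded
    into OTHER (original code preserved in ``raw_site_code``) with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    missing = [c for c in _REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata table missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise ValidationError(f"duplicate sample_id values: {dupes}")
    known = {s.upper() for s in sites}
    records: list[SampleMetadata] = []
    n_other = 0
    for row in df.itertuples(index=False):
        raw_site = str(row.site_code).strip().upper()
        site = raw_site if raw_site in known else "OTHER"
        if site == "OTHER" and raw_site not in ("OTHER", "NAN", ""):
            n_other += 1
        records.append(
            SampleMetadata(
                sample_id=str(row.sample_id),
                collection_id=str(getattr(row, "collection_id", "")),
                material=str(getattr(row, "material", "crude")),
                fraction_label=(str(row.fraction_label) if getattr(row, "fraction_label", None) not in (None, np.nan) else None),
                site_code=site,
                raw_site_code=raw_site,
                latitude=float(row.latitude),
                longitude=float(row.longitude),
                field_taxon=str(getattr(row, "field_taxon", "other")),
                collection_date=(str(row.collection_date) if getattr(row, "collection_date", None) not in (None, np.nan) else None),
            )
        )
    if n_other:
        warnings.warn(f"{n_other} samples with unknown site codes folded into OTHER", stacklevel=2)
    return records


def write_sample_metadata(
    records: Iterable[SampleMetadata], path: str | Path, seed: int | None = None, params: object = None
) -> Path:
    df = pd.DataFrame([asdict(r) for r in records])
    return write_tsv(df, path, seed=seed, params=params)


def write_tsv(
    df: pd.DataFrame, path: str | Path, seed: int | None = None, params: object = None, index: bool = False
) -> Path:
    """Write a TSV with the standard provenance comment header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {provenance_line(seed, params)}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# network serialization
# ---------------------------------------------------------------------------


def write_network_graphml(
    network, path: str | Path, seed: int | None = None, params: object = None
) -> Path:
    """Serialize a molecular network to GraphML plus an edge-list TSV twin.

    Node attributes: precursor m/z, member spectrum count, family id,
    library match name, per-site presence counts.  Edge attributes: cosine,
    matched peak count, precursor mass difference.
    """
    path = Path(path)
    graph = network.to_graph() if hasattr(network, "to_graph") else network
    nx.write_graphml(graph, path, named_key_ids=True)
    text = path.read_text(encoding="utf-8")
    lines = text.split("\n")
    lines.insert(1, f"<!-- {provenance_line(seed, params)} -->")
    path.write_text("\n".join(lines), encoding="utf-8")

    rows = [
        {"feature_a": a, "feature_b": b, **{k: v for k, v in data.items()}}
        for a, b, data in sorted(graph.edges(data=True))
    ]
    edge_df = pd.DataFrame(rows, columns=["feature_a", "feature_b", "cosine", "matched_peaks", "precursor_delta"])
    write_tsv(edge_df, path.with_suffix(".edges.tsv"), seed=seed, params=params)
    return path


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
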