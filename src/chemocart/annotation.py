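"""Mass and formula arithmetic for MS-based structure deduction.

The utilities here cover the annotation chain used to dereplicate natural
products and to deduce new analogs from fragmentation alone: monoisotopic
masses and adduct m/z values at ppm accuracy, ring-double-bond equivalents,
neutral-loss sequencing of peptide/depsipeptide fragment series against a
residue-mass dictionary, pairwise analog annotation from exact mass deltas
of common substituent changes, and chlorine counting from the M/M+2/M+4
isotope envelope.

Residue and delta dictionaries are TSV data files, so nonproteinogenic
units (Hiv, Dhoya, ...) can be extended without code changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ValidationError

# IUPAC monoisotopic atomic masses, Da, 6 decimals.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.007825,
    "C": 12.000000,
    "N": 14.003074,
    "O": 15.994915,
    "F": 18.998403,
    "Na": 22.989770,
    "P": 30.973762,
    "S": 31.972071,
    "Cl": 34.968853,
    "K": 38.963706,
    "Br": 78.918338,
    "I": 126.904473,
}
ELECTRON_MASS = 0.000549
#: natural abundance of 35Cl / 37Cl used for isotope-envelope fitting
CL35_ABUNDANCE = 0.7577
CL37_ABUNDANCE = 0.2423
#: spacing of the chlorine isotope envelope (37Cl - 35Cl)
CL_SPACING = 1.99705

_HALOGENS = ("F", "Cl", "Br", "I")
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass
class FormulaComposition:
    """Element -> count map plus net charge."""

    elements: dict[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        self.elements = {el: int(n) for el, n in self.elements.items() if int(n) != 0}
        if not self.elements:
            raise ValidationError("formula must contain at least one element")
        negative = [el for el, n in self.elements.items() if n < 0]
        if negative:
            raise ValidationError(f"negative element counts: {negative}")

    @classmethod
    def from_string(cls, formula: str, charge: int = 0) -> "FormulaComposition":
        """Parse a Hill-style formula string such as ``C28H45N3O7``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos:
                raise ValidationError(f"cannot parse formula {formula!r} at position {pos}")
            pos = match.end()
            el, num = match.group(1), match.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(formula):
            raise ValidationError(f"cannot parse formula {formula!r} at position {pos}")
        return cls(elements=counts, charge=charge)

    def __add__(self, other: "FormulaComposition") -> "FormulaComposition":
        merged = dict(self.elements)
        for el, n in other.elements.items():
            merged[el] = merged.get(el, 0) + n
        return FormulaComposition(elements=merged, charge=self.charge + other.charge)


def monoisotopic_mass(f: FormulaComposition) -> float:
    """Sum of element monoisotopic masses; charged species subtract one
    electron mass per positive charge (add per negative)."""
    unknown = sorted(set(f.elements) - set(ATOMIC_MASS))
    if unknown:
        raise ValidationError(f"unknown elements: {unknown}")
    mass = sum(ATOMIC_MASS[el] * n for el, n in f.elements.items())
    return mass - ELECTRON_MASS * f.charge


#: adduct -> (list of atoms gained, charge)
_ADDUCTS: dict[str, tuple[list[str], int]] = {
    "[M+H]+": (["H"], 1),
    "[M+Na]+": (["Na"], 1),
    "[M+K]+": (["K"], 1),
    "[M+2H]2+": (["H", "H"], 2),
}


def adduct_mz(f: FormulaComposition, adduct: str = "[M+H]+") -> float:
    """m/z of an adduct ion of the neutral molecule M:
    (M + sum of adduct atom masses - z * electron) / z."""
    if f.charge != 0:
        raise ValidationError("adduct_mz expects a neutral formula")
    if adduct not in _ADDUCTS:
        raise ValidationError(f"unsupported adduct {adduct!r}; known: {sorted(_ADDUCTS)}")
    atoms, z = _ADDUCTS[adduct]
    m = monoisotopic_mass(f)
    return (m + sum(ATOMIC_MASS[a] for a in atoms) - z * ELECTRON_MASS) / z


def rdbe(f: FormulaComposition) -> float:
    """Ring-double-bond equivalents (degrees of unsaturation):
    C - H/2 + N/2 + 1, with halogens counted like hydrogen and O/S ignored."""
    c = f.elements.get("C", 0)
    h = f.elements.get("H", 0) + sum(f.elements.get(x, 0) for x in _HALOGENS)
    n = f.elements.get("N", 0)
    return c - h / 2 + n / 2 + 1


def ppm_error(observed: float, theoretical: float) -> float:
    """|observed - theoretical| / theoretical * 1e6."""
    if observed <= 0 or theoretical <= 0:
        raise ValidationError("ppm_error requires positive masses")
    return abs(observed - theoretical) / theoretical * 1e6


# ---------------------------------------------------------------------------
# residue / delta dictionaries
# ---------------------------------------------------------------------------


def _load_dict(resource: str, path: str | Path | None, value_col: str) -> dict[str, float]:
    if path is None:
        with resources.files("chemocart.data").joinpath(resource).open("r") as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    if df["name"].duplicated().any():
        raise ValidationError(f"duplicate names in {resource}")
    return dict(zip(df["name"], df[value_col].astype(float)))


def load_residue_dictionary(path: str | Path | None = None) -> dict[str, float]:
    """name -> monoisotopic residue mass (Da). Masses must be positive."""
    d = _load_dict("residues.tsv", path, "mass")
    if any(v <= 0 for v in d.values()):
        raise ValidationError("residue masses must be positive")
    return d


def load_delta_dictionary(path: str | Path | None = None) -> dict[str, float]:
    """name -> exact mass delta (Da) of a substituent change. Deltas non-zero."""
    d = _load_dict("deltas.tsv", path, "delta")
    if any(v == 0 for v in d.values()):
        raise ValidationError("deltas must be non-zero")
    return d


# ---------------------------------------------------------------------------
# neutral-loss sequencing
# ---------------------------------------------------------------------------


@dataclass
class LossStep:
    from_mz: float
    to_mz: float
    loss_mass: float
    assignment: str  # residue name(s) joined by '|', or '?' when unmatched
    matched: bool
    deviation: float | None = None


@dataclass
class SequenceAnnotation:
    steps: list[LossStep] = field(default_factory=list)
    terminal_mz: float = 0.0

    @property
    def residues(self) -> list[str]:
        return [s.assignment for s in self.steps]

    @property
    def fully_matched(self) -> bool:
        return all(s.matched for s in self.steps)

    def sequence_string(self) -> str:
        parts = self.residues + [f"[terminal {self.terminal_mz:.4f}]"]
        return "-".join(parts)


def sequence_from_losses(
    fragment_series: list[float],
    residues: dict[str, float] | None = None,
    tolerance: float = 0.02,
) -> SequenceAnnotation:
    """Annotate a descending fragment-ion m/z series by its neutral losses.

    Each successive difference is matched against the residue dictionary
    within ``tolerance``; the closest residue wins, and residues tied for
    closest (isobaric units such as Leu/Ile or Ala vs N-Me-Gly) are reported
    jointly.  Differences matching nothing are flagged ``?`` with their mass
    — never silently guessed.  The final fragment mass is reported verbatim
    as the terminal residue candidate (any discrepancy with a theoretical
    ion mass is left to the caller to interpret).
    """
    if residues is None:
        residues = load_residue_dictionary()
    if tolerance <= 0:
        raise ValidationError("tolerance must be > 0")
    series = [float(x) for x in fragment_series]
    if len(series) < 1:
        raise ValidationError("fragment series is empty")
    if any(b >= a for a, b in zip(series, series[1:])):
        raise ValidationError("fragment series must be strictly descending")
    steps: list[LossStep] = []
    for a, b in zip(series, series[1:]):
        loss = a - b
        deviations = {name: abs(loss - mass) for name, mass in residues.items()}
        within = {name: dev for name, dev in deviations.items() if dev <= tolerance}
        if within:
            best = min(within.values())
            names = sorted(name for name, dev in within.items() if dev <= best + 1e-9)
            steps.append(LossStep(a, b, loss, "|".join(names), True, best))
        else:
            steps.append(LossStep(a, b, loss, f"?({loss:.4f})", False, None))
    return SequenceAnnotation(steps=steps, terminal_mz=series[-1])


# ---------------------------------------------------------------------------
# analog deltas
# ---------------------------------------------------------------------------


def annotate_analog_deltas(
    precursors: dict[str, float],
    deltas: dict[str, float] | None = None,
    tolerance: float = 0.02,
) -> pd.DataFrame:
    """Test all pairwise precursor mass differences within a molecular family
    against the delta dictionary.

    ``precursors`` maps feature id -> precursor m/z.  For each ordered pair
    (lighter, heavier) every dictionary entry whose positive delta magnitude
    matches the observed difference within ``tolerance`` is reported; a pair
    may carry several consistent annotations.
    """
    if deltas is None:
        deltas = load_delta_dictionary()
    if len(precursors) < 2:
        raise ValidationError("annotate_analog_deltas requires >= 2 features")
    items = sorted(precursors.items(), key=lambda kv: (kv[1], kv[0]))
    rows = []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            (fa, pa), (fb, pb) = items[i], items[j]
            observed = pb - pa
            for name, delta in sorted(deltas.items()):
                if abs(observed - abs(delta)) <= tolerance:
                    rows.append(
                        {
                            "feature_light": fa,
                            "feature_heavy": fb,
                            "observed_delta": observed,
                            "delta_name": name,
                            "dictionary_delta": delta,
                            "deviation": abs(observed - abs(delta)),
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["feature_light", "feature_heavy", "observed_delta", "delta_name", "dictionary_delta", "deviation"],
    )


# ---------------------------------------------------------------------------
# chlorine isotope scoring
# ---------------------------------------------------------------------------


def chlorine_envelope(n_cl: int) -> np.ndarray:
    """Theoretical M, M+2, ... M+2n intensity pattern for n chlorines:
    the binomial expansion of (p35 + p37)^n, normalized to sum 1."""
    from math import comb

    return np.array(
        [comb(n_cl, k) * CL35_ABUNDANCE ** (n_cl - k) * CL37_ABUNDANCE**k for k in range(n_cl + 1)]
    )


def chlorine_isotope_score(
    envelope: list[tuple[float, float]], max_cl: int = 5
) -> tuple[int, float]:
    """Estimate the chlorine count from an M/M+2/M+4/... isotope envelope.

    ``envelope`` is a list of (m/z, intensity) peaks spaced about 1.997 Da
    apart.  Observed intensities are normalized to sum 1 and compared with
    the binomial (0.7577/0.2423)^n pattern for each n in 0..max_cl; the best
    n minimizes the squared error between the two probability vectors, and
    the returned score 1 - err/2 lies in [0, 1] (1 is a perfect fit).
    Ties resolve to the smaller n.
    """
    if not envelope:
        raise ValidationError("empty isotope envelope")
    intensities = np.array([float(i) for _, i in envelope], dtype=float)
    if (intensities < 0).any() or intensities.sum() <= 0:
        raise ValidationError("envelope intensities must be non-negative with positive sum")
    if len(envelope) == 1:
        return 0, 1.0
    obs = intensities / intensities.sum()
    best_n, best_err = 0, np.inf
    for n in range(max_cl + 1):
        theo = chlorine_envelope(n)
        size = max(len(obs), len(theo))
        o = np.pad(obs, (0, size - len(obs)))
        t = np.pad(theo, (0, size - len(theo)))
        err = float(((o - t) ** 2).sum())
        if err < best_err - 1e-12:
            best_n, best_err = n, err
    return best_n, float(1.0 - best_err / 2.0)
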