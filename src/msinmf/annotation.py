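"""Adduct-mass annotation of negative-mode lipid features.

Formula parsing, monoisotopic mass and theoretical adduct m/z computation,
ppm errors, the single-chlorine M+2 isotope check, major-peak listing,
metabolite deduplication, and tissue/serum cross-referencing.

All masses are in daltons (Da) on the unified atomic mass scale; m/z values
are in thomson (Th) for singly charged anions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "CL35_MASS",
    "CL_M2_SPACING",
    "CL_M2_RATIO",
    "ElementalFormula",
    "AdductSpec",
    "AnnotatedFeature",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "theoretical_mz",
    "ion_to_neutral",
    "ppm_error",
    "annotate",
    "chlorine_isotope_ratio",
    "list_major_peaks",
    "dedupe_metabolites",
    "cross_reference",
    "load_reference_features",
]

#: Monoisotopic atomic masses (Da) of the supported elements.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.00054858
#: Mass removed by deprotonation: m(1H) - m(e-).
PROTON_MASS = 1.00727646
CL35_MASS = MONOISOTOPIC_MASS["Cl"]
#: 37Cl - 35Cl mass difference (Th, singly charged).
CL_M2_SPACING = 1.99705
#: Isotopic abundance ratio 37Cl/35Cl (24.22 / 75.77).
CL_M2_RATIO = 0.3196
#: Acceptance band for the one-chlorine verdict: CL_M2_RATIO +/- 25 %.
CL_RATIO_BAND = (0.24, 0.40)


class FormulaError(ValueError):
    """Raised for malformed or unsupported elemental formulas."""


class AdductError(ValueError):
    """Raised for unsupported adducts or incompatible formula/adduct pairs."""


# ---------------------------------------------------------------------------
# elemental formulas
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map for a neutral molecule or a bare ion skeleton."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        for element, n in counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unsupported element {element!r}")
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise FormulaError(f"invalid count {n!r} for element {element!r}")
        counts = {el: int(n) for el, n in counts.items() if n > 0}
        if not counts:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "counts", counts)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def add(self, element: str, n: int = 1) -> "ElementalFormula":
        counts = dict(self.counts)
        counts[element] = counts.get(element, 0) + n
        return ElementalFormula(counts)

    def remove(self, element: str, n: int = 1) -> "ElementalFormula":
        if self[element] < n:
            raise FormulaError(
                f"cannot remove {n} {element} from {self}: only {self[element]} present"
            )
        return self.add(element, -n)

    def merge(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return ElementalFormula(counts)

    def __str__(self) -> str:
        # Hill-ish ordering: C, H, then alphabetical.
        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(f"{el}{n if n > 1 else ''}" for el, n in ((e, self.counts[e]) for e in order))


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a molecular formula such as ``"C33H36N4O6"``.

    Also accepts the underscore-delimited dialect ``"C_33_H_36_N_4_O_6"``
    used in published tables (underscores are ignored).
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    cleaned = text.strip().replace("_", "")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN.match(cleaned, pos)
        if m is None or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(
                f"unknown element {element!r} in {text!r} at position {pos}"
            )
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts)


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass (Da) of a formula: sum of per-element masses."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return float(sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts.items()))


# ---------------------------------------------------------------------------
# adducts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdductSpec:
    """A singly charged negative-mode adduct.

    ``mass_delta`` is added to the neutral monoisotopic mass to obtain the
    ion m/z (charge magnitude 1, electron mass included).
    """

    name: str
    mass_delta: float
    charge: int = -1


ADDUCTS: Mapping[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS),
    "[M+Cl]-": AdductSpec("[M+Cl]-", CL35_MASS + ELECTRON_MASS),
}


def _resolve_adduct(adduct: AdductSpec | str) -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    key = adduct.strip().replace("^", "").replace(" ", "")
    if key not in ADDUCTS:
        raise AdductError(f"unsupported adduct {adduct!r}; supported: {sorted(ADDUCTS)}")
    return ADDUCTS[key]


def theoretical_mz(neutral_formula: ElementalFormula | str, adduct: AdductSpec | str) -> float:
    """Theoretical m/z (Th) of a singly charged negative adduct ion.

    The input formula is the NEUTRAL molecule; the adduct delta (proton
    removal or chloride attachment, electron mass included) is applied here.
    Full precision is returned; round to 4 decimals for reporting.
    """
    if isinstance(neutral_formula, str):
        neutral_formula = parse_formula(neutral_formula)
    adduct = _resolve_adduct(adduct)
    if adduct.name == "[M-H]-" and neutral_formula["H"] < 1:
        raise AdductError(f"[M-H]- requires at least one H, got {neutral_formula}")
    return monoisotopic_mass(neutral_formula) + adduct.mass_delta


def ion_to_neutral(formula: ElementalFormula | str, adduct: AdductSpec | str) -> ElementalFormula:
    """Convert a published ION formula to the neutral molecule.

    [M-H]- ion formulas gain one H; [M+Cl]- ion formulas lose their chlorine.
    A [M+Cl]- formula without chlorine is assumed to be neutral already
    (published tables mix the two conventions).
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    adduct = _resolve_adduct(adduct)
    if adduct.name == "[M-H]-":
        return formula.add("H", 1)
    if formula["Cl"] >= 1:
        return formula.remove("Cl", 1)
    return formula


def ppm_error(exp_mz: float, theo_mz: float) -> float:
    """Relative mass error |exp - theo| / theo in ppm, rounded to 1 decimal.

    Computed against the full-precision theoretical m/z (not the 4-decimal
    display value); this reproduces published values for the benchmark rows.
    """
    if theo_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    return round(abs(exp_mz - theo_mz) / theo_mz * 1e6, 1)


# ---------------------------------------------------------------------------
# annotated features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatedFeature:
    """One experimentally observed ion with its tentative identity."""

    exp_mz: float
    neutral_formula: ElementalFormula
    adduct: AdductSpec
    identity: str
    theo_mz: float = field(default=float("nan"))
    ppm: float = field(default=float("nan"))
    serum_overlap: bool = False
    serum_delta_mz: float | None = None

    @property
    def theo_mz_rounded(self) -> float:
        return round(self.theo_mz, 4)


def annotate(
    exp_mz: float,
    formula: ElementalFormula | str,
    adduct: AdductSpec | str,
    identity: str = "",
    formula_is_ion: bool = True,
) -> AnnotatedFeature:
    """Build an :class:`AnnotatedFeature` from an observed m/z and a formula."""
    adduct = _resolve_adduct(adduct)
    if isinstance(formula, str):
        formula = parse_formula(formula)
    neutral = ion_to_neutral(formula, adduct) if formula_is_ion else formula
    theo = theoretical_mz(neutral, adduct)
    return AnnotatedFeature(
        exp_mz=float(exp_mz),
        neutral_formula=neutral,
        adduct=adduct,
        identity=identity,
        theo_mz=theo,
        ppm=ppm_error(exp_mz, theo),
    )


# ---------------------------------------------------------------------------
# spectra-level checks
# ---------------------------------------------------------------------------

def _window_intensity(spectrum: np.ndarray, centers: np.ndarray, mz: float, tol: float) -> float:
    mask = (centers >= mz - tol) & (centers <= mz + tol)
    return float(np.asarray(spectrum)[mask].sum())


def chlorine_isotope_ratio(
    spectrum: np.ndarray,
    centers: np.ndarray,
    base_mz: float,
    tol: float = 0.01,
) -> tuple[float, bool]:
    """M+2/M intensity ratio at ``base_mz`` and the one-chlorine verdict.

    The monoisotopic (all-35Cl) intensity is summed in ``base_mz +/- tol``;
    the M+2 isotopologue in ``base_mz + 1.99705 +/- tol``.  The verdict is
    positive when the ratio falls within 0.3196 +/- 25 % — the ~3:1 pattern
    expected for a single chlorine atom.
    """
    spectrum = np.asarray(spectrum, dtype=float).ravel()
    centers = np.asarray(centers, dtype=float).ravel()
    if spectrum.shape != centers.shape:
        raise ValueError("spectrum and m/z centers must have the same length")
    base = _window_intensity(spectrum, centers, base_mz, tol)
    if base <= 0:
        raise ValueError(f"no base peak found within {tol} of m/z {base_mz}")
    m2 = _window_intensity(spectrum, centers, base_mz + CL_M2_SPACING, tol)
    ratio = m2 / base
    verdict = CL_RATIO_BAND[0] <= ratio <= CL_RATIO_BAND[1]
    return ratio, verdict


def list_major_peaks(
    spectrum: np.ndarray,
    centers: np.ndarray,
    threshold_percent: float = 5.0,
) -> list[tuple[float, float]]:
    """Local maxima at >= ``threshold_percent`` of the base peak.

    Neighbouring nonzero channels within one local bin width are grouped
    into a single peak (the group's intensity-weighted centroid, summed
    intensity).  Returns ``(mz, relative_percent)`` sorted by m/z.
    """
    spectrum = np.asarray(spectrum, dtype=float).ravel()
    centers = np.asarray(centers, dtype=float).ravel()
    if spectrum.shape != centers.shape:
        raise ValueError("spectrum and m/z centers must have the same length")
    if not np.any(spectrum > 0):
        raise ValueError("all-zero spectrum has no peaks")
    nz = np.flatnonzero(spectrum > 0)
    # group runs of nonzero channels separated by <= ~1 bin width
    groups: list[list[int]] = [[nz[0]]]
    for idx in nz[1:]:
        prev = groups[-1][-1]
        gap = centers[idx] - centers[prev]
        local_width = centers[prev + 1] - centers[prev] if prev + 1 < len(centers) else gap
        if gap <= 1.5 * local_width and idx - prev <= 2:
            groups[-1].append(idx)
        else:
            groups.append([idx])
    peaks = []
    for g in groups:
        inten = spectrum[g]
        total = inten.sum()
        mz = float(np.dot(centers[g], inten) / total)
        peaks.append((mz, float(total)))
    base = max(p[1] for p in peaks)
    out = [
        (mz, 100.0 * total / base)
        for mz, total in peaks
        if 100.0 * total / base >= threshold_percent
    ]
    return sorted(out)


# ---------------------------------------------------------------------------
# bookkeeping
# ---------------------------------------------------------------------------

def dedupe_metabolites(
    features: Sequence[AnnotatedFeature],
) -> tuple[int, int, list[tuple[str, list[AnnotatedFeature]]]]:
    """Group ions by identity label; returns (n_ions, n_metabolites, groups).

    A multi-candidate label such as ``"LPE(O-18:1), LPE(P-18:0)"`` counts as
    one group: the label is the unit of identity, not its components.
    """
    groups: dict[str, list[AnnotatedFeature]] = {}
    for feat in features:
        groups.setdefault(feat.identity, []).append(feat)
    ordered = sorted(groups.items(), key=lambda kv: min(f.exp_mz for f in kv[1]))
    return len(features), len(groups), ordered


def cross_reference(
    tissue: Sequence[AnnotatedFeature],
    serum_mz: Iterable[float],
    tol_mz: float = 0.005,
) -> list[AnnotatedFeature]:
    """Flag tissue features whose experimental m/z matches a serum feature.

    A match is any serum m/z within ``+/- tol_mz`` of the tissue feature's
    experimental m/z; the smallest |delta| is recorded.  Returns new feature
    objects with ``serum_overlap``/``serum_delta_mz`` set.
    """
    if tol_mz <= 0:
        raise ValueError("tolerance must be positive")
    serum = np.sort(np.asarray(list(serum_mz), dtype=float))
    out = []
    for feat in tissue:
        if serum.size:
            deltas = serum - feat.exp_mz
            best = int(np.argmin(np.abs(deltas)))
            if abs(deltas[best]) <= tol_mz:
                out.append(replace(feat, serum_overlap=True, serum_delta_mz=float(deltas[best])))
                continue
        out.append(replace(feat, serum_overlap=False, serum_delta_mz=None))
    return out


# ---------------------------------------------------------------------------
# reference fixture
# ---------------------------------------------------------------------------

def load_reference_features(path=None) -> pd.DataFrame:
    """Load the shipped reference feature table (or a compatible CSV).

    Columns: exp_mz, formula (as printed, underscore dialect), theo_mz_printed,
    ppm_printed, adduct, identity, serum_overlap, formula_is_ion, note.
    """
    if path is None:
        with resources.files("msinmf.data").joinpath("reference_features.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    df["serum_overlap"] = df["serum_overlap"].astype(bool)
    df["formula_is_ion"] = df["formula_is_ion"].astype(bool)
    return df


def annotate_reference_table(df: pd.DataFrame | None = None) -> list[AnnotatedFeature]:
    """Run the annotation engine over a reference table's rows."""
    if df is None:
        df = load_reference_features()
    feats = []
    for row in df.itertuples(index=False):
        feat = annotate(
            exp_mz=row.exp_mz,
            formula=row.formula,
            adduct=row.adduct,
            identity=row.identity,
            formula_is_ion=row.formula_is_ion,
        )
        feats.append(replace(feat, serum_overlap=bool(row.serum_overlap)))
    return feats
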