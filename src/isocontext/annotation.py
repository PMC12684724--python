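"""Candidate compound identities for LC-MS features.

Three annotation routes, mirroring common practice in untargeted
metabolomics:

* **MS1 accurate mass** — match each feature's m/z against adduct m/z
  values computed from a user-supplied compound/formula table within a
  ppm window.
* **Reference standards** — match m/z *and* retention time against
  in-house standards measured on the same instrument.
* **MS2 spectra** — align fragmentation spectra to features by precursor
  m/z and retention time, then score them against a spectral library
  with a square-root-intensity greedy cosine.

Annotation is candidate generation: a feature may carry several
candidates and no automatic best-hit collapse is performed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

from .errors import ConfigurationError, ParseError, ValidationError
from .io_tables import ANNOTATION_COLUMNS, FeatureTable

logger = logging.getLogger(__name__)

#: Proton mass in Da; electron mass neglected (< 0.5 mDa, below tolerances).
PROTON_MASS = 1.00727646

_VALID_ELEMENTS = frozenset(k for k in _ptmass.nist_mass if k.isalpha())
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into element counts.

    >>> parse_formula("C6H12O6")
    {'C': 6, 'H': 12, 'O': 6}
    """
    if not text or not text.strip():
        raise ParseError("empty formula")
    text = text.strip()
    comp: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise ParseError(f"unparseable formula '{text}' at position {pos}")
        sym, count = m.group(1), m.group(2)
        if sym not in _VALID_ELEMENTS:
            raise ParseError(
                f"unknown element '{sym}' in formula '{text}' at position {pos}"
            )
        pos = m.end()
        n = int(count) if count else 1
        if n <= 0:
            raise ParseError(f"zero count for element '{sym}' in '{text}'")
        comp[sym] = comp.get(sym, 0) + n
    if not comp:
        raise ParseError(f"formula '{text}' contains no atoms")
    return comp


def monoisotopic_mass(composition: dict[str, int]) -> float:
    """Monoisotopic (lightest-isotope) mass in Da of an element composition."""
    if not composition:
        raise ValidationError("empty composition has no mass")
    total = 0.0
    for sym, count in composition.items():
        if sym not in _VALID_ELEMENTS:
            raise ParseError(f"unknown element '{sym}'")
        if count < 0:
            raise ValidationError(f"negative count for element '{sym}'")
        total += count * _ptmass.nist_mass[sym][0][0]
    return total


@dataclass(frozen=True)
class AdductDef:
    """An ionization adduct [nM+X]z: m/z = (n*M + delta_mass) / |charge|."""

    name: str
    delta_mass: float
    charge: int
    multimer: int = 1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValidationError(f"adduct '{self.name}' has zero charge")
        if self.multimer < 1:
            raise ValidationError(f"adduct '{self.name}' has multimer < 1")


#: Default adduct set, editable via a user-supplied adduct table.
DEFAULT_ADDUCTS: list[AdductDef] = [
    AdductDef("[M+H]+", PROTON_MASS, 1),
    AdductDef("[M+Na]+", 22.98922070, 1),
    AdductDef("[M+NH4]+", 18.03382555, 1),
    AdductDef("[M-H]-", -PROTON_MASS, -1),
    AdductDef("[M+Cl]-", 34.96940126, -1),
    AdductDef("[2M+H]+", PROTON_MASS, 1, multimer=2),
    AdductDef("[M+2H]2+", 2 * PROTON_MASS, 2),
]


def adduct_mz(neutral_mass: float, adduct: AdductDef) -> float:
    """m/z of a neutral mass under an adduct definition."""
    if neutral_mass <= 0:
        raise ValidationError("neutral mass must be positive")
    return (adduct.multimer * neutral_mass + adduct.delta_mass) / abs(adduct.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValidationError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class ReferenceStandard:
    """A compound measured in-house: known m/z and retention time."""

    compound_name: str
    formula: str
    rt: float
    mz: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValidationError(f"standard '{self.compound_name}': mz must be > 0")
        if self.rt < 0:
            raise ValidationError(f"standard '{self.compound_name}': rt must be >= 0")


@dataclass
class Ms2Spectrum:
    """A fragmentation spectrum: precursor m/z, rt, peaks sorted by m/z."""

    precursor_mz: float
    rt: float
    peaks: list[tuple[float, float]]
    name: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(((float(m), float(i)) for m, i in self.peaks),
                            key=lambda p: p[0])
        if any(i < 0 for _, i in self.peaks):
            raise ValidationError("negative peak intensity")


# ---------------------------------------------------------------------------
# MS1 accurate-mass annotation
# ---------------------------------------------------------------------------

def annotate_ms1(features: FeatureTable, compounds: pd.DataFrame,
                 adducts: list[AdductDef] | None = None,
                 ppm_tol: float = 5.0) -> pd.DataFrame:
    """Match every feature m/z against compound x adduct theoretical m/z.

    ``compounds`` needs columns ``name`` and ``formula``. Every hit within
    ``ppm_tol`` becomes one annotation row (source="ms1"); a feature's
    rows are ordered by absolute ppm error. Unparseable formulas are
    skipped with a warning and counted in the attached report.
    """
    if ppm_tol <= 0:
        raise ConfigurationError("ppm_tol must be positive")
    adducts = list(adducts) if adducts is not None else list(DEFAULT_ADDUCTS)
    theo = []  # (name, formula, adduct_name, theoretical mz)
    skipped = 0
    for _, row in compounds.iterrows():
        try:
            m = monoisotopic_mass(parse_formula(str(row["formula"])))
        except (ParseError, ValidationError) as exc:
            logger.warning("skipping compound '%s': %s", row["name"], exc)
            skipped += 1
            continue
        for ad in adducts:
            theo.append((str(row["name"]), str(row["formula"]), ad.name,
                         adduct_mz(m, ad)))
    rows = []
    theo_mz = np.array([t[3] for t in theo]) if theo else np.empty(0)
    for fid in features.feature_ids:
        fmz = float(features.data.loc[fid, "mz"])
        if len(theo_mz) == 0:
            continue
        errs = 1e6 * (fmz - theo_mz) / theo_mz
        hits = np.flatnonzero(np.abs(errs) <= ppm_tol)
        for idx in sorted(hits, key=lambda i: (abs(errs[i]), theo[i][0], theo[i][2])):
            name, formula, ad_name, _ = theo[idx]
            rows.append({"feature_id": fid, "compound_name": name,
                         "formula": formula, "adduct": ad_name,
                         "ppm_error": float(errs[idx]), "source": "ms1",
                         "score": np.nan})
    out = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    out.attrs["skipped_compounds"] = skipped
    return out


def match_reference_standards(features: FeatureTable,
                              standards: list[ReferenceStandard],
                              ppm_tol: float = 5.0,
                              rt_tol: float = 10.0) -> pd.DataFrame:
    """Annotate features against measured standards (m/z AND rt windows).

    When several standards hit one feature, ties are broken by the
    smallest combined normalized distance |ppm|/ppm_tol + |drt|/rt_tol.
    """
    if ppm_tol <= 0 or rt_tol <= 0:
        raise ConfigurationError("ppm_tol and rt_tol must be positive")
    rows = []
    for fid in features.feature_ids:
        fmz = float(features.data.loc[fid, "mz"])
        frt = float(features.data.loc[fid, "rt"])
        candidates = []
        for std in standards:
            perr = ppm_error(fmz, std.mz)
            drt = frt - std.rt
            if abs(perr) <= ppm_tol and abs(drt) <= rt_tol:
                dist = abs(perr) / ppm_tol + abs(drt) / rt_tol
                candidates.append((dist, std, perr))
        if not candidates:
            continue
        candidates.sort(key=lambda c: (c[0], c[1].compound_name))
        dist, std, perr = candidates[0]
        rows.append({"feature_id": fid, "compound_name": std.compound_name,
                     "formula": std.formula, "adduct": "",
                     "ppm_error": float(perr), "source": "standard",
                     "score": np.nan})
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


# ---------------------------------------------------------------------------
# MS2 alignment and spectral matching
# ---------------------------------------------------------------------------

def align_ms2_to_features(ms2: list[Ms2Spectrum], features: FeatureTable,
                          ppm_tol: float = 10.0,
                          rt_tol: float = 15.0) -> tuple[dict[str, list[Ms2Spectrum]],
                                                         list[Ms2Spectrum]]:
    """Assign each MS2 spectrum to the feature matching its precursor.

    A spectrum matching several features goes to the nearest precursor in
    ppm. Returns (feature_id -> spectra, unassigned spectra).
    """
    if ppm_tol <= 0 or rt_tol <= 0:
        raise ConfigurationError("ppm_tol and rt_tol must be positive")
    assignments: dict[str, list[Ms2Spectrum]] = {}
    unassigned: list[Ms2Spectrum] = []
    fids = features.feature_ids
    fmz = features.data["mz"].to_numpy(dtype=float)
    frt = features.data["rt"].to_numpy(dtype=float)
    for spec in ms2:
        errs = 1e6 * (spec.precursor_mz - fmz) / fmz
        ok = (np.abs(errs) <= ppm_tol) & (np.abs(spec.rt - frt) <= rt_tol)
        idx = np.flatnonzero(ok)
        if len(idx) == 0:
            unassigned.append(spec)
            continue
        best = min(idx, key=lambda i: (abs(errs[i]), fids[i]))
        assignments.setdefault(fids[best], []).append(spec)
    return assignments, unassigned


def spectral_similarity(a: Ms2Spectrum, b: Ms2Spectrum,
                        mz_tol: float = 0.01) -> float:
    """Greedy square-root cosine similarity between two spectra in [0, 1].

    Peaks are paired one-to-one within ``mz_tol``, closest m/z difference
    first; the cosine is then taken over square-root-scaled intensity
    vectors that include unpaired peaks (as zero on the other side), so
    unshared signal lowers the score. Symmetric by construction.
    """
    if not a.peaks or not b.peaks:
        raise ValidationError("spectral similarity undefined for empty spectrum")
    pairs = []
    for i, (mza, _) in enumerate(a.peaks):
        for j, (mzb, _) in enumerate(b.peaks):
            d = abs(mza - mzb)
            if d <= mz_tol:
                pairs.append((d, i, j))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j))
    va, vb = [], []
    for i, j in matched:
        va.append(np.sqrt(a.peaks[i][1]))
        vb.append(np.sqrt(b.peaks[j][1]))
    for i, (_, inten) in enumerate(a.peaks):
        if i not in used_a:
            va.append(np.sqrt(inten))
            vb.append(0.0)
    for j, (_, inten) in enumerate(b.peaks):
        if j not in used_b:
            va.append(0.0)
            vb.append(np.sqrt(inten))
    va = np.asarray(va)
    vb = np.asarray(vb)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValidationError("spectral similarity undefined for all-zero spectrum")
    return float(np.clip(va @ vb / (na * nb), 0.0, 1.0))


def annotate_ms2(assignments: dict[str, list[Ms2Spectrum]],
                 library: list[Ms2Spectrum],
                 mz_tol: float = 0.01,
                 precursor_ppm_tol: float = 10.0,
                 min_score: float = 0.7) -> pd.DataFrame:
    """Score assigned MS2 spectra against a named spectral library.

    Library entries whose precursor lies within the ppm window and whose
    similarity reaches ``min_score`` become annotations (source="ms2"),
    ranked per feature by score descending.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ConfigurationError("min_score must be within [0, 1]")
    if not library:
        logger.warning("empty MS2 library; no ms2 annotations produced")
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)
    rows = []
    for fid, spectra in assignments.items():
        hits = []
        for spec in spectra:
            for entry in library:
                perr = ppm_error(spec.precursor_mz, entry.precursor_mz)
                if abs(perr) > precursor_ppm_tol:
                    continue
                score = spectral_similarity(spec, entry, mz_tol=mz_tol)
                if score >= min_score:
                    hits.append((score, perr, entry))
        hits.sort(key=lambda h: (-h[0], abs(h[1]), h[2].name))
        for score, perr, entry in hits:
            rows.append({"feature_id": fid, "compound_name": entry.name,
                         "formula": "", "adduct": "",
                         "ppm_error": float(perr), "source": "ms2",
                         "score": float(score)})
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def read_adduct_table(path, sep: str = ",") -> list[AdductDef]:
    """Load a custom adduct set: columns name, delta_mass, charge[, multimer]."""
    df = pd.read_csv(path, sep=sep)
    out = []
    for _, row in df.iterrows():
        out.append(AdductDef(str(row["name"]), float(row["delta_mass"]),
                             int(row["charge"]),
                             int(row.get("multimer", 1) or 1)))
    names = [a.name for a in out]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate adduct names in adduct table")
    return out


def read_standards_table(path, sep: str = ",") -> list[ReferenceStandard]:
    """Load reference standards: columns name, formula, rt, mz."""
    df = pd.read_csv(path, sep=sep)
    return [ReferenceStandard(str(r["name"]), str(r["formula"]),
                              float(r["rt"]), float(r["mz"]))
            for _, r in df.iterrows()]
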