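"""MS/MS spectrum annotation for (oxidized) xyloglucan oligosaccharides.

The evidence logic mirrors expert annotation of ion-trap CID spectra of
LPMO digests:

1. The precursor is classified against a defined mass list: non-oxidized,
   ``minus2`` (C4 keto / C1 delta-lactone, -2.016 Da) or ``plus16`` (C1
   aldonic / C4 gem-diol, +15.995 Da -- which is also where formic acid
   adducts of non-oxidized species of a neighbouring composition land).
2. ``plus16`` precursors showing a clean -46 loss are re-assigned as
   formate adducts of the non-oxidized composition; otherwise they are
   recorded as C1-oxidized at composition level only (C1 products
   co-elute and cannot be structurally localized).
3. ``minus2`` precursors are matched against all isomeric C4-keto
   candidate structures (XXXG-repeat grammar by default); candidates are
   scored by their matched theoretical fragments, with candidate-unique
   ("diagnostic") fragments up-weighted.  All co-optimal isomers are
   reported, ties broken lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .core import (
    MONOISOTOPIC,
    Composition,
    IonSpecies,
    OxForm,
    XGStructure,
    enumerate_structures,
    generate_mass_list,
)
from .fragments import DEFAULT_TYPES, FragmentIon, fragment_structure

__all__ = [
    "Spectrum",
    "EmptySpectrumError",
    "PrecursorCall",
    "Annotation",
    "SpectrumAnnotation",
    "AnnotationReport",
    "default_mass_list",
    "classify_precursor",
    "annotate_spectrum",
    "annotate_digest",
]


class EmptySpectrumError(ValueError):
    """Raised when a spectrum with no fragment peaks is annotated."""


@dataclass
class Spectrum:
    """Precursor plus fragment peak list (peaks kept sorted by m/z)."""

    precursor_mz: float
    precursor_charge: int = 1
    polarity: str = "-"
    peaks: list[tuple[float, float]] = field(default_factory=list)
    spectrum_id: str = ""

    def __post_init__(self) -> None:
        for mz_, inten in self.peaks:
            if not (inten >= 0) or mz_ != mz_ or inten != inten:
                raise ValueError("peak m/z and intensities must be finite, >= 0")
        self.peaks = sorted((float(a), float(b)) for a, b in self.peaks)

    @property
    def base_intensity(self) -> float:
        return max((i for _, i in self.peaks), default=0.0)


@dataclass(frozen=True)
class PrecursorCall:
    """Oxidation/adduct call for a precursor against the mass list."""

    category: str  # non-oxidized | minus2 | plus16 | unassigned
    compositions: tuple[str, ...]
    matches: tuple[tuple[str, str, str], ...]  # (composition, form, ion)


@dataclass
class Annotation:
    """One candidate structure with its fragment-match evidence."""

    candidate: XGStructure
    matched: list[tuple[FragmentIon, float, float]]  # fragment, peak mz, rel int
    informative_count: int
    score: float
    co_optimal: bool = False
    note: str = ""


@dataclass
class SpectrumAnnotation:
    spectrum_id: str
    precursor_mz: float
    call: PrecursorCall
    formate_adduct: bool
    annotations: list[Annotation]

    @property
    def co_optimal_structures(self) -> list[XGStructure]:
        return [a.candidate for a in self.annotations if a.co_optimal]


@dataclass
class AnnotationReport:
    """Digest-level collection of per-spectrum annotations."""

    entries: list[SpectrumAnnotation]

    def product_tally(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for e in self.entries:
            for s in e.co_optimal_structures:
                tally[s.code] = tally.get(s.code, 0) + 1
        return dict(sorted(tally.items()))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            if not e.annotations:
                rows.append(
                    {
                        "spectrum_id": e.spectrum_id,
                        "precursor_mz": e.precursor_mz,
                        "call": e.call.category,
                        "candidate": "",
                        "score": 0.0,
                        "co_optimal": False,
                        "matched_fragments": "",
                        "note": "formate adduct" if e.formate_adduct else "",
                    }
                )
            for a in e.annotations:
                rows.append(
                    {
                        "spectrum_id": e.spectrum_id,
                        "precursor_mz": e.precursor_mz,
                        "call": e.call.category,
                        "candidate": a.candidate.code,
                        "score": a.score,
                        "co_optimal": a.co_optimal,
                        "matched_fragments": ";".join(
                            f"{f.ftype}{f.index}:{peak:.2f}({rel:.1f})"
                            for f, peak, rel in a.matched
                        ),
                        "note": a.note,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "spectrum_id",
                "precursor_mz",
                "call",
                "candidate",
                "score",
                "co_optimal",
                "matched_fragments",
                "note",
            ],
        )


def default_mass_list(
    dp_range: tuple[int, int] = (1, 9), include_fucose: bool = False
) -> pd.DataFrame:
    """Mass list used for precursor classification in negative mode."""
    return generate_mass_list(
        dp_range=dp_range,
        oxidation_forms=(
            OxForm.NONE,
            OxForm.C4_KETO,
            OxForm.C1_LACTONE,
            OxForm.C1_ALDONIC,
        ),
        ion_kinds=(IonSpecies.M_MINUS_H, IonSpecies.M_PLUS_FORMATE_MINUS_H),
        include_fucose=include_fucose,
    )


_MINUS2 = {OxForm.C4_KETO.value, OxForm.C1_LACTONE.value}
_PLUS16 = {OxForm.C1_ALDONIC.value, OxForm.C4_GEMDIOL.value}
_FORMATE = IonSpecies.M_PLUS_FORMATE_MINUS_H.label


def _row_category(form: str, ion: str) -> str:
    if form in _MINUS2:
        return "minus2"
    if form in _PLUS16 or ion == _FORMATE:
        return "plus16"
    return "non-oxidized"


def classify_precursor(
    precursor_mz: float, mass_list: pd.DataFrame, tolerance: float = 0.3
) -> PrecursorCall:
    """Classify a precursor m/z against a defined mass list.

    The category follows the closest-matching row; all rows within
    tolerance are reported so isobaric ambiguities (e.g. C1-oxidized H5P2
    vs the formate adduct of H4P3) stay visible.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    delta = (mass_list["mz"] - precursor_mz).abs()
    hits = mass_list.loc[delta <= tolerance].copy()
    if hits.empty:
        return PrecursorCall("unassigned", (), ())
    hits["delta"] = delta.loc[hits.index]
    hits = hits.sort_values(["delta", "composition"], kind="mergesort")
    category = _row_category(hits.iloc[0]["form"], hits.iloc[0]["ion"])
    same = hits[
        [_row_category(r["form"], r["ion"]) == category for _, r in hits.iterrows()]
    ]
    comps = tuple(dict.fromkeys(same["composition"]))
    matches = tuple(
        (r["composition"], r["form"], r["ion"]) for _, r in same.iterrows()
    )
    return PrecursorCall(category, comps, matches)


def _composition_from_label(mass_list: pd.DataFrame, label: str) -> Composition:
    row = mass_list.loc[mass_list["composition"] == label].iloc[0]
    return Composition(
        int(row["hexose"]), int(row["pentose"]), int(row["deoxyhexose"])
    )


def _score_candidates(
    sp: Spectrum,
    candidates: Sequence[XGStructure],
    tolerance: float,
    intensity_floor: float,
    diagnostic_weight: float,
    note: str = "",
) -> list[Annotation]:
    floor = intensity_floor * sp.base_intensity
    usable = [(mz_, inten) for mz_, inten in sp.peaks if inten >= floor]
    theo = {c: fragment_structure(c, DEFAULT_TYPES) for c in candidates}

    def is_shared(c: XGStructure, frag_mz: float) -> bool:
        for other, frs in theo.items():
            if other is c:
                continue
            if any(abs(f.mz - frag_mz) <= tolerance for f in frs):
                return True
        return False

    annotations = []
    for c in candidates:
        matched: list[tuple[FragmentIon, float, float]] = []
        matched_mzs: set[int] = set()
        score = 0.0
        informative = 0
        base = sp.base_intensity or 1.0
        for f in theo[c]:
            best = None
            for peak_mz, inten in usable:
                d = abs(peak_mz - f.mz)
                if d <= tolerance and (best is None or d < best[0]):
                    best = (d, peak_mz, inten)
            if best is None:
                continue
            key = round(f.mz / max(tolerance, 1e-6))
            if key in matched_mzs:
                continue  # count each theoretical m/z once
            matched_mzs.add(key)
            diagnostic = len(candidates) > 1 and not is_shared(c, f.mz)
            w = diagnostic_weight if diagnostic else 1.0
            informative += int(diagnostic)
            score += w
            matched.append((f, best[1], 100.0 * best[2] / base))
        annotations.append(
            Annotation(
                candidate=c,
                matched=matched,
                informative_count=informative,
                score=score,
                note=note,
            )
        )
    annotations.sort(key=lambda a: (-a.score, a.candidate.code))
    if annotations:
        top = annotations[0].score
        for a in annotations:
            a.co_optimal = a.score == top and top > 0
    return annotations


def annotate_spectrum(
    sp: Spectrum,
    mass_list: Optional[pd.DataFrame] = None,
    tolerance: float = 0.3,
    precursor_tolerance: float = 0.3,
    grammar: str = "xxxg",
    intensity_floor: float = 0.005,
    diagnostic_weight: float = 3.0,
) -> SpectrumAnnotation:
    """Assign candidate structures to one spectrum (see module docstring)."""
    if not sp.peaks:
        raise EmptySpectrumError("spectrum has no fragment peaks")
    if mass_list is None:
        mass_list = default_mass_list()
    call = classify_precursor(sp.precursor_mz, mass_list, precursor_tolerance)
    formate = False
    annotations: list[Annotation] = []

    if call.category == "minus2":
        candidates: list[XGStructure] = []
        for comp_label, form, _ion in call.matches:
            if form != OxForm.C4_KETO.value:
                continue  # lactone stays composition-level
            comp = _composition_from_label(mass_list, comp_label)
            candidates.extend(
                enumerate_structures(comp, OxForm.C4_KETO, grammar=grammar)
            )
        candidates = sorted(set(candidates), key=lambda s: s.code)
        annotations = _score_candidates(
            sp, candidates, tolerance, intensity_floor, diagnostic_weight
        )
    elif call.category == "plus16":
        loss = sp.precursor_mz - MONOISOTOPIC.formic_acid
        formate = any(abs(mz_ - loss) <= tolerance for mz_, _ in sp.peaks)
        if formate:
            candidates = []
            for comp_label, form, ion in call.matches:
                if ion != _FORMATE or form != OxForm.NONE.value:
                    continue
                comp = _composition_from_label(mass_list, comp_label)
                candidates.extend(
                    enumerate_structures(comp, OxForm.NONE, grammar=grammar)
                )
            candidates = sorted(set(candidates), key=lambda s: s.code)
            annotations = _score_candidates(
                sp,
                candidates,
                tolerance,
                intensity_floor,
                diagnostic_weight,
                note="formate adduct of non-oxidized product",
            )
        # else: C1-oxidized at composition level only; no localization
    elif call.category == "non-oxidized":
        candidates = []
        for comp_label, form, ion in call.matches:
            if form != OxForm.NONE.value or ion == _FORMATE:
                continue
            comp = _composition_from_label(mass_list, comp_label)
            candidates.extend(
                enumerate_structures(comp, OxForm.NONE, grammar=grammar)
            )
        candidates = sorted(set(candidates), key=lambda s: s.code)
        annotations = _score_candidates(
            sp, candidates, tolerance, intensity_floor, diagnostic_weight
        )

    return SpectrumAnnotation(
        spectrum_id=sp.spectrum_id,
        precursor_mz=sp.precursor_mz,
        call=call,
        formate_adduct=formate,
        annotations=annotations,
    )


def annotate_digest(
    spectra: Sequence[Spectrum],
    mass_list: Optional[pd.DataFrame] = None,
    **params,
) -> AnnotationReport:
    """Annotate a list of spectra; deterministic given inputs."""
    if mass_list is None:
        mass_list = default_mass_list()
    entries = [annotate_spectrum(sp, mass_list, **params) for sp in spectra]
    return AnnotationReport(entries)
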