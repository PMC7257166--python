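"""Synthetic xyloglucan polymers, oxidative digests, spectra and alignments.

The generators emulate the study conditions of LPMO xyloglucan digests:

* polymers are (SSSG)n block repeats (tamarind-type: S in {X, L}; black
  currant additionally carries fucosylated F units on galactosylated
  positions);
* a substitution-intolerant enzyme cuts only bonds whose reducing-side
  unit is an unbranched G, leaving C4-keto G termini; a tolerant enzyme
  cuts anywhere with substituted positions up-weighted and mixes C4 and
  C1 oxidation; an inactive enzyme leaves the polymer intact;
* spectra are theoretical fragment sets degraded with m/z jitter, peak
  dropout and uniform decoy peaks, with exponential intensities boosted
  for B/Y ions.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import Spectrum
from .core import MONOISOTOPIC, IonSpecies, OxForm, XGStructure
from .fragments import DEFAULT_TYPES, fragment_structure
from .segphylo import SegmentBoundaryMap

__all__ = [
    "DigestRuleSet",
    "SpectrumNoiseModel",
    "simulate_polymer",
    "simulate_digest",
    "simulate_spectrum",
    "simulate_digest_spectra",
    "simulate_segment_families",
    "DEFAULT_FAMILIES",
]


@dataclass(frozen=True)
class DigestRuleSet:
    """Rule set describing one enzyme's oxidative cleavage behaviour."""

    mode: str  # intolerant | tolerant | inactive
    c4_fraction: float = 1.0  # oxidation mix: P(C4 keto) vs P(C1 aldonic)
    substituted_weight: float = 3.0
    cut_density: float = 0.5
    min_dp: int = 2
    max_dp: int = 8

    def __post_init__(self) -> None:
        if self.mode not in ("intolerant", "tolerant", "inactive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 <= self.c4_fraction <= 1:
            raise ValueError("c4_fraction must be a probability")
        if self.substituted_weight < 0 or self.cut_density < 0:
            raise ValueError("weights must be non-negative")

    @classmethod
    def for_mode(cls, mode: str) -> "DigestRuleSet":
        """Defaults emulating the characterized enzyme behaviours.

        The tolerant enzyme produced both C1- and C4-oxidized products;
        the intolerant one only C4.  The 70/30 C4:C1 mix and the cut
        density are stated defaults, not fitted values.
        """
        if mode == "intolerant":
            return cls(mode="intolerant", c4_fraction=1.0)
        if mode == "tolerant":
            return cls(mode="tolerant", c4_fraction=0.7)
        return cls(mode="inactive")


@dataclass(frozen=True)
class SpectrumNoiseModel:
    """Ion-trap-quality noise for simulated MS/MS spectra."""

    mz_jitter_sd: float = 0.05
    fragment_dropout: float = 0.10
    decoy_peak_rate: float = 3.0
    intensity_scale: float = 1.0
    by_ion_boost: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "mz_jitter_sd",
            "fragment_dropout",
            "decoy_peak_rate",
            "intensity_scale",
            "by_ion_boost",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def noiseless(cls) -> "SpectrumNoiseModel":
        return cls(0.0, 0.0, 0.0, 1.0, 1.0)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_polymer(
    n_blocks: int,
    p_L: float = 0.35,
    p_F: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> XGStructure:
    """An (SSSG)n polymer; substituted positions are X, upgraded to L with
    probability ``p_L`` and (black-currant mode) L further to F with ``p_F``."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if not (0 <= p_L <= 1 and 0 <= p_F <= 1):
        raise ValueError("p_L and p_F must be probabilities")
    rng = _rng(seed)
    units: list[str] = []
    for _ in range(n_blocks):
        for _ in range(3):
            u = "X"
            if rng.random() < p_L:
                u = "F" if (p_F and rng.random() < p_F) else "L"
            units.append(u)
        units.append("G")
    return XGStructure(tuple(units))


def simulate_digest(
    polymer: XGStructure,
    rules: DigestRuleSet,
    seed: int | np.random.Generator = 0,
) -> list[XGStructure]:
    """Rule-based oxidative digest; returns all products, intact order.

    Each cut hydrolyses one backbone bond (adding one water across the two
    products) and oxidizes the new terminus: C4-keto on the reducing-side
    product's non-reducing unit, or C1-aldonic on the non-reducing-side
    product's reducing unit.  A middle product flanked by a C4 cut on its
    left and a C1 cut on its right keeps only the C4 mark (the model holds
    one oxidation state per product).
    """
    rng = _rng(seed)
    if rules.mode == "inactive":
        return [polymer]
    units = polymer.units
    n = len(units)
    cuts: list[tuple[int, str]] = []  # (bond index i: between i and i+1, ox type)
    for i in range(n - 1):
        reducing_side = units[i + 1]
        if rules.mode == "intolerant":
            if reducing_side != "G":
                continue
            p = rules.cut_density
        else:
            w = 1.0 if reducing_side == "G" else rules.substituted_weight
            w_max = max(1.0, rules.substituted_weight)
            p = rules.cut_density * w / w_max
        if rng.random() < p:
            ox = "C4" if rng.random() < rules.c4_fraction else "C1"
            cuts.append((i, ox))

    products: list[XGStructure] = []
    start = 0
    left_ox: Optional[str] = None  # oxidation inherited from the cut on the left
    for i, ox in cuts + [(n - 1, "")]:
        seg = units[start : i + 1]
        form = OxForm.NONE
        if left_ox == "C4":
            form = OxForm.C4_KETO
        elif ox == "C1":
            form = OxForm.C1_ALDONIC
        products.append(XGStructure(seg, form))
        start = i + 1
        left_ox = ox
    return products


def simulate_spectrum(
    product: XGStructure,
    noise: SpectrumNoiseModel = SpectrumNoiseModel(),
    seed: int | np.random.Generator = 0,
    spectrum_id: str = "",
) -> Spectrum:
    """Noisy negative-mode MS/MS spectrum of one product."""
    rng = _rng(seed)
    theo = fragment_structure(product, DEFAULT_TYPES)
    peaks: dict[float, float] = {}
    for f in theo:
        if noise.fragment_dropout and rng.random() < noise.fragment_dropout:
            continue
        inten = rng.exponential(noise.intensity_scale)
        if f.ftype in ("B", "Y"):
            inten *= noise.by_ion_boost
        mz_ = f.mz + (
            rng.normal(0.0, noise.mz_jitter_sd) if noise.mz_jitter_sd else 0.0
        )
        peaks[mz_] = peaks.get(mz_, 0.0) + inten
    precursor = product.mz(IonSpecies.M_MINUS_H)
    n_decoys = rng.poisson(noise.decoy_peak_rate) if noise.decoy_peak_rate else 0
    for _ in range(n_decoys):
        peaks[rng.uniform(150.0, precursor)] = rng.exponential(
            0.3 * noise.intensity_scale
        )
    obs_precursor = precursor + (
        rng.normal(0.0, noise.mz_jitter_sd) if noise.mz_jitter_sd else 0.0
    )
    return Spectrum(
        precursor_mz=obs_precursor,
        precursor_charge=1,
        polarity="-",
        peaks=sorted(peaks.items()),
        spectrum_id=spectrum_id or product.code,
    )


def simulate_digest_spectra(
    polymer: XGStructure,
    rules: DigestRuleSet,
    noise: SpectrumNoiseModel = SpectrumNoiseModel(),
    seed: int | np.random.Generator = 0,
) -> tuple[list[XGStructure], list[Spectrum]]:
    """Digest a polymer and acquire spectra of the observable oxidized
    products (DP within the rule set's window) -- the LC-MS/MS step."""
    rng = _rng(seed)
    products = simulate_digest(polymer, rules, rng)
    observable = [
        p
        for p in products
        if p.oxidation is not OxForm.NONE and rules.min_dp <= p.dp <= rules.max_dp
    ]
    spectra = [
        simulate_spectrum(p, noise, rng, spectrum_id=f"scan{i}")
        for i, p in enumerate(observable)
    ]
    return products, spectra


# ---------------------------------------------------------------------------
# synthetic segment families
# ---------------------------------------------------------------------------

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: family label -> mean ungapped segment lengths; +Seg1/-Seg1 differ in
#: Seg1 length and so on.  Means are synthetic but sized like real AA9
#: active-site segments (short ~4-6 aa, long/extended ~11-14 aa).
DEFAULT_FAMILIES: dict[str, dict[str, int]] = {
    "+Seg1-Seg2": {"Seg1": 13, "Seg2": 4, "Seg3": 5, "Seg4": 7, "Seg5": 6},
    "-Seg1+Seg2": {"Seg1": 5, "Seg2": 12, "Seg3": 5, "Seg4": 7, "Seg5": 6},
    "-Seg1-Seg2": {"Seg1": 5, "Seg2": 4, "Seg3": 5, "Seg4": 7, "Seg5": 6},
}

_SEGMENTS = ("Seg1", "Seg2", "Seg3", "Seg4", "Seg5")
_CORE_WIDTH = 8
_SEG_MARGIN = 4
_FAMILY_DIVERGENCE = 0.35
_WITHIN_FAMILY_DIVERGENCE = 0.05
_LENGTH_SD = 1.0


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(AA_ALPHABET[rng.integers(len(AA_ALPHABET))])
        else:
            out.append(ch)
    return "".join(out)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), length))


def simulate_segment_families(
    n_per_family: int = 10,
    families: Optional[dict[str, dict[str, int]]] = None,
    seed: int | np.random.Generator = 0,
) -> tuple[MultipleSeqAlignment, SegmentBoundaryMap, dict, dict]:
    """Synthetic segments-only MSA with configuration-family structure.

    Returns (alignment, boundary map, leaf -> family label, leaf -> true
    segment lengths).  Families share a root consensus mutated per family,
    so within-family distances are small and families resolve as clades.
    """
    families = families or DEFAULT_FAMILIES
    if len(families) < 2:
        raise ValueError("need at least 2 families")
    rng = _rng(seed)

    seg_widths = {
        name: max(params[name] for params in families.values()) + _SEG_MARGIN
        for name in _SEGMENTS
    }
    root_core = [_random_seq(_CORE_WIDTH, rng) for _ in range(len(_SEGMENTS) + 1)]
    root_seg = {name: _random_seq(seg_widths[name], rng) for name in _SEGMENTS}

    records, labels, truth = [], {}, {}
    ranges: dict[str, tuple[int, int]] = {}
    col = _CORE_WIDTH
    for name in _SEGMENTS:
        ranges[name] = (col, col + seg_widths[name])
        col += seg_widths[name] + _CORE_WIDTH
    bmap = SegmentBoundaryMap(ranges)

    for fam_label, params in families.items():
        fam_core = [_mutate(c, _FAMILY_DIVERGENCE, rng) for c in root_core]
        fam_seg = {
            name: _mutate(root_seg[name], _FAMILY_DIVERGENCE, rng)
            for name in _SEGMENTS
        }
        for k in range(n_per_family):
            rid = f"{fam_label}|{k:02d}"
            parts = []
            lengths = {}
            for i, name in enumerate(_SEGMENTS):
                parts.append(_mutate(fam_core[i], _WITHIN_FAMILY_DIVERGENCE, rng))
                mean_len = params[name]
                length = int(
                    np.clip(
                        round(rng.normal(mean_len, _LENGTH_SD)),
                        1,
                        seg_widths[name],
                    )
                )
                lengths[name] = length
                body = _mutate(
                    fam_seg[name][:length], _WITHIN_FAMILY_DIVERGENCE, rng
                )
                parts.append(body + "-" * (seg_widths[name] - length))
            parts.append(
                _mutate(fam_core[len(_SEGMENTS)], _WITHIN_FAMILY_DIVERGENCE, rng)
            )
            seq = "".join(parts)
            records.append(SeqRecord(Seq(seq), id=rid, description=""))
            labels[rid] = fam_label
            truth[rid] = lengths

    msa = MultipleSeqAlignment(records)
    return msa, bmap, labels, truth
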