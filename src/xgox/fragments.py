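"""In-silico negative-mode CID fragmentation of xyloglucan oligosaccharides.

Fragments follow the Domon-Costello glycan nomenclature: B/C ions contain
the non-reducing end, Y/Z ions the reducing end, A/X are cross-ring
cleavages and D ions are internal products from a double C/Z cleavage.
Negative-mode CID of neutral oligosaccharides is dominated by C/Z- and
A-type ions; C4-oxidized species additionally give the diagnostic loss of
the oxidized terminal unit (-160.04 for an unbranched, -292.08 for a
xylosylated glucosyl) and a cross-ring ion on the oxidized ring.

Cross-ring mass offsets are empirical rules calibrated against published
ion-trap spectra of xyloglucan oligosaccharides, not first-principles atom
bookkeeping: the 0,2A ion on the reducing-end residue sits 60.021 below the
deprotonated precursor, and each 2,4X ion sits 102.032 above its paired
Y ion.

All fragment m/z values are reported as singly deprotonated species by
default; doubly charged variants are available via ``max_charge=2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import MONOISOTOPIC, UNIT_TABLE, IonSpecies, OxForm, XGStructure

__all__ = [
    "FragmentIon",
    "DEFAULT_TYPES",
    "A02_OFFSET",
    "X24_OFFSET",
    "fragment_structure",
    "neutral_loss_series",
    "fragments_to_dataframe",
]

#: empirical cross-ring offsets (Da), see module docstring
A02_OFFSET = 60.021
X24_OFFSET = 102.032

DEFAULT_TYPES = frozenset({"B", "C", "Y", "Z", "A02", "X24", "D", "water_loss"})

#: maximum residue span of a D ion: a double C/Z cleavage on three linked
#: sugar residues around a branch point
_D_MAX_RESIDUES = 3


@dataclass(frozen=True)
class FragmentIon:
    """A typed fragment with its computed (deprotonated) m/z.

    ``index`` bookkeeping: B/C carry the residue count of the fragment; Y/Z
    carry the backbone position (1-based from the reducing end) of the unit
    lost at the cleaved bond; 2,4X reuses its paired Y index.
    """

    ftype: str
    index: int
    covered: str
    mz: float
    carries_oxidation: bool
    charge: int = 1


def _residue_mass(units: Sequence[str]) -> float:
    m = MONOISOTOPIC
    total = 0.0
    for u in units:
        c = UNIT_TABLE[u]
        total += (
            c.hexose * m.hexose_residue
            + c.pentose * m.pentose_residue
            + c.deoxyhexose * m.deoxyhexose_residue
        )
    return total


#: side-chain subtrees cleavable off each unit: (residue mass lambda, label)
def _side_chain_bonds(unit: str) -> list[tuple[float, str]]:
    m = MONOISOTOPIC
    if unit == "X":
        return [(m.pentose_residue, "Xyl")]
    if unit == "L":
        return [
            (m.pentose_residue + m.hexose_residue, "Gal-Xyl"),
            (m.hexose_residue, "Gal"),
        ]
    if unit == "F":
        return [
            (
                m.pentose_residue + m.hexose_residue + m.deoxyhexose_residue,
                "Fuc-Gal-Xyl",
            ),
            (m.hexose_residue + m.deoxyhexose_residue, "Fuc-Gal"),
            (m.deoxyhexose_residue, "Fuc"),
        ]
    return []


def fragment_structure(
    s: XGStructure,
    types: frozenset[str] | set[str] = DEFAULT_TYPES,
    max_charge: int = 1,
    include_side_chains: bool = True,
) -> list[FragmentIon]:
    """Generate theoretical negative-mode CID fragments of a structure.

    Every glycosidic bond (backbone and side chain) yields its B/C/Y/Z
    pair; cross-ring ions follow the calibrated offsets; D ions cover
    contiguous internal backbone spans of at most three residues.  The
    oxidation mass shift travels with whichever side retains the oxidized
    unit (C4: non-reducing side, so B/C; C1: reducing side, so Y/Z).
    """
    if not types:
        raise ValueError("types must be non-empty")
    m = MONOISOTOPIC
    n = len(s.units)
    ox = s.oxidation
    precursor = s.mz(IonSpecies.M_MINUS_H)
    frags: list[FragmentIon] = []

    def add(ftype, index, covered, neutral_like, carries):
        """neutral_like is the deprotonated 1- m/z already."""
        frags.append(FragmentIon(ftype, index, covered, neutral_like, carries))
        if max_charge >= 2:
            neutral = neutral_like + m.proton
            frags.append(
                FragmentIon(
                    ftype,
                    index,
                    covered,
                    (neutral - 2 * m.proton) / 2,
                    carries,
                    charge=2,
                )
            )

    # backbone glycosidic bonds
    for i in range(n - 1):
        prefix = s.units[: i + 1]
        suffix = s.units[i + 1 :]
        b_base = _residue_mass(prefix) + (ox.mass_shift if ox.is_c4 else 0.0)
        y_base = (
            _residue_mass(suffix)
            + m.water
            + (ox.mass_shift if ox.is_c1 else 0.0)
        )
        b_index = sum(
            UNIT_TABLE[u].hexose + UNIT_TABLE[u].pentose + UNIT_TABLE[u].deoxyhexose
            for u in prefix
        )
        y_index = n - i  # backbone position (from reducing end) of the lost unit
        cov_b = "".join(prefix)
        cov_y = "".join(suffix)
        if "B" in types:
            add("B", b_index, cov_b, b_base - m.proton, ox.is_c4)
        if "C" in types:
            add("C", b_index, cov_b, b_base + m.water - m.proton, ox.is_c4)
        if "Y" in types:
            add("Y", y_index, cov_y, y_base - m.proton, ox.is_c1)
        if "Z" in types:
            add("Z", y_index, cov_y, y_base - m.water - m.proton, ox.is_c1)
        if "X24" in types:
            add("X24", y_index, f"{cov_y}+ring", y_base - m.proton + X24_OFFSET, ox.is_c1)

    # side-chain glycosidic bonds
    if include_side_chains:
        whole = s.neutral_mass
        for j, unit in enumerate(s.units):
            pos = n - j  # backbone position from the reducing end
            for sub_mass, label in _side_chain_bonds(unit):
                if "B" in types:
                    add("B", pos, f"{label}@{unit}{pos}", sub_mass - m.proton, False)
                if "Y" in types:
                    add(
                        "Y",
                        pos,
                        f"M-{label}@{unit}{pos}",
                        whole - sub_mass - m.proton,
                        ox is not OxForm.NONE,
                    )

    # cross-ring 0,2A on the reducing-end residue (empirical offset)
    if "A02" in types and n >= 1:
        add("A02", n, "".join(s.units), precursor - A02_OFFSET, ox is not OxForm.NONE)

    if "water_loss" in types:
        add(
            "water_loss",
            0,
            "".join(s.units),
            precursor - m.water,
            ox is not OxForm.NONE,
        )

    # D ions: internal double C/Z cleavage spanning <= 3 linked residues
    if "D" in types and n >= 3:
        for a in range(1, n - 1):
            for b in range(a + 1, n):
                span = s.units[a:b]
                res = sum(
                    UNIT_TABLE[u].hexose
                    + UNIT_TABLE[u].pentose
                    + UNIT_TABLE[u].deoxyhexose
                    for u in span
                )
                if res > _D_MAX_RESIDUES:
                    continue
                add("D", a, "".join(span), _residue_mass(span) - m.proton, False)

    # deduplicate identical (type, charge, m/z) entries
    seen: set[tuple[str, int, int]] = set()
    unique: list[FragmentIon] = []
    for f in frags:
        key = (f.ftype, f.charge, round(f.mz * 10000))
        if key not in seen:
            seen.add(key)
            unique.append(f)
    unique.sort(key=lambda f: (f.mz, f.ftype, f.index))
    return unique


def neutral_loss_series(
    precursor_mz: float, adduct_kind: IonSpecies = IonSpecies.M_MINUS_H
) -> list[tuple[float, float, str]]:
    """Diagnostic neutral losses expected below a negative-mode precursor.

    Returns (observed fragment m/z, loss, interpretation) tuples.  Formate
    adducts of non-oxidized species betray themselves through a clean -46
    (formic acid) loss; water loss is ubiquitous.
    """
    m = MONOISOTOPIC
    out = [(precursor_mz - m.water, m.water, "water loss")]
    if adduct_kind is IonSpecies.M_PLUS_FORMATE_MINUS_H:
        out.append(
            (
                precursor_mz - m.formic_acid,
                m.formic_acid,
                "formic acid adduct of non-oxidized product",
            )
        )
    return out


def fragments_to_dataframe(
    s: XGStructure, fragments: Sequence[FragmentIon]
) -> pd.DataFrame:
    """Tabulate fragments for TSV export."""
    return pd.DataFrame(
        [
            {
                "structure": s.code,
                "ftype": f.ftype,
                "index": f.index,
                "charge": f.charge,
                "mz": f.mz,
                "covered_units": f.covered,
                "carries_oxidation": f.carries_oxidation,
            }
            for f in fragments
        ]
    )
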