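"""Xyloglucan oligosaccharide grammar, composition, mass and ion m/z calculus.

Xyloglucan (XG) is a beta-1,4-glucan whose backbone glucosyl units carry
side chains; in the Fry one-letter code each backbone unit together with its
full side chain is written as a single letter:

====  =========================================  ===================
code  residues                                   composition (H,P,dH)
====  =========================================  ===================
G     Glc                                        (1, 0, 0)
X     Glc + Xyl                                  (1, 1, 0)
L     Glc + Xyl + Gal                            (2, 1, 0)
F     Glc + Xyl + Gal + Fuc                      (2, 1, 1)
====  =========================================  ===================

Structure strings read non-reducing (left) to reducing (right) end.

Lytic polysaccharide monooxygenases (LPMOs) oxidize the backbone either at
C4 of the new non-reducing terminus (keto form, -2.016 Da, hydrating to a
gem-diol, +15.995 Da) or at C1 of the new reducing terminus (delta-lactone,
-2.016 Da, hydrolysing to the aldonic acid, +15.995 Da).  All masses here
are monoisotopic.
"""

from __future__ import annotations

import enum
import itertools
import re
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "MassTable",
    "MONOISOTOPIC",
    "Composition",
    "OxForm",
    "IonSpecies",
    "XGStructure",
    "XGParseError",
    "UNIT_TABLE",
    "parse_code",
    "neutral_mass",
    "mz",
    "enumerate_structures",
    "generate_mass_list",
    "flag_mass_ambiguities",
    "AmbiguityGroup",
]


@dataclass(frozen=True)
class MassTable:
    """Monoisotopic building-block masses in Da (IUPAC atomic masses)."""

    hexose_residue: float = 162.052824
    pentose_residue: float = 132.042259
    deoxyhexose_residue: float = 146.057909
    water: float = 18.010565
    proton: float = 1.007276
    hydrogen: float = 1.007825
    lithium_cation: float = 7.015455  # 7Li minus one electron
    formic_acid: float = 46.005480
    oxygen: float = 15.994915
    keto_shift: float = 2.015650  # loss of two hydrogens (keto / lactone)
    electron: float = 0.000549


MONOISOTOPIC = MassTable()


class Composition(NamedTuple):
    """Monosaccharide residue counts of an oligosaccharide (HnPm notation)."""

    hexose: int
    pentose: int
    deoxyhexose: int = 0

    @property
    def label(self) -> str:
        s = f"H{self.hexose}P{self.pentose}"
        if self.deoxyhexose:
            s += f"F{self.deoxyhexose}"
        return s

    @property
    def residue_mass(self) -> float:
        m = MONOISOTOPIC
        return (
            self.hexose * m.hexose_residue
            + self.pentose * m.pentose_residue
            + self.deoxyhexose * m.deoxyhexose_residue
        )


#: Fry unit -> (hexose, pentose, deoxyhexose) residue counts.  Data-driven so
#: additional letters (e.g. arabinosylated S units) can be registered, but the
#: shipped grammar is the G/X/L/F set used for tamarind and black-currant XG.
UNIT_TABLE: dict[str, Composition] = {
    "G": Composition(1, 0, 0),
    "X": Composition(1, 1, 0),
    "L": Composition(2, 1, 0),
    "F": Composition(2, 1, 1),
}


class OxForm(enum.Enum):
    """Oxidation state of an oligosaccharide terminus.

    C4 forms sit on the non-reducing terminal backbone glucosyl, C1 forms on
    the reducing terminal one.  Keto and lactone are both -2.016 Da relative
    to the non-oxidized species; gem-diol and aldonic acid are both +15.995.
    """

    NONE = "none"
    C4_KETO = "C4_keto"
    C4_GEMDIOL = "C4_gemdiol"
    C1_LACTONE = "C1_lactone"
    C1_ALDONIC = "C1_aldonic"

    @property
    def mass_shift(self) -> float:
        m = MONOISOTOPIC
        return {
            OxForm.NONE: 0.0,
            OxForm.C4_KETO: -m.keto_shift,
            OxForm.C1_LACTONE: -m.keto_shift,
            OxForm.C4_GEMDIOL: +m.oxygen,
            OxForm.C1_ALDONIC: +m.oxygen,
        }[self]

    @property
    def position(self) -> str:
        if self in (OxForm.C4_KETO, OxForm.C4_GEMDIOL):
            return "nonreducing_terminal"
        if self in (OxForm.C1_LACTONE, OxForm.C1_ALDONIC):
            return "reducing_terminal"
        return "none"

    @property
    def is_c4(self) -> bool:
        return self.position == "nonreducing_terminal"

    @property
    def is_c1(self) -> bool:
        return self.position == "reducing_terminal"


#: ASCII oxidation prefixes for structure strings; the literature-style
#: ``_O=G_`` marker (keto C4 on the leftmost unit) is accepted on input.
_OX_PREFIX = {
    OxForm.C4_KETO: "O4k:",
    OxForm.C4_GEMDIOL: "O4g:",
    OxForm.C1_LACTONE: "O1l:",
    OxForm.C1_ALDONIC: "O1a:",
}
_PREFIX_OX = {v: k for k, v in _OX_PREFIX.items()}
_PREFIX_OX["_O=G_"] = OxForm.C4_KETO


class IonSpecies(enum.Enum):
    """Adduct/charge descriptor turning a neutral mass into an observed m/z."""

    M_MINUS_H = ("[M-H]-", 1, "-")
    M_MINUS_2H = ("[M-2H]2-", 2, "-")
    M_PLUS_LI = ("[M+Li]+", 1, "+")
    M_PLUS_FORMATE_MINUS_H = ("[M+HCOOH-H]-", 1, "-")

    def __init__(self, label: str, charge: int, polarity: str) -> None:
        self.label = label
        self.charge = charge
        self.polarity = polarity

    def ion_mz(self, neutral: float) -> float:
        m = MONOISOTOPIC
        if self is IonSpecies.M_MINUS_H:
            return neutral - m.proton
        if self is IonSpecies.M_MINUS_2H:
            return (neutral - 2 * m.proton) / 2
        if self is IonSpecies.M_PLUS_LI:
            return neutral + m.lithium_cation
        if self is IonSpecies.M_PLUS_FORMATE_MINUS_H:
            return neutral + m.formic_acid - m.proton
        raise ValueError(f"unsupported ion species: {self}")


class XGParseError(ValueError):
    """Raised for malformed xyloglucan structure strings."""


@dataclass(frozen=True)
class XGStructure:
    """An ordered xyloglucan oligosaccharide; index 0 is the non-reducing end.

    ``oxidation`` applies to the backbone glucosyl of the terminal unit the
    form belongs to (C4 forms: unit 0; C1 forms: the last unit).
    """

    units: tuple[str, ...]
    oxidation: OxForm = OxForm.NONE

    def __post_init__(self) -> None:
        if len(self.units) < 1:
            raise XGParseError("a structure needs at least one unit")
        for u in self.units:
            if u not in UNIT_TABLE:
                raise XGParseError(f"unknown Fry unit code {u!r}")
        object.__setattr__(self, "units", tuple(self.units))

    # -- formatting ---------------------------------------------------------
    @property
    def code(self) -> str:
        return _OX_PREFIX.get(self.oxidation, "") + "".join(self.units)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code

    @classmethod
    def parse(cls, code: str) -> "XGStructure":
        return parse_code(code)

    # -- composition and mass ----------------------------------------------
    @property
    def composition(self) -> Composition:
        h = p = d = 0
        for u in self.units:
            c = UNIT_TABLE[u]
            h += c.hexose
            p += c.pentose
            d += c.deoxyhexose
        return Composition(h, p, d)

    @property
    def neutral_mass(self) -> float:
        return (
            self.composition.residue_mass
            + MONOISOTOPIC.water
            + self.oxidation.mass_shift
        )

    def mz(self, ion: IonSpecies) -> float:
        return ion.ion_mz(self.neutral_mass)

    # -- helpers ------------------------------------------------------------
    def with_oxidation(self, form: OxForm) -> "XGStructure":
        return XGStructure(self.units, form)

    @property
    def dp(self) -> int:
        """Degree of polymerisation counted in backbone units."""
        return len(self.units)


_CODE_RE = re.compile(r"^(O4k:|O4g:|O1l:|O1a:|_O=G_)?([A-Za-z]*)$")


def parse_code(code: str) -> XGStructure:
    """Parse a Fry one-letter structure string.

    Accepts an optional oxidation prefix: ``O4k:`` (C4 keto; the literature
    style ``_O=G_`` is a synonym), ``O4g:`` (C4 gem-diol), ``O1l:`` (C1
    delta-lactone) or ``O1a:`` (C1 aldonic acid).
    """
    if not isinstance(code, str) or code == "":
        raise XGParseError("empty structure code")
    m = _CODE_RE.match(code)
    if m is None:
        raise XGParseError(f"malformed structure code {code!r}")
    prefix, body = m.groups()
    if body == "":
        raise XGParseError(f"structure code {code!r} has no units")
    for ch in body:
        if ch not in UNIT_TABLE:
            raise XGParseError(f"unknown Fry unit code {ch!r} in {code!r}")
    form = _PREFIX_OX[prefix] if prefix else OxForm.NONE
    return XGStructure(tuple(body), form)


def neutral_mass(s: XGStructure) -> float:
    """Monoisotopic neutral mass: residues + water + oxidation shift."""
    return s.neutral_mass


def mz(s: XGStructure, ion: IonSpecies) -> float:
    """m/z of a structure observed as the given ion species."""
    return s.mz(ion)


# ---------------------------------------------------------------------------
# isomer enumeration
# ---------------------------------------------------------------------------

def _unit_count_solutions(comp: Composition) -> list[dict[str, int]]:
    """All (G,X,L,F) unit-count vectors realising a residue composition."""
    h, p, d = comp
    if min(h, p, d) < 0:
        return []
    sols = []
    f = d
    for x in range(0, p - d + 1):
        l = p - d - x
        g = h - x - 2 * l - 2 * f
        if g >= 0:
            sols.append({"G": g, "X": x, "L": l, "F": f})
    return sols


def _multiset_permutations(counts: dict[str, int]) -> Iterable[tuple[str, ...]]:
    items = sorted(k for k, v in counts.items() for _ in range(v))
    if not items:
        return
    # distinct permutations of a small multiset
    seen_prefix: list[tuple[str, ...]] = []

    def rec(remaining: list[str], acc: tuple[str, ...]):
        if not remaining:
            yield acc
            return
        used = set()
        for i, u in enumerate(remaining):
            if u in used:
                continue
            used.add(u)
            yield from rec(remaining[:i] + remaining[i + 1 :], acc + (u,))

    yield from rec(items, ())


def fits_xxxg_repeat(units: Sequence[str]) -> bool:
    """True if ``units`` is a substring of an (SSSG)n repeat, S in {X,L,F}.

    Tamarind and black-currant xyloglucan are built from XXXG-type blocks:
    every fourth backbone unit is unbranched (G) and the rest substituted.
    A product string fits if some phase r places all its G units (and only
    them) at positions congruent to 3 (mod 4).
    """
    for r in range(4):
        ok = True
        for j, u in enumerate(units):
            at_g_slot = (j + r) % 4 == 3
            if (u == "G") != at_g_slot:
                ok = False
                break
        if ok:
            return True
    return False


def enumerate_structures(
    composition: tuple[int, int, int] | Composition,
    oxidation: OxForm = OxForm.NONE,
    grammar: str = "free",
) -> tuple[XGStructure, ...]:
    """Exact, duplicate-free set of structures matching a residue composition.

    Parameters
    ----------
    composition : (hexose, pentose, deoxyhexose) residue counts.
    oxidation : oxidation form applied to every enumerated structure.
    grammar : ``"free"`` (any unit string) or ``"xxxg"`` (substrings of an
        (SSSG)n repeat only).

    Infeasible compositions yield an empty tuple.
    """
    if grammar not in ("free", "xxxg"):
        raise ValueError(f"unknown grammar {grammar!r}")
    comp = Composition(*composition)
    out: list[XGStructure] = []
    for counts in _unit_count_solutions(comp):
        for units in _multiset_permutations(counts):
            if grammar == "xxxg" and not fits_xxxg_repeat(units):
                continue
            out.append(XGStructure(units, oxidation))
    return tuple(sorted(set(out), key=lambda s: s.code))


# ---------------------------------------------------------------------------
# mass lists
# ---------------------------------------------------------------------------

def canonical_code(comp: Composition) -> str:
    """A representative unit string for a composition (alphabetical order)."""
    for counts in _unit_count_solutions(comp):
        return "".join(
            u * counts[u] for u in ("F", "G", "L", "X") if counts[u]
        )
    return ""


def compositions_for_dp(
    dp_range: tuple[int, int], include_fucose: bool = False
) -> list[Composition]:
    """Residue compositions reachable with dp_min..dp_max backbone units."""
    lo, hi = dp_range
    if lo < 1 or hi < lo:
        raise ValueError("dp_range bounds must satisfy 1 <= lo <= hi")
    letters = "GXLF" if include_fucose else "GXL"
    seen: set[Composition] = set()
    for n in range(lo, hi + 1):
        for combo in itertools.combinations_with_replacement(letters, n):
            h = p = d = 0
            for u in combo:
                c = UNIT_TABLE[u]
                h += c.hexose
                p += c.pentose
                d += c.deoxyhexose
            seen.add(Composition(h, p, d))
    return sorted(seen)


def generate_mass_list(
    dp_range: tuple[int, int] = (1, 9),
    oxidation_forms: Sequence[OxForm] = (
        OxForm.NONE,
        OxForm.C4_KETO,
        OxForm.C1_ALDONIC,
    ),
    ion_kinds: Sequence[IonSpecies] = (IonSpecies.M_MINUS_H,),
    include_fucose: bool = False,
) -> pd.DataFrame:
    """Defined mass list: one row per (composition, form, ion kind, charge).

    Isomers share a row (compositions deduplicated); rows sorted by m/z.
    Columns: hexose, pentose, deoxyhexose, composition, example_code, form,
    ion, charge, mz.
    """
    rows = []
    for comp in compositions_for_dp(dp_range, include_fucose):
        base = comp.residue_mass + MONOISOTOPIC.water
        for form in oxidation_forms:
            neutral = base + form.mass_shift
            for ion in ion_kinds:
                rows.append(
                    {
                        "hexose": comp.hexose,
                        "pentose": comp.pentose,
                        "deoxyhexose": comp.deoxyhexose,
                        "composition": comp.label,
                        "example_code": canonical_code(comp),
                        "form": form.value,
                        "ion": ion.label,
                        "charge": ion.charge,
                        "mz": ion.ion_mz(neutral),
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "hexose",
            "pentose",
            "deoxyhexose",
            "composition",
            "example_code",
            "form",
            "ion",
            "charge",
            "mz",
        ],
    )
    return df.sort_values("mz", kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class AmbiguityGroup:
    """Rows of a mass list that collide within tolerance, plus the rule that
    disambiguates them downstream."""

    indices: tuple[int, ...]
    mz_values: tuple[float, ...]
    rule: str


_MINUS2_FORMS = {OxForm.C4_KETO.value, OxForm.C1_LACTONE.value}
_PLUS16_FORMS = {OxForm.C1_ALDONIC.value, OxForm.C4_GEMDIOL.value}


def flag_mass_ambiguities(
    table: pd.DataFrame, tolerance: float = 0.05
) -> list[AmbiguityGroup]:
    """Group mass-list rows whose m/z coincide within ``tolerance``.

    Each group is annotated with the downstream disambiguation rule:
    C1-oxidized (+16) vs formate adduct of a non-oxidized species is settled
    by the diagnostic -46 (formic acid) fragment; keto vs lactone (-2 forms
    of the same composition) only by fragment position.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    ordered = table.sort_values("mz", kind="mergesort")
    groups: list[list[int]] = []
    cur: list[int] = []
    prev_mz = None
    for idx, row in ordered.iterrows():
        if prev_mz is not None and row["mz"] - prev_mz <= tolerance:
            cur.append(idx)
        else:
            if len(cur) > 1:
                groups.append(cur)
            cur = [idx]
        prev_mz = row["mz"]
    if len(cur) > 1:
        groups.append(cur)

    out = []
    for g in groups:
        sub = table.loc[g]
        forms = set(sub["form"])
        ions = set(sub["ion"])
        has_formate = IonSpecies.M_PLUS_FORMATE_MINUS_H.label in ions
        if has_formate and forms & _PLUS16_FORMS:
            rule = "check -46 formic acid loss fragment"
        elif forms >= _MINUS2_FORMS and sub["composition"].nunique() == 1:
            rule = "mass-identical -2 forms; resolve by fragment position"
        else:
            rule = "co-isobaric; resolve by MS/MS fragments"
        out.append(
            AmbiguityGroup(
                indices=tuple(g),
                mz_values=tuple(float(x) for x in sub["mz"]),
                rule=rule,
            )
        )
    return out
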