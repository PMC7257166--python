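"""Cleavage-site profiling and LPMO mode-of-action classification.

An LPMO that attacks xyloglucan only at unbranched backbone glucosyls
leaves C4-oxidized products whose new non-reducing terminus is a G unit
("substitution-intolerant"); an enzyme that cleaves next to substituted
glucosyls leaves oxidized X/L/F termini ("substitution-tolerant").  The
tolerance index is the fraction of structurally localized oxidized termini
that are substituted:

    tolerance_index = (#X + #L + #F oxidized termini) / (all oxidized termini)

Products classified only at composition level (C1-oxidized species, which
co-elute and resist localization, or C4 products without an MS/MS-resolved
terminus) count as evidence of activity but not towards the index.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .annotate import AnnotationReport
from .core import XGStructure, parse_code

__all__ = [
    "CleavageProfile",
    "ModeCall",
    "build_profile",
    "profile_from_structures",
    "classify_mode",
    "MODE_INTOLERANT",
    "MODE_TOLERANT",
    "MODE_INACTIVE",
    "MODE_INDETERMINATE",
]

MODE_INTOLERANT = "Substitution-intolerant"
MODE_TOLERANT = "Substitution-tolerant"
MODE_INACTIVE = "Inactive"
MODE_INDETERMINATE = "Indeterminate"

_SUBSTITUTED = ("X", "L", "F")


@dataclass
class CleavageProfile:
    """Aggregated oxidized-terminus evidence for one digest."""

    terminus_counts: Counter = field(default_factory=Counter)
    c1_count: int = 0
    composition_only_count: int = 0
    nonoxidized_end_counts: Counter = field(default_factory=Counter)

    @property
    def localized_total(self) -> int:
        return sum(self.terminus_counts.values())

    @property
    def oxidized_total(self) -> int:
        return self.localized_total + self.c1_count + self.composition_only_count

    @property
    def tolerance_index(self) -> Optional[float]:
        """Fraction of localized oxidized termini on substituted units.

        ``None`` (undefined) when no terminus was localized.
        """
        total = self.localized_total
        if total == 0:
            return None
        return sum(self.terminus_counts[u] for u in _SUBSTITUTED) / total


def build_profile(report: AnnotationReport) -> CleavageProfile:
    """Tally oxidized termini from a digest annotation report.

    Each co-optimal C4-localized candidate counts once (co-eluting isomers
    are all reported, as in manual annotation); plus16 calls without a
    formate explanation count as composition-level C1 products; minus2
    calls that found no structural candidate count as composition-only
    oxidized products.
    """
    profile = CleavageProfile()
    for entry in report.entries:
        if entry.call.category == "minus2":
            structures = entry.co_optimal_structures
            if structures:
                for s in structures:
                    profile.terminus_counts[s.units[0]] += 1
                    profile.nonoxidized_end_counts[s.units[-1]] += 1
            else:
                profile.composition_only_count += 1
        elif entry.call.category == "plus16" and not entry.formate_adduct:
            profile.c1_count += 1
    return profile


def profile_from_structures(
    codes: Iterable[str | XGStructure],
    c1_count: int = 0,
    composition_only_count: int = 0,
) -> CleavageProfile:
    """Profile from a flat list of C4-oxidized structure strings.

    Useful for re-tallying published annotation tables.
    """
    profile = CleavageProfile(
        c1_count=c1_count, composition_only_count=composition_only_count
    )
    for code in codes:
        s = code if isinstance(code, XGStructure) else parse_code(code)
        if not s.oxidation.is_c4:
            raise ValueError(f"{s.code}: terminus tally needs a C4-oxidized form")
        profile.terminus_counts[s.units[0]] += 1
        profile.nonoxidized_end_counts[s.units[-1]] += 1
    return profile


@dataclass(frozen=True)
class ModeCall:
    """Auditable classification record."""

    label: str
    tolerance_index: Optional[float]
    terminus_counts: dict
    c1_count: int
    composition_only_count: int
    low: float
    high: float

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["terminus_counts"] = dict(self.terminus_counts)
        return json.dumps(d, indent=2, sort_keys=True)


def classify_mode(
    profile: CleavageProfile, low: float = 0.30, high: float = 0.50
) -> ModeCall:
    """Call the mode-of-action from a cleavage profile.

    Inactive when no oxidized product at all; substitution-intolerant when
    the tolerance index is at most ``low``; substitution-tolerant when at
    least ``high``; indeterminate otherwise (including active digests whose
    products were never structurally localized).
    """
    if not (0 <= low < high <= 1):
        raise ValueError("thresholds must satisfy 0 <= low < high <= 1")
    idx = profile.tolerance_index
    if profile.oxidized_total == 0:
        label = MODE_INACTIVE
    elif idx is None:
        label = MODE_INDETERMINATE
    elif idx <= low:
        label = MODE_INTOLERANT
    elif idx >= high:
        label = MODE_TOLERANT
    else:
        label = MODE_INDETERMINATE
    return ModeCall(
        label=label,
        tolerance_index=idx,
        terminus_counts=dict(profile.terminus_counts),
        c1_count=profile.c1_count,
        composition_only_count=profile.composition_only_count,
        low=low,
        high=high,
    )
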