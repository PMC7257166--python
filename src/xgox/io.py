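"""File I/O: MGF peak lists, FASTA alignments, Newick trees, TSV reports."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from pyteomics import mgf as _mgf
from skbio import TreeNode

from .annotate import AnnotationReport, Spectrum

__all__ = [
    "MGFError",
    "read_mgf",
    "write_mgf",
    "read_fasta_msa",
    "write_fasta_msa",
    "write_newick",
    "write_report",
    "RunConfig",
]


class MGFError(ValueError):
    """Malformed MGF input; the message names the offending line."""


def _validate_mgf_text(path: Path) -> None:
    """Structural lint of an MGF file so errors can name line numbers
    (the parser itself is pyteomics)."""
    in_block = False
    has_pepmass = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped == "BEGIN IONS":
            if in_block:
                raise MGFError(f"line {lineno}: nested BEGIN IONS")
            in_block, has_pepmass = True, False
        elif stripped == "END IONS":
            if not in_block:
                raise MGFError(f"line {lineno}: END IONS without BEGIN IONS")
            if not has_pepmass:
                raise MGFError(f"line {lineno}: spectrum block missing PEPMASS")
            in_block = False
        elif in_block:
            if "=" in stripped:
                if stripped.upper().startswith("PEPMASS="):
                    has_pepmass = True
                continue
            fields = stripped.split()
            if len(fields) < 2:
                raise MGFError(f"line {lineno}: malformed peak line {stripped!r}")
            try:
                float(fields[0]), float(fields[1])
            except ValueError:
                raise MGFError(
                    f"line {lineno}: non-numeric peak line {stripped!r}"
                ) from None
    if in_block:
        raise MGFError("unterminated spectrum block (missing END IONS)")


def read_mgf(path) -> list[Spectrum]:
    """Read an MGF peak-list file into Spectrum objects."""
    path = Path(path)
    _validate_mgf_text(path)
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            pepmass = params["pepmass"][0]
            charge_list = params.get("charge")
            charge = abs(int(charge_list[0])) if charge_list else 1
            polarity = "-"
            if charge_list and int(charge_list[0]) > 0:
                polarity = "+"
            spectra.append(
                Spectrum(
                    precursor_mz=float(pepmass),
                    precursor_charge=charge,
                    polarity=polarity,
                    peaks=list(
                        zip(
                            entry["m/z array"].tolist(),
                            entry["intensity array"].tolist(),
                        )
                    ),
                    spectrum_id=str(params.get("title", f"spectrum{i}")),
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra to MGF (negative-mode charges carry a '-' sign)."""
    entries = []
    for i, sp in enumerate(spectra):
        sign = -1 if sp.polarity == "-" else 1
        entries.append(
            {
                "m/z array": [mz_ for mz_, _ in sp.peaks],
                "intensity array": [inten for _, inten in sp.peaks],
                "params": {
                    "title": sp.spectrum_id or f"spectrum{i}",
                    "pepmass": sp.precursor_mz,
                    "charge": [sign * sp.precursor_charge],
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_fasta_msa(path) -> MultipleSeqAlignment:
    """Read a FASTA multiple sequence alignment; ragged input is an error."""
    try:
        return AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise ValueError(f"{path}: not a valid FASTA alignment ({exc})") from exc


def write_fasta_msa(msa: MultipleSeqAlignment, path) -> None:
    AlignIO.write(msa, str(path), "fasta")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def write_report(report: AnnotationReport | pd.DataFrame, path) -> None:
    """TSV export of an annotation report (or any DataFrame)."""
    df = report.to_dataframe() if isinstance(report, AnnotationReport) else report
    df.to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Pipeline parameters; every default is documented in docs/methods.md."""

    fragment_tolerance: float = 0.3  # Da, ion-trap MS/MS matching
    precursor_tolerance: float = 0.3  # Da
    intensity_floor: float = 0.005  # fraction of base peak
    diagnostic_weight: float = 3.0
    grammar: str = "xxxg"
    mode_low: float = 0.30  # tolerance-index threshold for "intolerant"
    mode_high: float = 0.50  # threshold for "tolerant"
    dp_min: int = 1
    dp_max: int = 9
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)
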