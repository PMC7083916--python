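"""Theoretical glycosidic fragments in Domon–Costello nomenclature.

B/C ions retain the non-reducing end (index counted from the NRE), Y/Z
ions retain the reducing end and its tag (index counted from the RE).
Neutral-mass bookkeeping uses the residue-sum convention:

    B_i = sum(residues 1..i)            C_i = B_i + H2O
    Y_j = sum(last j residues) + H2O + tag_delta
    Z_j = Y_j - H2O

so that B_i + Y_(n-i) equals the precursor neutral mass exactly.  For an
untagged (free reducing end) saccharide the full-length B_n ion — the
precursor minus the anomeric hydroxyl as water — is also emitted, which
is how full-length "B" ions of untagged standards are reported.
Sulfate-loss satellites are neutral-loss variants flagged as such;
cross-ring A/X fragments are not modelled.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass

from . import chem
from .chem import Composition
from .errors import FragmentError
from .saccharide import NO_TAG, ReducingEndTag, SaccharideSequence

SERIES = ("B", "C", "Y", "Z")
NRE_SERIES = ("B", "C")
RE_SERIES = ("Y", "Z")

_LABEL_RE = re.compile(
    r"^(?:\[)?(B|C|Y|Z|I)(\d+)(?:[-−](?:(\d+))?SO3)?"
    r"(?:[-−](\d+)H\](\d+)[-−])?$"
)


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical fragment with its residue run and charge state."""

    series: str
    index: int
    residues: tuple
    tag: ReducingEndTag = NO_TAG
    charge: int = 1
    so3_losses: int = 0

    def __post_init__(self):
        if self.series not in SERIES + ("internal",):
            raise FragmentError(f"unknown series {self.series!r}")
        if self.charge < 1:
            raise FragmentError("charge must be >= 1")
        if self.so3_losses < 0:
            raise FragmentError("so3_losses must be >= 0")
        max_losses = sum(r.so3_count for r in self.residues)
        if self.so3_losses > max_losses:
            raise FragmentError(
                f"{self.so3_losses} SO3 losses exceed the {max_losses} "
                "sulfates on the fragment"
            )
        object.__setattr__(self, "residues", tuple(self.residues))

    @property
    def satellite(self) -> bool:
        """True for sulfate-loss satellites (corroborating evidence only)."""
        return self.so3_losses > 0

    @property
    def neutral_composition(self) -> Composition:
        total = Composition()
        for r in self.residues:
            total = total + r.composition
        if self.series in ("C", "Y"):
            total = total + chem.H2O
        if self.series in RE_SERIES:
            total = total + self.tag.composition_delta
        for _ in range(self.so3_losses):
            total = total - chem.SO3
        return total

    @property
    def neutral_mass(self) -> float:
        return chem.monoisotopic_mass(self.neutral_composition)

    @property
    def mz(self) -> float:
        return chem.mz_from_neutral(self.neutral_mass, self.charge)

    @property
    def label(self) -> str:
        return fragment_label(self)

    def charged_label(self) -> str:
        base = fragment_label(self)
        if self.charge == 1:
            return base
        return f"[{base}-{self.charge}H]{self.charge}-"


def fragment_label(f: FragmentIon) -> str:
    """Canonical label, e.g. ``"B3"``, ``"Y2-SO3"``, ``"I2"`` (internal)."""
    series = "I" if f.series == "internal" else f.series
    base = f"{series}{f.index}"
    if f.so3_losses == 1:
        base += "-SO3"
    elif f.so3_losses > 1:
        base += f"-{f.so3_losses}SO3"
    return base


def parse_fragment_label(label: str) -> dict:
    """Inverse of the label formats, accepting ASCII ``-`` or U+2212.

    Returns a dict with ``series``, ``index``, ``so3_losses``, ``charge``
    (charge 1 unless a ``[..-zH]z-`` wrapper is present).
    """
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise FragmentError(f"cannot parse fragment label {label!r}")
    series = "internal" if m.group(1) == "I" else m.group(1)
    losses = 0
    if "SO3" in label:
        losses = int(m.group(3)) if m.group(3) else 1
    charge = int(m.group(5)) if m.group(5) else 1
    return {
        "series": series,
        "index": int(m.group(2)),
        "so3_losses": losses,
        "charge": charge,
    }


def fragment_residues(seq: SaccharideSequence, series: str, index: int) -> tuple:
    """Residue run of a named glycosidic fragment of *seq*.

    B/C indices run 1..n-1 from the NRE (1..n when the reducing end is
    untagged); Y/Z indices run 1..n-1 from the RE.
    """
    n = len(seq)
    if series in NRE_SERIES:
        top = n if seq.tag.name == "none" else n - 1
        if not 1 <= index <= top:
            raise FragmentError(f"{series}{index} out of range for dp{n}")
        return seq.residues[:index]
    if series in RE_SERIES:
        if not 1 <= index <= n - 1:
            raise FragmentError(f"{series}{index} out of range for dp{n}")
        return seq.residues[n - index :]
    raise FragmentError(f"unknown series {series!r}")


def make_fragment(
    seq: SaccharideSequence,
    series: str,
    index: int,
    charge: int = 1,
    so3_losses: int = 0,
) -> FragmentIon:
    """Build one fragment of *seq* by series and index."""
    return FragmentIon(
        series,
        index,
        fragment_residues(seq, series, index),
        tag=seq.tag if series in RE_SERIES else NO_TAG,
        charge=charge,
        so3_losses=so3_losses,
    )


def precursor_ion(seq: SaccharideSequence, charge: int = 1) -> FragmentIon:
    """The intact precursor, represented as a full-length C ion.

    C_n carries all residues plus water plus the tag, i.e. the intact
    neutral molecule; handy for uniform m/z bookkeeping.
    """
    return FragmentIon("Y", len(seq), seq.residues, tag=seq.tag, charge=charge)


def generate_fragments(
    seq: SaccharideSequence,
    series_set=SERIES,
    max_charge: int = 1,
    max_so3_losses: int = 1,
    include_internal: bool = False,
    include_full_b: bool = True,
) -> list:
    """All (series, index, loss, charge) fragments of *seq*, each once.

    ``include_full_b`` additionally emits the full-length B ion for
    untagged sequences (loss of the anomeric hydroxyl as water).
    """
    if len(seq) < 2:
        raise FragmentError("fragmentation requires at least two residues")
    if max_charge < 1:
        raise FragmentError("max_charge must be >= 1")
    series_set = tuple(series_set)
    if not series_set:
        raise FragmentError("series_set must not be empty")
    for s in series_set:
        if s not in SERIES:
            raise FragmentError(f"unknown series {s!r}")
    n = len(seq)
    out = []

    def emit(series, index):
        residues = fragment_residues(seq, series, index)
        n_sulf = sum(r.so3_count for r in residues)
        for loss in range(0, min(max_so3_losses, n_sulf) + 1):
            for z in range(1, max_charge + 1):
                out.append(
                    FragmentIon(
                        series,
                        index,
                        residues,
                        tag=seq.tag if series in RE_SERIES else NO_TAG,
                        charge=z,
                        so3_losses=loss,
                    )
                )

    for series in series_set:
        top = n - 1
        if series == "B" and seq.tag.name == "none" and include_full_b:
            top = n
        for index in range(1, top + 1):
            emit(series, index)

    if include_internal:
        # contiguous runs touching neither terminus
        for start in range(1, n - 1):
            for stop in range(start + 1, n):
                residues = seq.residues[start:stop]
                for z in range(1, max_charge + 1):
                    out.append(
                        FragmentIon(
                            "internal", stop - start, residues, charge=z
                        )
                    )
    return out


def fragment_table(fragments) -> str:
    """CSV rendering of a fragment list (label, masses, composition)."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(
        [
            "label",
            "series",
            "index",
            "so3_losses",
            "charge",
            "neutral_mass",
            "mz",
            "composition",
        ]
    )
    for f in fragments:
        w.writerow(
            [
                f.charged_label(),
                f.series,
                f.index,
                f.so3_losses,
                f.charge,
                f"{f.neutral_mass:.4f}",
                f"{f.mz:.4f}",
                chem.formula(f.neutral_composition),
            ]
        )
    return buf.getvalue()
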