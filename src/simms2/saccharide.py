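"""Heparan-sulfate saccharide sequences: grammar, validation and masses.

HS chains alternate a uronic acid (GlcA, its C5 epimer IdoA, or the
lyase-generated unsaturated dUA at the non-reducing end) with a
glucosamine whose amine is N-acetylated, N-sulfated or free.  O-sulfates
sit at C2 of the uronic acid and at C3/C6 of the glucosamine.  Sequences
are written non-reducing end first with hyphen-separated tokens in the
field's standard shorthand, e.g. ``dUA-GlcNS-IdoA2S-GlcNS3S`` (the
unicode form ``ΔUA`` is accepted on input), optionally ending in a
reducing-end tag token ``R1``/``R2``/``R3``.

Synthetic standards may start with a glucosamine instead of a uronic
acid; parsing such sequences requires ``allow_leading_glcn=True`` so
that accidental reversals are still caught.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from . import chem
from .chem import Composition
from .errors import GrammarError

URONIC_KINDS = ("DeltaHexA", "GlcA", "IdoA")
GLCN_KIND = "GlcN"
N_STATES = ("acetyl", "sulfo", "free")

_N_STATE_TOKEN = {"acetyl": "Ac", "sulfo": "S", "free": ""}
_URONIC_TOKEN = {"DeltaHexA": "dUA", "GlcA": "GlcA", "IdoA": "IdoA"}
_URONIC_TOKEN_UNICODE = {"DeltaHexA": "ΔUA", "GlcA": "GlcA", "IdoA": "IdoA"}

_URONIC_RE = re.compile(r"^(ΔUA|dUA|GlcA|IdoA)(2S)?$")
_GLCN_RE = re.compile(r"^GlcN(Ac|S)?(3S)?(6S)?$")
_BRACKET_RE = re.compile(r"\[([^\[\]]+)\]_?(\d+)")


@dataclass(frozen=True)
class Residue:
    """One monosaccharide unit.

    ``kind`` is ``DeltaHexA``/``GlcA``/``IdoA`` for uronic acids or
    ``GlcN`` for glucosamine; ``n_state`` applies to GlcN only;
    ``sulfation`` holds O-sulfate positions ({"2S"} on uronic kinds,
    subset of {"3S", "6S"} on GlcN).
    """

    kind: str
    n_state: str | None = None
    sulfation: frozenset = frozenset()

    def __post_init__(self):
        if self.kind in URONIC_KINDS:
            if self.n_state is not None:
                raise GrammarError(f"{self.kind} carries no N-group")
            if not self.sulfation <= {"2S"}:
                raise GrammarError(
                    f"illegal O-sulfation {sorted(self.sulfation)} on {self.kind}"
                )
        elif self.kind == GLCN_KIND:
            if self.n_state not in N_STATES:
                raise GrammarError(f"GlcN requires an N-state, got {self.n_state!r}")
            if not self.sulfation <= {"3S", "6S"}:
                raise GrammarError(
                    f"illegal O-sulfation {sorted(self.sulfation)} on GlcN"
                )
        else:
            raise GrammarError(f"unknown residue kind {self.kind!r}")
        object.__setattr__(self, "sulfation", frozenset(self.sulfation))

    @property
    def is_uronic(self) -> bool:
        return self.kind in URONIC_KINDS

    @property
    def so3_count(self) -> int:
        """Number of SO3 groups on this residue (N- plus O-sulfates)."""
        return len(self.sulfation) + (1 if self.n_state == "sulfo" else 0)

    @property
    def composition(self) -> Composition:
        if self.kind == "DeltaHexA":
            base = chem.DELTA_HEXA
        elif self.kind in ("GlcA", "IdoA"):
            base = chem.HEXA
        elif self.n_state == "acetyl":
            base = chem.HEXNAC
        else:
            base = chem.HEXN
        n_so3 = len(self.sulfation) + (1 if self.n_state == "sulfo" else 0)
        out = Composition(base)
        for _ in range(n_so3):
            out = out + chem.SO3
        return out

    def token(self, unicode_delta: bool = False) -> str:
        if self.is_uronic:
            names = _URONIC_TOKEN_UNICODE if unicode_delta else _URONIC_TOKEN
            return names[self.kind] + ("2S" if "2S" in self.sulfation else "")
        suffix = ("3S" if "3S" in self.sulfation else "") + (
            "6S" if "6S" in self.sulfation else ""
        )
        return "GlcN" + _N_STATE_TOKEN[self.n_state] + suffix


@dataclass(frozen=True)
class ReducingEndTag:
    """Monovalent aglycone group replacing the anomeric hydroxyl hydrogen.

    ``mass_delta`` relative to the free reducing end is (group - H); for
    the untagged case the delta is zero.
    """

    name: str
    group_formula: str | None = None

    def __post_init__(self):
        if self.name == "none" and self.group_formula is not None:
            raise GrammarError("untagged reducing end takes no group formula")
        if self.name != "none" and not self.group_formula:
            raise GrammarError(f"tag {self.name!r} requires a group formula")

    @property
    def composition_delta(self) -> Composition:
        if self.name == "none":
            return Composition()
        return chem.comp(self.group_formula) - chem.comp("H")

    @property
    def mass_delta(self) -> float:
        return chem.monoisotopic_mass(self.composition_delta)


NO_TAG = ReducingEndTag("none")

#: Built-in tags.  R2's group formula is as stated for the methoxyphenyl
#: glycoside; R1 (aminopentyl linker) and R3 (p-nitrophenyl) follow from
#: the named chemistry and can be overridden with custom tags.
TAGS = {
    "none": NO_TAG,
    "R1": ReducingEndTag("R1", "C5H12N"),
    "R2": ReducingEndTag("R2", "C7H7O"),
    "R3": ReducingEndTag("R3", "C6H4NO2"),
}


@dataclass(frozen=True)
class SaccharideSequence:
    """Ordered residues, non-reducing end (NRE) first, plus an RE tag."""

    residues: tuple
    tag: ReducingEndTag = NO_TAG
    label: str | None = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "residues", tuple(self.residues))
        if not self.residues:
            raise GrammarError("sequence must contain at least one residue")
        for i, r in enumerate(self.residues):
            if i and r.is_uronic == self.residues[i - 1].is_uronic:
                raise GrammarError(
                    f"residues {i} and {i + 1} violate uronic/GlcN alternation"
                )
            if r.kind == "DeltaHexA" and i != 0:
                raise GrammarError("dUA is only valid at the non-reducing end")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def leading_glcn(self) -> bool:
        return not self.residues[0].is_uronic

    @property
    def so3_count(self) -> int:
        return sum(r.so3_count for r in self.residues)

    def to_record(self) -> dict:
        return {
            "residues": [
                {
                    "kind": r.kind,
                    "n_state": r.n_state,
                    "sulfation": sorted(r.sulfation),
                }
                for r in self.residues
            ],
            "tag": self.tag.name,
            "tag_formula": self.tag.group_formula,
            "label": self.label,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "SaccharideSequence":
        residues = tuple(
            Residue(r["kind"], r.get("n_state"), frozenset(r.get("sulfation", ())))
            for r in rec["residues"]
        )
        name = rec.get("tag", "none")
        tag = TAGS.get(name) or ReducingEndTag(name, rec.get("tag_formula"))
        return cls(residues, tag, rec.get("label"))

    def to_json(self) -> str:
        return json.dumps(self.to_record(), sort_keys=True)


def _parse_token(token: str) -> Residue:
    m = _URONIC_RE.match(token)
    if m:
        name = m.group(1)
        kind = {"dUA": "DeltaHexA", "ΔUA": "DeltaHexA"}.get(name, name)
        sulf = frozenset({"2S"} if m.group(2) else ())
        return Residue(kind, None, sulf)
    m = _GLCN_RE.match(token)
    if m:
        n_state = {"Ac": "acetyl", "S": "sulfo", None: "free"}[m.group(1)]
        sulf = set()
        if m.group(2):
            sulf.add("3S")
        if m.group(3):
            sulf.add("6S")
        return Residue(GLCN_KIND, n_state, frozenset(sulf))
    raise GrammarError(f"unknown or illegal residue token {token!r}")


def _expand_brackets(text: str) -> str:
    while True:
        m = _BRACKET_RE.search(text)
        if not m:
            return text
        unit, n = m.group(1), int(m.group(2))
        text = text[: m.start()] + "-".join([unit] * n) + text[m.end() :]


def parse_sequence(
    text: str,
    *,
    allow_leading_glcn: bool = False,
    label: str | None = None,
) -> SaccharideSequence:
    """Parse a grammar string into a validated :class:`SaccharideSequence`.

    Bracketed repeats are expanded first, so
    ``"GlcNAc6S-[IdoA-GlcNAc6S]3-IdoA-R2"`` is accepted.  A leading
    glucosamine is an error unless ``allow_leading_glcn`` is set.
    """
    if not text or not text.strip():
        raise GrammarError("empty sequence string")
    tokens = [t for t in _expand_brackets(text.strip()).split("-") if t]
    tag = NO_TAG
    if tokens and (tokens[-1] in TAGS or tokens[-1].startswith("R")):
        if tokens[-1] in TAGS:
            tag = TAGS[tokens[-1]]
            tokens = tokens[:-1]
        elif re.fullmatch(r"R\d+", tokens[-1]):
            raise GrammarError(f"unknown reducing-end tag {tokens[-1]!r}")
    if not tokens:
        raise GrammarError("sequence contains only a tag token")
    residues = tuple(_parse_token(t) for t in tokens)
    if not residues[0].is_uronic and not allow_leading_glcn:
        raise GrammarError(
            "sequence starts with a glucosamine; pass allow_leading_glcn=True "
            "if this orientation is intended"
        )
    return SaccharideSequence(residues, tag, label)


def format_sequence(seq: SaccharideSequence, *, unicode_delta: bool = False) -> str:
    """Inverse of :func:`parse_sequence` (token-for-token)."""
    tokens = [r.token(unicode_delta=unicode_delta) for r in seq.residues]
    if seq.tag.name != "none":
        tokens.append(seq.tag.name)
    return "-".join(tokens)


def composition(seq: SaccharideSequence) -> Composition:
    """Neutral elemental composition: residues + H2O + tag delta."""
    total = Composition(chem.H2O)
    for r in seq.residues:
        total = total + r.composition
    return total + seq.tag.composition_delta


def neutral_mass(seq: SaccharideSequence, monoisotopic: bool = True) -> float:
    """Neutral mass in Da of the intact (tagged) saccharide."""
    c = composition(seq)
    return chem.monoisotopic_mass(c) if monoisotopic else chem.average_mass(c)


def mz(mass: float, charge: int, polarity: str = "negative") -> float:
    """Negative-mode m/z for a neutral mass; [M - zH]^z-."""
    if polarity != "negative":
        raise ValueError("only negative-mode ionization is modelled")
    return chem.mz_from_neutral(mass, charge)
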