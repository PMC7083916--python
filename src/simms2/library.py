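"""CCS reference library of defined HS standards.

A :class:`LibraryRegistry` stores a roster of standards (id, structure
where known) and CCS entries keyed by (standard id, ion, charge).  The
ion is ``"precursor"`` or a fragment label such as ``"B2"``; charges the
source did not state are stored as unspecified (``None``) and matched
permissively.  CCS values are kept exactly as printed (integer Å^2 for
the packaged data); queries never mutate the registry.

Libraries round-trip through a CSV schema
``standard_id,sequence,ion,charge,ccs_A2,provenance`` (roster-only rows
use ion ``structure`` with an empty CCS field) and a JSON mirror.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field

from . import _paper_data, chem
from .errors import FragmentError, GrammarError, LibraryError
from .fragmentation import (
    FragmentIon,
    fragment_residues,
    parse_fragment_label,
)
from .saccharide import (
    NO_TAG,
    SaccharideSequence,
    format_sequence,
    parse_sequence,
)

PRECURSOR = "precursor"
STRUCTURE = "structure"

CSV_HEADER = "standard_id,sequence,ion,charge,ccs_A2,provenance"


def _natural_key(standard_id: str):
    m = re.fullmatch(r"#(\d+)", standard_id)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, standard_id)


@dataclass(frozen=True)
class LibraryEntry:
    """One CCS record: (standard, ion, charge) -> Å^2."""

    standard_id: str
    ion: str
    ccs: float
    charge: int | None = None
    provenance: str = ""

    def __post_init__(self):
        if self.ccs <= 0:
            raise LibraryError(f"CCS must be positive, got {self.ccs}")
        if not self.standard_id:
            raise LibraryError("entry requires a standard id")
        if self.ion != PRECURSOR:
            parse_fragment_label(self.ion)  # validates the label

    @property
    def key(self):
        return (self.standard_id, self.ion, self.charge)


@dataclass(frozen=True)
class StandardRecord:
    """Roster entry for one standard; sequence may be unknown."""

    standard_id: str
    sequence: SaccharideSequence | None = None
    description: str = ""


@dataclass
class LibraryRegistry:
    """Set of CCS entries plus the standards roster, conflict-checked."""

    entries: dict = field(default_factory=dict)
    standards: dict = field(default_factory=dict)

    def add_standard(self, record: StandardRecord) -> None:
        old = self.standards.get(record.standard_id)
        if old is not None and old.sequence is not None and record.sequence is not None:
            if format_sequence(old.sequence) != format_sequence(record.sequence):
                raise LibraryError(
                    f"conflicting sequences for standard {record.standard_id}"
                )
        if old is not None and record.sequence is None:
            return
        if old is not None and not record.description:
            record = StandardRecord(
                record.standard_id, record.sequence, old.description
            )
        self.standards[record.standard_id] = record

    def add(self, entry: LibraryEntry) -> None:
        if entry.key in self.entries:
            raise LibraryError(f"duplicate library key {entry.key}")
        seq = self.sequence_of(entry.standard_id)
        if seq is not None and entry.ion != PRECURSOR:
            spec = parse_fragment_label(entry.ion)
            # raises if the index is inconsistent with the sequence length
            fragment_residues(seq, spec["series"], spec["index"])
        self.entries[entry.key] = entry
        if entry.standard_id not in self.standards:
            self.standards[entry.standard_id] = StandardRecord(entry.standard_id)

    def sequence_of(self, standard_id: str) -> SaccharideSequence | None:
        rec = self.standards.get(standard_id)
        return rec.sequence if rec else None

    def ccs(self, standard_id: str, ion: str = PRECURSOR, charge=None) -> float:
        """CCS of one entry; charge is matched permissively when omitted."""
        hits = [
            e
            for e in self.entries.values()
            if e.standard_id == standard_id
            and e.ion == ion
            and (charge is None or e.charge is None or e.charge == charge)
        ]
        if not hits:
            raise LibraryError(f"no entry for ({standard_id}, {ion}, {charge})")
        if len(hits) > 1:
            raise LibraryError(f"ambiguous entry for ({standard_id}, {ion})")
        return hits[0].ccs

    def entry_fragment(self, entry: LibraryEntry) -> FragmentIon | None:
        """Resolve an entry's ion against its standard's sequence.

        Returns the theoretical fragment (or full-length precursor-like
        ion) with residues, or None when the structure is unknown.
        """
        seq = self.sequence_of(entry.standard_id)
        if seq is None:
            return None
        if entry.ion == PRECURSOR:
            return FragmentIon(
                "Y", len(seq), seq.residues, tag=seq.tag,
                charge=entry.charge or 1,
            )
        spec = parse_fragment_label(entry.ion)
        tag = seq.tag if spec["series"] in ("Y", "Z") else NO_TAG
        return FragmentIon(
            spec["series"],
            spec["index"],
            fragment_residues(seq, spec["series"], spec["index"]),
            tag=tag,
            charge=entry.charge or spec["charge"],
            so3_losses=spec["so3_losses"],
        )

    def query(
        self,
        mass: float | None = None,
        ppm: float = 10.0,
        ion: str | None = None,
        series: str | None = None,
        index: int | None = None,
        charge: int | None = None,
        ccs: float | None = None,
        ccs_tol: float = 0.0,
        standard_id: str | None = None,
    ) -> list:
        """Entries passing every supplied filter, sorted by |ΔCCS|.

        The mass filter compares the entry ion's neutral mass (resolved
        from its standard's sequence) within ±ppm; entries whose
        structure is unknown cannot mass-match and are dropped by it.
        """
        if all(
            v is None
            for v in (mass, ion, series, index, charge, ccs, standard_id)
        ):
            raise LibraryError("query requires at least one filter")
        out = []
        for e in sorted(self.entries.values(), key=lambda e: (
            _natural_key(e.standard_id), e.ion, e.charge or 0
        )):
            if standard_id is not None and e.standard_id != standard_id:
                continue
            if ion is not None and e.ion != ion:
                continue
            if charge is not None and e.charge is not None and e.charge != charge:
                continue
            if series is not None or index is not None:
                if e.ion == PRECURSOR:
                    continue
                spec = parse_fragment_label(e.ion)
                if series is not None and spec["series"] != series:
                    continue
                if index is not None and spec["index"] != index:
                    continue
            if ccs is not None and abs(e.ccs - ccs) > ccs_tol:
                continue
            if mass is not None:
                frag = self.entry_fragment(e)
                if frag is None:
                    continue
                if abs(chem.ppm_error(mass, frag.neutral_mass)) > ppm:
                    continue
            out.append(e)
        if ccs is not None:
            out.sort(key=lambda e: (abs(e.ccs - ccs), _natural_key(e.standard_id)))
        return out

    def merge(self, other: "LibraryRegistry") -> "LibraryRegistry":
        """New registry holding both; duplicate keys must agree exactly."""
        out = LibraryRegistry()
        for reg in (self, other):
            for rec in reg.standards.values():
                out.add_standard(rec)
        for reg in (self, other):
            for e in reg.entries.values():
                if e.key in out.entries:
                    if out.entries[e.key].ccs != e.ccs:
                        raise LibraryError(f"conflicting CCS for key {e.key}")
                    continue
                out.add(e)
        return out

    def copy(self) -> "LibraryRegistry":
        return LibraryRegistry(dict(self.entries), dict(self.standards))

    # ---- serialization -------------------------------------------------

    def _sorted_rows(self):
        rows = []
        for sid in sorted(self.standards, key=_natural_key):
            rec = self.standards[sid]
            seq = format_sequence(rec.sequence) if rec.sequence else ""
            rows.append([sid, seq, STRUCTURE, "", "", rec.description])
        for key in sorted(
            self.entries, key=lambda k: (_natural_key(k[0]), k[1], k[2] or 0)
        ):
            e = self.entries[key]
            rec = self.standards.get(e.standard_id)
            seq = format_sequence(rec.sequence) if rec and rec.sequence else ""
            ccs = f"{int(e.ccs)}" if float(e.ccs).is_integer() else f"{e.ccs}"
            rows.append(
                [e.standard_id, seq, e.ion,
                 "" if e.charge is None else str(e.charge), ccs, e.provenance]
            )
        return rows

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(CSV_HEADER.split(","))
        w.writerows(self._sorted_rows())
        return buf.getvalue()

    def to_json(self) -> str:
        rows = [
            dict(zip(CSV_HEADER.split(","), row)) for row in self._sorted_rows()
        ]
        return json.dumps({"entries": rows}, indent=1, sort_keys=True) + "\n"


def _registry_from_rows(rows) -> LibraryRegistry:
    reg = LibraryRegistry()
    for lineno, row in rows:
        sid = row.get("standard_id", "").strip()
        seq_text = row.get("sequence", "").strip()
        ion = row.get("ion", "").strip()
        charge = row.get("charge", "").strip()
        ccs = row.get("ccs_A2", "").strip()
        prov = row.get("provenance", "").strip()
        if not sid or not ion:
            raise LibraryError(f"row {lineno}: standard_id and ion are required")
        try:
            seq = (
                parse_sequence(seq_text, allow_leading_glcn=True, label=sid)
                if seq_text
                else None
            )
            if ion == STRUCTURE:
                reg.add_standard(StandardRecord(sid, seq, prov))
                continue
            if seq is not None:
                reg.add_standard(StandardRecord(sid, seq))
            entry = LibraryEntry(
                sid,
                ion,
                float(ccs),
                None if charge == "" else int(charge),
                prov,
            )
            reg.add(entry)
        except (LibraryError, GrammarError, FragmentError) as exc:
            raise LibraryError(f"row {lineno}: {exc}") from exc
        except ValueError as exc:
            raise LibraryError(f"row {lineno}: malformed value ({exc})") from exc
    return reg


def load_library(path) -> LibraryRegistry:
    """Load a registry from a ``.csv`` or ``.json`` library file."""
    text = open(path, encoding="utf-8").read()
    if str(path).endswith(".json"):
        rows = json.loads(text)["entries"]
        return _registry_from_rows((i + 1, r) for i, r in enumerate(rows))
    lines = io.StringIO(text)
    reader = csv.DictReader(lines)
    if reader.fieldnames != CSV_HEADER.split(","):
        raise LibraryError(
            f"bad header {reader.fieldnames}; expected {CSV_HEADER}"
        )
    return _registry_from_rows((i + 2, r) for i, r in enumerate(reader))


def write_library(reg: LibraryRegistry, path) -> None:
    """Write a registry to CSV or JSON; write→load→write is byte-stable."""
    data = reg.to_json() if str(path).endswith(".json") else reg.to_csv()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(data)


def builtin_paper_library() -> LibraryRegistry:
    """The packaged registry of published standards and CCS values."""
    reg = LibraryRegistry()
    for sid, (text, desc) in _paper_data.STANDARD_SEQUENCES.items():
        seq = (
            parse_sequence(text, allow_leading_glcn=True, label=sid)
            if text
            else None
        )
        reg.add_standard(StandardRecord(sid, seq, desc))
    for sid, ccs in _paper_data.PRECURSOR_CCS.items():
        reg.add(
            LibraryEntry(sid, PRECURSOR, ccs, None, _paper_data.PRECURSOR_PROVENANCE)
        )
    for sid, ion, ccs, prov in _paper_data.FRAGMENT_CCS:
        reg.add(LibraryEntry(sid, ion, ccs, None, prov))
    return reg
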