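"""Shotgun overlap sequencing of HS saccharides from IMMS observations.

The pipeline mirrors the three-dimensional identification strategy —
mass, fragmentation and ion mobility:

1. ``infer_composition``  — bounded integer decomposition of the
   precursor mass into residue / acetyl / sulfate / tag counts;
2. ``enumerate_candidates`` — exhaustive isomer expansion of a
   composition (or of a disaccharide-unit table) under the alternation
   and dUA-at-NRE rules, with each saturated uronic acid expanded to
   both GlcA and IdoA epimers where unresolved;
3. ``match_observations`` — for every observed (m/z, charge, CCS)
   fragment, library entries that agree in mass AND CCS and whose own
   fragment agrees residue-for-residue with the candidate's
   prefix/suffix, so a match transfers sequence information from the
   standard to the unknown;
4. ``sequence`` — coverage scoring over the n-1 cleavage sites and an
   explicit verdict.

A matched B_i/C_i ion confirms residues 1..i and is counted as covering
cleavage sites 1..i; Y_j/Z_j cover sites n-j..n-1.  A matched precursor
CCS identifies the intact structure and covers every site.  Sulfate-loss
satellites corroborate but never cover a site on their own.  Candidates
are ranked by (covered sites, matched observations); the verdict is
``unambiguous`` only when a single candidate strictly leads that
ranking — two epimer variants that no CCS evidence separates always tie,
keeping GlcA/IdoA honesty.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

from . import chem
from .errors import (
    CandidateCapError,
    ConstraintError,
    EmptyLibraryError,
    SimmsError,
)
from .fragmentation import FragmentIon
from .library import PRECURSOR, LibraryEntry, LibraryRegistry
from .saccharide import (
    NO_TAG,
    TAGS,
    GLCN_KIND,
    ReducingEndTag,
    Residue,
    SaccharideSequence,
    format_sequence,
    parse_sequence,
)

DEFAULT_CANDIDATE_CAP = 100_000


@dataclass(frozen=True)
class Observation:
    """One observed ion: m/z, charge, optionally CCS and intensity."""

    mz: float
    charge: int
    ccs: float | None = None
    intensity: float | None = None

    def __post_init__(self):
        if self.mz <= 0 or self.charge < 1:
            raise ValueError("m/z and charge must be positive")
        if self.ccs is not None and self.ccs <= 0:
            raise ValueError("ccs must be positive when given")


@dataclass(frozen=True)
class Tolerances:
    """Matching windows: ppm on mass; relative CCS with an absolute floor."""

    mass_ppm: float = 10.0
    ccs_rel: float = 0.005
    ccs_abs_floor: float = 2.0

    def ccs_window(self, ccs: float) -> float:
        return max(self.ccs_abs_floor, self.ccs_rel * ccs)


@dataclass(frozen=True)
class DisaccharideUnit:
    """One uronic+GlcN unit from compositional (disaccharide) analysis.

    ``uronic`` is ``"dUA"`` for a lyase-read unit with unresolved epimer,
    ``"UA"`` for the same (alias), or ``"GlcA"``/``"IdoA"`` when the
    epimer is known from orthogonal evidence; resolved units are
    interior-only (the original NRE epimer is unknowable once
    unsaturated).
    """

    uronic: str
    uronic_2s: bool
    n_state: str
    glcn_sulfation: frozenset

    def __post_init__(self):
        if self.uronic not in ("dUA", "UA", "GlcA", "IdoA"):
            raise ConstraintError(f"unknown uronic token {self.uronic!r}")
        object.__setattr__(self, "glcn_sulfation", frozenset(self.glcn_sulfation))

    @property
    def epimer_resolved(self) -> bool:
        return self.uronic in ("GlcA", "IdoA")

    @classmethod
    def parse(cls, text: str) -> "DisaccharideUnit":
        parts = text.strip().split("-")
        if len(parts) != 2:
            raise ConstraintError(f"disaccharide unit needs two tokens: {text!r}")
        utok, gtok = parts
        u2s = utok.endswith("2S")
        if u2s:
            utok = utok[:-2]
        utok = {"ΔUA": "dUA"}.get(utok, utok)
        if utok not in ("dUA", "UA", "GlcA", "IdoA"):
            raise ConstraintError(f"unknown uronic token in unit {text!r}")
        g = parse_sequence("dUA-" + gtok, label=None).residues[1]
        return cls(utok, u2s, g.n_state, g.sulfation)

    def glcn_residue(self) -> Residue:
        return Residue(GLCN_KIND, self.n_state, self.glcn_sulfation)

    def uronic_residues(self, at_nre: bool):
        """Possible uronic residues for this unit at a given position."""
        sulf = frozenset({"2S"} if self.uronic_2s else ())
        if at_nre:
            if self.epimer_resolved:
                return []  # resolved units are interior by construction
            return [Residue("DeltaHexA", None, sulf)]
        if self.epimer_resolved:
            return [Residue(self.uronic, None, sulf)]
        return [Residue("GlcA", None, sulf), Residue("IdoA", None, sulf)]


@dataclass(frozen=True)
class CompositionConstraint:
    """Residue/sulfate/tag counts a candidate must realize exactly."""

    delta_hexa: int
    hexa: int  # saturated uronic acids (GlcA or IdoA)
    hexnac: int
    hexns: int
    o_so3: int  # O-sulfates (2S/3S/6S), i.e. SO3 beyond the N-sulfates
    tag: ReducingEndTag = NO_TAG
    disaccharides: tuple = ()
    leading_glcn: bool = False

    def __post_init__(self):
        for name in ("delta_hexa", "hexa", "hexnac", "hexns", "o_so3"):
            if getattr(self, name) < 0:
                raise ConstraintError(f"{name} must be non-negative")
        if self.delta_hexa > 1:
            raise ConstraintError("at most one unsaturated uronic acid (at the NRE)")
        if self.n_residues == 0:
            raise ConstraintError("empty composition")
        n_u = self.delta_hexa + self.hexa
        n_g = self.hexnac + self.hexns
        if abs(n_u - n_g) > 1:
            raise ConstraintError(
                f"counts {n_u} uronic / {n_g} GlcN cannot alternate"
            )
        if self.leading_glcn and n_g < n_u:
            raise ConstraintError("leading-GlcN sequence needs GlcN count >= uronic")
        if self.delta_hexa and (self.leading_glcn or n_g > n_u):
            raise ConstraintError("dUA sits at the NRE; sequence cannot lead with GlcN")
        if self.o_so3 > n_u + 2 * n_g:
            raise ConstraintError("more O-sulfates than available positions")
        object.__setattr__(self, "disaccharides", tuple(self.disaccharides))

    @property
    def n_residues(self) -> int:
        return self.delta_hexa + self.hexa + self.hexnac + self.hexns

    @property
    def neutral_mass(self) -> float:
        m = (
            self.delta_hexa * chem.monoisotopic_mass(chem.DELTA_HEXA)
            + self.hexa * chem.monoisotopic_mass(chem.HEXA)
            + self.hexnac * chem.monoisotopic_mass(chem.HEXNAC)
            + self.hexns * (chem.monoisotopic_mass(chem.HEXN) + chem.SO3_MASS)
            + self.o_so3 * chem.SO3_MASS
            + chem.H2O_MASS
        )
        return m + self.tag.mass_delta

    @classmethod
    def from_sequence(
        cls, seq: SaccharideSequence, *, epimers_free: bool = True
    ) -> "CompositionConstraint":
        """Counts of a known sequence (epimer identity is not retained)."""
        delta = sum(1 for r in seq.residues if r.kind == "DeltaHexA")
        hexa = sum(1 for r in seq.residues if r.kind in ("GlcA", "IdoA"))
        nac = sum(1 for r in seq.residues if r.n_state == "acetyl")
        ns = sum(1 for r in seq.residues if r.n_state == "sulfo")
        o_so3 = sum(len(r.sulfation) for r in seq.residues)
        return cls(delta, hexa, nac, ns, o_so3, seq.tag,
                   leading_glcn=seq.leading_glcn)


def infer_composition(
    precursor_mz: float,
    charge: int,
    tolerance_ppm: float = 10.0,
    tag_set=None,
    max_residues: int = 12,
) -> list:
    """All residue/SO3/acetyl/tag count vectors matching a precursor m/z.

    Bounded integer search assuming negative-mode [M - zH]^z- ions and
    no free-amine glucosamine (every GlcN is NAc or NS).  Returns
    constraints sorted by |ppm error|; an empty list when nothing fits.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    tags = list(tag_set) if tag_set is not None else list(TAGS.values())
    target = chem.neutral_from_mz(precursor_mz, charge)
    m_delta = chem.monoisotopic_mass(chem.DELTA_HEXA)
    m_hexa = chem.monoisotopic_mass(chem.HEXA)
    m_nac = chem.monoisotopic_mass(chem.HEXNAC)
    m_ns = chem.monoisotopic_mass(chem.HEXN) + chem.SO3_MASS
    out = []
    for tag in tags:
        base = chem.H2O_MASS + tag.mass_delta
        for n_delta in (0, 1):
            for n_hexa in range(0, max_residues + 1 - n_delta):
                n_u = n_delta + n_hexa
                for n_g in range(max(0, n_u - 1), n_u + 2):
                    if n_u + n_g > max_residues or n_u + n_g == 0:
                        continue
                    if n_delta and n_g > n_u:
                        continue  # dUA implies a uronic NRE
                    for n_nac in range(0, n_g + 1):
                        n_ns = n_g - n_nac
                        core = (
                            base
                            + n_delta * m_delta
                            + n_hexa * m_hexa
                            + n_nac * m_nac
                            + n_ns * m_ns
                        )
                        rest = target - core
                        n_oso3 = round(rest / chem.SO3_MASS)
                        if n_oso3 < 0 or n_oso3 > n_u + 2 * n_g:
                            continue
                        mass = core + n_oso3 * chem.SO3_MASS
                        err = chem.ppm_error(target, mass)
                        if abs(err) > tolerance_ppm:
                            continue
                        try:
                            out.append(
                                (
                                    abs(err),
                                    CompositionConstraint(
                                        n_delta, n_hexa, n_nac, n_ns,
                                        n_oso3, tag,
                                        leading_glcn=n_g > n_u,
                                    ),
                                )
                            )
                        except ConstraintError:
                            continue
    out.sort(key=lambda t: (t[0], t[1].n_residues))
    return [c for _, c in out]


def _count_candidates(constraint: CompositionConstraint) -> int:
    n_u = constraint.delta_hexa + constraint.hexa
    n_g = constraint.hexnac + constraint.hexns
    n_sites = n_u + 2 * n_g
    return (
        math.comb(n_g, constraint.hexnac)
        * math.comb(n_sites, constraint.o_so3)
        * 2**constraint.hexa
    )


def _enumerate_from_counts(constraint: CompositionConstraint, cap: int):
    n_u = constraint.delta_hexa + constraint.hexa
    n_g = constraint.hexnac + constraint.hexns
    if _count_candidates(constraint) > cap:
        raise CandidateCapError(
            f"{_count_candidates(constraint)} candidates exceed the cap of {cap}"
        )
    n = n_u + n_g
    if constraint.leading_glcn:
        uronic_pos = list(range(1, n, 2))
        glcn_pos = list(range(0, n, 2))
    else:
        uronic_pos = list(range(0, n, 2))
        glcn_pos = list(range(1, n, 2))
    # O-sulfation sites: one 2S slot per uronic, 3S and 6S slots per GlcN
    sites = [(p, "2S") for p in uronic_pos]
    for p in glcn_pos:
        sites.extend([(p, "3S"), (p, "6S")])
    out = []
    for nac_positions in itertools.combinations(glcn_pos, constraint.hexnac):
        for sulfated in itertools.combinations(sites, constraint.o_so3):
            sulf_by_pos = {}
            for p, s in sulfated:
                sulf_by_pos.setdefault(p, set()).add(s)
            epimer_slots = [p for p in uronic_pos
                            if not (constraint.delta_hexa and p == 0)]
            for epimers in itertools.product(("GlcA", "IdoA"),
                                             repeat=len(epimer_slots)):
                kind_at = dict(zip(epimer_slots, epimers))
                residues = []
                for p in range(n):
                    sulf = frozenset(sulf_by_pos.get(p, ()))
                    if p in glcn_pos:
                        nst = "acetyl" if p in nac_positions else "sulfo"
                        residues.append(Residue(GLCN_KIND, nst, sulf))
                    elif constraint.delta_hexa and p == 0:
                        residues.append(Residue("DeltaHexA", None, sulf))
                    else:
                        residues.append(Residue(kind_at[p], None, sulf))
                out.append(SaccharideSequence(tuple(residues), constraint.tag))
    return out


def _enumerate_from_units(constraint: CompositionConstraint, cap: int):
    units = list(constraint.disaccharides)
    n = 2 * len(units)
    if constraint.n_residues and constraint.n_residues != n:
        raise ConstraintError(
            f"{len(units)} disaccharide units are inconsistent with "
            f"{constraint.n_residues} residues"
        )
    seen, out = set(), []
    for order in set(itertools.permutations(range(len(units)))):
        orders = [units[i] for i in order]
        per_unit = []
        ok = True
        for k, u in enumerate(orders):
            at_nre = k == 0 and constraint.delta_hexa == 1
            uronics = u.uronic_residues(at_nre=at_nre)
            if k == 0 and constraint.delta_hexa == 0 and not u.epimer_resolved:
                uronics = [Residue("GlcA", None,
                                   frozenset({"2S"} if u.uronic_2s else ())),
                           Residue("IdoA", None,
                                   frozenset({"2S"} if u.uronic_2s else ()))]
            if not uronics:
                ok = False
                break
            per_unit.append([(ur, u.glcn_residue()) for ur in uronics])
        if not ok:
            continue
        for combo in itertools.product(*per_unit):
            residues = tuple(r for pair in combo for r in pair)
            try:
                seq = SaccharideSequence(residues, constraint.tag)
            except SimmsError:  # pragma: no cover - units always alternate
                continue
            key = format_sequence(seq)
            if key not in seen:
                seen.add(key)
                out.append(seq)
            if len(out) > cap:
                raise CandidateCapError(f"candidates exceed the cap of {cap}")
    return out


def enumerate_candidates(
    constraint: CompositionConstraint,
    cap: int = DEFAULT_CANDIDATE_CAP,
) -> list:
    """Exhaustive, duplicate-free candidate sequences for a constraint.

    With a disaccharide-unit table the candidates are the unit orderings
    (NRE unit unsaturated when the composition says so, unresolved
    epimers expanded); otherwise all placements of N-acetyl groups and
    O-sulfates plus the GlcA/IdoA expansion of every saturated uronic.
    Aborts with :class:`CandidateCapError` above *cap*.
    """
    if constraint.disaccharides:
        out = _enumerate_from_units(constraint, cap)
    else:
        out = _enumerate_from_counts(constraint, cap)
    return sorted(out, key=format_sequence)


@dataclass(frozen=True)
class Evidence:
    """One observation matched to a library entry for one candidate."""

    observation: Observation
    entry: LibraryEntry
    fragment: FragmentIon  # the candidate's own fragment
    mass_error_ppm: float
    ccs_error_A2: float

    @property
    def satellite(self) -> bool:
        return self.fragment.satellite

    @property
    def ccs_error_rel(self) -> float:
        return self.ccs_error_A2 / self.entry.ccs


def _resolve_entries(registry: LibraryRegistry):
    """Library entries with their fragment resolved from the standard."""
    out = []
    for e in registry.entries.values():
        frag = registry.entry_fragment(e)
        if frag is not None:
            out.append((e, frag))
    return out


def _prematch(observations, resolved, tolerances: Tolerances):
    """Candidate-independent screen: per observation, the library
    entries that already agree in CCS, charge and neutral mass."""
    out = []
    for obs in observations:
        hits = []
        if obs.ccs is not None:
            for entry, lib_frag in resolved:
                if abs(entry.ccs - obs.ccs) > tolerances.ccs_window(entry.ccs):
                    continue
                if entry.charge is not None and entry.charge != obs.charge:
                    continue
                lib_mz = chem.mz_from_neutral(lib_frag.neutral_mass, obs.charge)
                err = chem.ppm_error(obs.mz, lib_mz)
                if abs(err) > tolerances.mass_ppm:
                    continue
                hits.append((entry, lib_frag, err))
        out.append((obs, hits))
    return out


def _match_prematched(prematched, candidate, max_so3_losses):
    """Residue-for-residue agreement of pre-screened entries with the
    candidate's prefixes/suffixes; the only per-candidate work."""
    n = len(candidate)
    untagged = candidate.tag.name == "none"
    out = []
    for obs, hits in prematched:
        for entry, lib_frag, err in hits:
            if entry.ion == PRECURSOR:
                if candidate.residues != lib_frag.residues:
                    continue
                if candidate.tag.name != lib_frag.tag.name:
                    continue
                frag = FragmentIon(
                    "Y", n, candidate.residues,
                    tag=candidate.tag, charge=obs.charge,
                )
            else:
                if lib_frag.so3_losses > max_so3_losses:
                    continue
                series, idx = lib_frag.series, lib_frag.index
                if series in ("B", "C"):
                    top = n if (untagged and series == "B") else n - 1
                    if not 1 <= idx <= top:
                        continue
                    residues = candidate.residues[:idx]
                    tag = NO_TAG
                elif series in ("Y", "Z"):
                    if not 1 <= idx <= n - 1:
                        continue
                    residues = candidate.residues[n - idx :]
                    tag = candidate.tag
                    if tag.name != lib_frag.tag.name:
                        continue
                else:
                    continue
                if residues != lib_frag.residues:
                    continue
                try:
                    frag = FragmentIon(
                        series, idx, residues, tag=tag,
                        charge=obs.charge, so3_losses=lib_frag.so3_losses,
                    )
                except SimmsError:
                    continue
            out.append(Evidence(obs, entry, frag, err, abs(entry.ccs - obs.ccs)))
    out.sort(
        key=lambda ev: (
            ev.observation.mz,
            ev.entry.standard_id,
            ev.entry.ion,
            ev.fragment.series,
        )
    )
    return out


def match_observations(
    observations,
    candidate: SaccharideSequence,
    registry: LibraryRegistry,
    tolerances: Tolerances = Tolerances(),
    max_so3_losses: int = 1,
) -> list:
    """Evidence records linking observations to library CCS entries.

    A record requires (i) a theoretical fragment of *candidate* within
    the ppm window of the observation, (ii) a library entry of the same
    series/index/loss whose own neutral mass also matches, (iii) CCS
    agreement within the window, and (iv) residue-for-residue agreement
    between the entry's fragment and the candidate's prefix/suffix
    (epimer included).  Precursor entries must match the full sequence.
    Since agreement is residue-exact, the observed mass error against
    the candidate's fragment equals the error against the library one.
    """
    if tolerances.mass_ppm <= 0:
        raise ValueError("tolerances must be positive")
    prematched = _prematch(observations, _resolve_entries(registry), tolerances)
    return _match_prematched(prematched, candidate, max_so3_losses)


def _covered_sites(candidate: SaccharideSequence, evidence) -> set:
    n = len(candidate)
    sites = set()
    for ev in evidence:
        if ev.satellite:
            continue  # corroborating only
        f = ev.fragment
        if ev.entry.ion == PRECURSOR:
            sites.update(range(1, n))
        elif f.series in ("B", "C"):
            sites.update(range(1, min(f.index, n - 1) + 1))
        else:
            sites.update(range(n - f.index, n))
    return {s for s in sites if 1 <= s <= n - 1}


@dataclass(frozen=True)
class CandidateResult:
    """Evidence, coverage and ambiguity bookkeeping for one candidate."""

    sequence: SaccharideSequence
    evidence: tuple
    covered_sites: tuple
    uncovered_sites: tuple
    epimer_ambiguous_positions: tuple = ()

    @property
    def n_sites(self) -> int:
        return len(self.covered_sites) + len(self.uncovered_sites)

    @property
    def coverage(self) -> float:
        return len(self.covered_sites) / self.n_sites if self.n_sites else 0.0

    @property
    def n_matched_observations(self) -> int:
        return len({ev.observation for ev in self.evidence if not ev.satellite})

    @property
    def score(self):
        return (len(self.covered_sites), self.n_matched_observations)


@dataclass(frozen=True)
class SequencingReport:
    """Ranked candidates with evidence and an explicit verdict.

    ``verdict`` is ``("unambiguous", [sequence])`` when one candidate
    strictly leads the (coverage, matched-observations) ranking,
    ``("ambiguous", [tied sequences...])`` when several tie at the top,
    and ``("insufficient", [])`` when nothing matched at all.
    """

    candidates: tuple
    verdict_status: str
    verdict_sequences: tuple

    @property
    def best(self) -> CandidateResult | None:
        return self.candidates[0] if self.candidates else None

    def to_record(self) -> dict:
        return {
            "verdict": {
                "status": self.verdict_status,
                "sequences": [format_sequence(s) for s in self.verdict_sequences],
            },
            "candidates": [
                {
                    "sequence": format_sequence(c.sequence),
                    "coverage": round(c.coverage, 6),
                    "covered_sites": list(c.covered_sites),
                    "uncovered_sites": list(c.uncovered_sites),
                    "epimer_ambiguous_positions": list(
                        c.epimer_ambiguous_positions
                    ),
                    "evidence": [
                        {
                            "observation_mz": ev.observation.mz,
                            "observation_ccs": ev.observation.ccs,
                            "standard_id": ev.entry.standard_id,
                            "ion": ev.entry.ion,
                            "library_ccs": ev.entry.ccs,
                            "fragment": ev.fragment.label,
                            "mass_error_ppm": round(ev.mass_error_ppm, 3),
                            "ccs_error_A2": round(ev.ccs_error_A2, 3),
                            "satellite": ev.satellite,
                        }
                        for ev in c.evidence
                    ],
                }
                for c in self.candidates
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_record(), indent=1, sort_keys=True) + "\n"


def _epimer_difference_positions(a: SaccharideSequence, b: SaccharideSequence):
    """Positions (1-based) where a and b differ only by GlcA/IdoA swap."""
    if len(a) != len(b):
        return None
    positions = []
    for i, (ra, rb) in enumerate(zip(a.residues, b.residues)):
        if ra == rb:
            continue
        if {ra.kind, rb.kind} == {"GlcA", "IdoA"} and ra.sulfation == rb.sulfation:
            positions.append(i + 1)
        else:
            return None
    return positions or None


def sequence(
    observations,
    registry: LibraryRegistry,
    precursor: Observation | None = None,
    constraint: CompositionConstraint | None = None,
    candidates=None,
    tolerances: Tolerances = Tolerances(),
    tag_set=None,
    candidate_cap: int = DEFAULT_CANDIDATE_CAP,
    max_so3_losses: int = 1,
) -> SequencingReport:
    """Run the full shotgun assignment pipeline.

    Candidates come from, in order of precedence: an explicit
    ``candidates`` list, an explicit ``constraint``, or composition
    inference from the ``precursor`` observation.  The precursor, when
    given with a CCS, is also matched against library precursor entries.
    """
    observations = list(observations)
    if not observations and precursor is None:
        raise ValueError("at least one observation is required")
    if not registry.entries:
        raise EmptyLibraryError("reference library holds no CCS entries")
    if candidates is None:
        if constraint is not None:
            constraints = [constraint]
        elif precursor is not None:
            constraints = infer_composition(
                precursor.mz, precursor.charge, tolerances.mass_ppm, tag_set
            )
        else:
            raise ValueError(
                "provide candidates, a constraint, or a precursor observation"
            )
        candidates = []
        seen = set()
        for c in constraints:
            for s in enumerate_candidates(c, cap=candidate_cap):
                key = format_sequence(s)
                if key not in seen:
                    seen.add(key)
                    candidates.append(s)
    candidates = list(candidates)
    if len(candidates) > candidate_cap:
        raise CandidateCapError(
            f"{len(candidates)} candidates exceed the cap of {candidate_cap}"
        )

    matchable = list(observations)
    if precursor is not None and precursor.ccs is not None:
        matchable.append(precursor)
    prematched = _prematch(matchable, _resolve_entries(registry), tolerances)

    results = []
    for cand in candidates:
        ev = tuple(_match_prematched(prematched, cand, max_so3_losses))
        covered = _covered_sites(cand, ev)
        all_sites = set(range(1, len(cand)))
        results.append(
            CandidateResult(
                sequence=cand,
                evidence=ev,
                covered_sites=tuple(sorted(covered)),
                uncovered_sites=tuple(sorted(all_sites - covered)),
            )
        )
    results.sort(key=lambda r: (-r.score[0], -r.score[1],
                                format_sequence(r.sequence)))

    if not results or results[0].score == (0, 0):
        return SequencingReport(tuple(results), "insufficient", ())
    top = results[0]
    tied = [r for r in results if r.score == top.score]
    if len(tied) == 1:
        return SequencingReport(
            tuple(results), "unambiguous", (top.sequence,)
        )
    # annotate pure-epimer ties so reports can say *where* the ambiguity is
    annotated = []
    tied_seqs = [r.sequence for r in tied]
    for r in results:
        if r in tied:
            pos = set()
            for other in tied_seqs:
                if other is r.sequence:
                    continue
                diff = _epimer_difference_positions(r.sequence, other)
                if diff:
                    pos.update(diff)
            r = CandidateResult(
                r.sequence, r.evidence, r.covered_sites, r.uncovered_sites,
                tuple(sorted(pos)),
            )
        annotated.append(r)
    return SequencingReport(
        tuple(annotated), "ambiguous", tuple(r.sequence for r in tied)
    )


def coverage_map(report: SequencingReport, candidate) -> dict:
    """Per-site supporting evidence for one candidate in a report.

    *candidate* may be a sequence object or its grammar string.  Maps
    each cleavage site (1..n-1) to the list of ``(standard_id, ion)``
    contributors, exposing the shotgun overlap explicitly.
    """
    want = candidate if isinstance(candidate, str) else format_sequence(candidate)
    for r in report.candidates:
        if format_sequence(r.sequence) == want:
            n = len(r.sequence)
            out = {s: [] for s in range(1, n)}
            for ev in r.evidence:
                if ev.satellite:
                    continue
                f = ev.fragment
                if ev.entry.ion == PRECURSOR:
                    span = range(1, n)
                elif f.series in ("B", "C"):
                    span = range(1, min(f.index, n - 1) + 1)
                else:
                    span = range(n - f.index, n)
                for s in span:
                    out[s].append((ev.entry.standard_id, ev.entry.ion))
            return {s: sorted(set(v)) for s, v in out.items()}
    raise SimmsError(f"candidate {want!r} not present in report")
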