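"""Composition inference, candidate enumeration and shotgun matching."""

import itertools

import pytest

import simms2 as s
from simms2 import chem
from simms2.errors import CandidateCapError, ConstraintError, EmptyLibraryError
from simms2.library import PRECURSOR, LibraryEntry, LibraryRegistry, StandardRecord
from simms2.sequencer import (
    CompositionConstraint,
    DisaccharideUnit,
    Observation,
    Tolerances,
)


# -- composition inference ---------------------------------------------

def test_infer_composition_disaccharide_example():
    found = s.infer_composition(416.0504, 1, 10.0)
    assert len(found) == 1
    c = found[0]
    assert (c.delta_hexa, c.hexa, c.hexnac, c.hexns, c.o_so3) == (1, 0, 0, 1, 0)
    assert c.tag.name == "none"


def test_infer_composition_impossible_mass_is_empty():
    assert s.infer_composition(100.0, 1, 10.0) == []


def test_infer_composition_monotone_in_tolerance():
    mz = s.mz(s.neutral_mass(s.parse_sequence("dUA-GlcNS-IdoA2S-GlcNS3S")), 2)
    narrow = s.infer_composition(mz, 2, 1.0)
    wide = s.infer_composition(mz, 2, 50.0)
    assert {repr(c) for c in narrow} <= {repr(c) for c in wide}


def test_infer_composition_brute_force_oracle():
    """Exhaustive small search agrees: every count vector <= 4 residues
    whose mass lands in the window is found, and nothing else."""
    target_seq = s.parse_sequence("dUA2S-GlcNS3S6S")
    mz = s.mz(s.neutral_mass(target_seq), 1)
    found = s.infer_composition(mz, 1, 10.0, tag_set=[s.NO_TAG])
    expected = set()
    m_d = chem.monoisotopic_mass(chem.DELTA_HEXA)
    m_u = chem.monoisotopic_mass(chem.HEXA)
    m_ac = chem.monoisotopic_mass(chem.HEXNAC)
    m_ns = chem.monoisotopic_mass(chem.HEXN) + chem.SO3_MASS
    target = chem.neutral_from_mz(mz, 1)
    for nd, nu, nac, nns, no in itertools.product(range(2), range(5),
                                                  range(5), range(5), range(13)):
        n_g = nac + nns
        n_uro = nd + nu
        if not n_uro + n_g or abs(n_uro - n_g) > 1 or n_uro + n_g > 4:
            continue
        if nd and n_g > n_uro:
            continue
        if no > n_uro + 2 * n_g:
            continue
        mass = (nd * m_d + nu * m_u + nac * m_ac + nns * m_ns
                + no * chem.SO3_MASS + chem.H2O_MASS)
        if abs(chem.ppm_error(target, mass)) <= 10.0:
            expected.add((nd, nu, nac, nns, no))
    got = {(c.delta_hexa, c.hexa, c.hexnac, c.hexns, c.o_so3) for c in found}
    assert got == expected
    assert (1, 0, 0, 1, 3) in got


# -- enumeration --------------------------------------------------------

def test_epimer_expansion_count():
    # hexamer with all sulfation fixed, three saturated uronics free
    con = CompositionConstraint.from_sequence(
        s.parse_sequence("GlcA-GlcNS6S-IdoA-GlcNS6S-GlcA-GlcNS6S-R1")
    )
    fixed_sulf = CompositionConstraint(
        con.delta_hexa, con.hexa, con.hexnac, con.hexns, con.o_so3, con.tag
    )
    cands = s.enumerate_candidates(fixed_sulf)
    with_63 = [
        c for c in cands
        if all(r.sulfation == frozenset({"6S"}) for r in c.residues[1::2])
    ]
    assert len(with_63) == 2**3


def test_free_disaccharide_enumeration_matches_cartesian_product():
    # dUA + GlcN with 2S, N-state, 3S, 6S each free: 2*2*2*2 = 16
    count = 0
    for o_so3 in range(0, 4):
        for nac in (0, 1):
            try:
                con = CompositionConstraint(1, 0, nac, 1 - nac, o_so3)
            except ConstraintError:
                continue
            count += len(s.enumerate_candidates(con))
    assert count == 16


def test_empty_constraint_is_an_error():
    with pytest.raises(ConstraintError):
        CompositionConstraint(0, 0, 0, 0, 0)


def test_candidate_cap_guards_explosions():
    con = CompositionConstraint(0, 5, 0, 5, 8, s.TAGS["R1"])
    with pytest.raises(CandidateCapError):
        s.enumerate_candidates(con, cap=100)


def test_unit_table_enumeration_respects_nre_rule():
    units = tuple(
        DisaccharideUnit.parse(u)
        for u in ("dUA-GlcNS", "IdoA2S-GlcNS", "GlcA-GlcNAc")
    )
    con = CompositionConstraint(1, 2, 1, 2, 1, disaccharides=units)
    cands = s.enumerate_candidates(con)
    texts = {s.format_sequence(c) for c in cands}
    # resolved units are interior-only; the unsaturated unit leads
    assert texts == {
        "dUA-GlcNS-IdoA2S-GlcNS-GlcA-GlcNAc",
        "dUA-GlcNS-GlcA-GlcNAc-IdoA2S-GlcNS",
    }


def test_unit_table_generic_units_expand_epimers():
    units = tuple(
        DisaccharideUnit.parse(u) for u in ("dUA-GlcNS", "dUA-GlcNAc")
    )
    con = CompositionConstraint(1, 1, 1, 1, 0, disaccharides=units)
    texts = {s.format_sequence(c) for c in s.enumerate_candidates(con)}
    assert texts == {
        "dUA-GlcNS-GlcA-GlcNAc",
        "dUA-GlcNS-IdoA-GlcNAc",
        "dUA-GlcNAc-GlcA-GlcNS",
        "dUA-GlcNAc-IdoA-GlcNS",
    }


# -- matching -----------------------------------------------------------

def test_exact_window_semantics(registry, obs_for):
    s16 = registry.sequence_of("#16")
    tol = Tolerances(ccs_rel=0.0, ccs_abs_floor=0.0)
    good = s.match_observations([obs_for(s16, "B", 2, 135)], s16, registry, tol)
    assert {e.entry.key[:2] for e in good} == {("#12", "B2"), ("#16", "B2")}
    perturbed = s.match_observations(
        [obs_for(s16, "B", 2, 136)], s16, registry, tol
    )
    assert perturbed == []


def test_b4_ccs_distinguishes_3s_from_6s(registry, obs_for):
    s33 = registry.sequence_of("#33")
    s34 = registry.sequence_of("#34")
    obs = [obs_for(s34, "B", 4, 220)]
    assert s.match_observations(obs, s33, registry) == []
    ev = s.match_observations(obs, s34, registry)
    assert [e.entry.standard_id for e in ev] == ["#34"]


def test_matching_requires_residue_agreement_not_just_mass(registry, obs_for):
    # an epimer-swapped candidate has identical masses but must not match
    s16 = registry.sequence_of("#16")
    swapped = s.parse_sequence("IdoA-GlcNS6S-IdoA-GlcNS6S-GlcA-GlcNS6S-R1")
    obs = [obs_for(s16, "B", 2, 135)]
    assert s.match_observations(obs, s16, registry) != []
    assert s.match_observations(obs, swapped, registry) == []


def test_satellite_matches_never_cover_alone(obs_for):
    reg = LibraryRegistry()
    seq = s.parse_sequence("dUA-GlcNS-IdoA2S-GlcNS3S")
    reg.add_standard(StandardRecord("#T", seq))
    reg.add(LibraryEntry("#T", "B2-SO3", 120.0))
    f = s.make_fragment(seq, "B", 2, so3_losses=1)
    obs = [Observation(mz=f.mz, charge=1, ccs=120.0)]
    rep = s.sequence(obs, reg, candidates=[seq])
    assert rep.verdict_status == "insufficient"
    assert rep.candidates[0].evidence  # matched, but corroborating only
    assert rep.candidates[0].covered_sites == ()


# -- full pipeline ------------------------------------------------------

def test_fig3_style_overlap_assignment(registry, obs_for):
    s16 = registry.sequence_of("#16")
    obs = [
        obs_for(s16, "B", 2, 135),
        obs_for(s16, "B", 3, 160),
        obs_for(s16, "Y", 2, 156),
        obs_for(s16, "Y", 3, 213),
    ]
    prec = Observation(mz=chem.mz_from_neutral(s.neutral_mass(s16), 2), charge=2)
    rep = s.sequence(obs, registry, precursor=prec)
    assert rep.verdict_status == "unambiguous"
    assert s.format_sequence(rep.verdict_sequences[0]) == s.format_sequence(s16)
    assert rep.best.covered_sites == (1, 2, 3, 4, 5)


def test_coverage_map_shows_the_overlap(registry, obs_for):
    s16 = registry.sequence_of("#16")
    obs = [
        obs_for(s16, "B", 2, 135),
        obs_for(s16, "B", 3, 160),
        obs_for(s16, "Y", 2, 156),
        obs_for(s16, "Y", 3, 213),
    ]
    prec = Observation(mz=chem.mz_from_neutral(s.neutral_mass(s16), 2), charge=2)
    rep = s.sequence(obs, registry, precursor=prec)
    cm = s.coverage_map(rep, rep.best.sequence)
    assert set(cm) == {1, 2, 3, 4, 5}
    b_sites = {site for site, who in cm.items()
               if any(ion.startswith("B") for _, ion in who)}
    y_sites = {site for site, who in cm.items()
               if any(ion.startswith("Y") for _, ion in who)}
    assert b_sites | y_sites == {1, 2, 3, 4, 5}
    assert any(sid == "#12" for who in cm.values() for sid, _ in who)
    assert any(sid == "#14" for who in cm.values() for sid, _ in who)


def test_coverage_map_zero_evidence_and_monotonicity(registry, obs_for):
    s16 = registry.sequence_of("#16")
    obs = [obs_for(s16, "B", 2, 135), obs_for(s16, "Y", 2, 156)]
    rep = s.sequence(obs, registry, candidates=[s16])
    cm = s.coverage_map(rep, s16)
    covered_two = {k for k, v in cm.items() if v}
    rep_one = s.sequence(obs[:1], registry, candidates=[s16])
    cm_one = s.coverage_map(rep_one, s16)
    covered_one = {k for k, v in cm_one.items() if v}
    assert covered_one <= covered_two  # removing evidence never adds coverage
    rep_zero = s.sequence(
        [Observation(mz=123.456, charge=1, ccs=50.0)], registry,
        candidates=[s16],
    )
    assert s.coverage_map(rep_zero, s16) == {k: [] for k in range(1, 6)}


def test_insufficient_verdict_retains_candidates(registry):
    cands = [
        registry.sequence_of("#33"),
        registry.sequence_of("#34"),
    ]
    rep = s.sequence(
        [Observation(mz=100.0, charge=1, ccs=50.0)], registry,
        candidates=cands,
    )
    assert rep.verdict_status == "insufficient"
    assert len(rep.candidates) == 2


def test_empty_library_is_an_error():
    with pytest.raises(EmptyLibraryError):
        s.sequence(
            [Observation(mz=100.0, charge=1, ccs=50.0)],
            LibraryRegistry(),
            candidates=[s.parse_sequence("dUA-GlcNS")],
        )


def test_epimer_honesty(registry, obs_for):
    """Without CCS evidence on a GlcA/IdoA site, the verdict must not
    claim that site."""
    hs1 = registry.sequence_of("#HS1")
    obs = [obs_for(hs1, "B", k, c) for k, c in ((1, 71), (2, 110),
                                                (3, 162), (4, 201))]
    swapped = s.parse_sequence("dUA-GlcNS-IdoA2S-GlcNS-IdoA-GlcNAc")
    rep = s.sequence(obs, registry, candidates=[hs1, swapped])
    assert rep.verdict_status == "ambiguous"
    assert len(rep.verdict_sequences) == 2
    assert rep.candidates[0].epimer_ambiguous_positions == (5,)


def test_determinism_byte_identical_reports(registry, obs_for):
    s16 = registry.sequence_of("#16")
    obs = [obs_for(s16, "B", 2, 135), obs_for(s16, "Y", 3, 213)]
    prec = Observation(mz=chem.mz_from_neutral(s.neutral_mass(s16), 2), charge=2)
    a = s.sequence(obs, registry, precursor=prec).to_json()
    b = s.sequence(obs, registry, precursor=prec).to_json()
    assert a == b


# -- brute-force oracle equivalence ------------------------------------

def _oracle_match(observations, candidate, registry, tol):
    """Naive reference matcher: scan every candidate fragment against
    every resolvable library entry and apply the definitions directly."""
    hits = []
    frags = {}
    for z in {o.charge for o in observations}:
        frags[z] = [
            f
            for f in s.generate_fragments(
                candidate, ("B", "C", "Y", "Z"), max_charge=z, max_so3_losses=1
            )
            if f.charge == z
        ]
    for obs in observations:
        if obs.ccs is None:
            continue
        for entry in registry.entries.values():
            lib_frag = registry.entry_fragment(entry)
            if lib_frag is None:
                continue
            if entry.ion == PRECURSOR:
                if abs(entry.ccs - obs.ccs) > tol.ccs_window(entry.ccs):
                    continue
                lib_mz = chem.mz_from_neutral(lib_frag.neutral_mass, obs.charge)
                if abs(chem.ppm_error(obs.mz, lib_mz)) > tol.mass_ppm:
                    continue
                if (candidate.residues == lib_frag.residues
                        and candidate.tag.name == lib_frag.tag.name):
                    hits.append((obs.mz, entry.key, "Y", len(candidate), 0))
                continue
            if abs(entry.ccs - obs.ccs) > tol.ccs_window(entry.ccs):
                continue
            lib_mz = chem.mz_from_neutral(lib_frag.neutral_mass, obs.charge)
            if abs(chem.ppm_error(obs.mz, lib_mz)) > tol.mass_ppm:
                continue
            for f in frags[obs.charge]:
                if (f.series, f.index, f.so3_losses) != (
                    lib_frag.series, lib_frag.index, lib_frag.so3_losses
                ):
                    continue
                if f.residues != lib_frag.residues:
                    continue
                if f.series in ("Y", "Z") and (
                    candidate.tag.name != lib_frag.tag.name
                ):
                    continue
                if abs(chem.ppm_error(obs.mz, f.mz)) > tol.mass_ppm:
                    continue
                hits.append((obs.mz, entry.key, f.series, f.index, f.so3_losses))
    return sorted(hits)


def _oracle_verdict(observations, candidates, registry, tol):
    n_map = {}
    for cand in candidates:
        hits = _oracle_match(observations, cand, registry, tol)
        covered = set()
        n = len(cand)
        for _, _, series, idx, losses in hits:
            if losses:
                continue
            if series in ("B", "C"):
                covered |= set(range(1, min(idx, n - 1) + 1))
            else:
                covered |= {k for k in range(n - idx, n) if 1 <= k <= n - 1}
        n_obs = len({h[0] for h in hits if not h[4]})
        n_map[s.format_sequence(cand)] = (len(covered), n_obs)
    best = max(n_map.values())
    tied = [k for k, v in n_map.items() if v == best]
    if best == (0, 0):
        return "insufficient", []
    if len(tied) == 1:
        return "unambiguous", tied
    return "ambiguous", sorted(tied)


def test_sequencer_agrees_with_brute_force_oracle(rng):
    """Randomised dp<=6 instances with small synthetic libraries."""
    tol = Tolerances()
    for trial in range(12):
        dp = int(rng.integers(2, 7))
        truth = s.random_sequence(rng, dp, max_o_so3=2)
        fx = s.make_fixture(truth, s.builtin_paper_library(),
                            seed=int(rng.integers(0, 1000)),
                            auto_extend=True)
        con = CompositionConstraint.from_sequence(truth)
        cands = s.enumerate_candidates(con)
        if len(cands) > 200:
            cands = cands[:200] + [truth]
        rep = s.sequence(fx.observations, fx.registry, candidates=cands,
                         tolerances=tol)
        status, seqs = _oracle_verdict(fx.observations, cands, fx.registry, tol)
        assert rep.verdict_status == status
        assert sorted(s.format_sequence(x) for x in rep.verdict_sequences) == (
            sorted(seqs)
        )
        for cand in cands[:5]:
            ev = s.match_observations(fx.observations, cand, fx.registry, tol)
            got = sorted(
                (e.observation.mz, e.entry.key, e.fragment.series,
                 e.fragment.index, e.fragment.so3_losses)
                for e in ev
            )
            assert got == _oracle_match(fx.observations, cand, fx.registry, tol)


def test_soundness_truth_always_in_maximal_set(rng):
    """When observations derive exactly from library entries of the
    truth's fragments, the truth attains maximal coverage."""
    for trial in range(8):
        dp = int(rng.integers(3, 8))
        truth = s.random_sequence(rng, dp, max_o_so3=2)
        fx = s.make_fixture(truth, s.builtin_paper_library(), seed=trial,
                            auto_extend=True)
        rep = s.sequence(fx.observations, fx.registry, precursor=fx.precursor)
        best_score = rep.candidates[0].score
        truth_text = s.format_sequence(truth)
        winners = {
            s.format_sequence(c.sequence)
            for c in rep.candidates
            if c.score == best_score
        }
        assert truth_text in winners
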