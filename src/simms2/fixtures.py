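"""End-to-end synthetic fixtures: fabricate SIMMS2 inputs from a truth.

``make_fixture`` inverts the sequencing strategy for testing: given a
ground-truth sequence and a CCS registry it emits the observation table
(fragment m/z from the fragmenter, CCS from registry entries plus
optional noise) and, on request, the stepped-field ATD series that
would have produced each CCS.  When the registry lacks entries for the
truth's fragments it can be auto-extended with synthetic CCS values
drawn reproducibly from the fragment's composition — those values are
fabrications for closed-loop testing, not measurements.

``random_sequence`` draws grammar-valid truths for property sweeps.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import LibraryError
from .fragmentation import generate_fragments, precursor_ion
from .library import PRECURSOR, LibraryEntry, LibraryRegistry, StandardRecord
from .mobility import (
    DEFAULT_CONFIG,
    InstrumentConfig,
    SteppedFieldSeries,
    simulate_stepped_field,
)
from .saccharide import (
    NO_TAG,
    TAGS,
    Residue,
    SaccharideSequence,
    format_sequence,
    neutral_mass,
)
from .sequencer import Observation, Tolerances


@dataclass(frozen=True)
class RunConfig:
    """Everything that, together with the input files, fixes a run."""

    instrument: InstrumentConfig = DEFAULT_CONFIG
    tolerances: Tolerances = Tolerances()
    seed: int = 0
    candidate_cap: int = 100_000
    max_so3_losses: int = 1
    verbosity: int = 0

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        inst = InstrumentConfig(**data.get("instrument", {}))
        tol = Tolerances(**data.get("tolerances", {}))
        return cls(
            instrument=inst,
            tolerances=tol,
            seed=int(data.get("seed", 0)),
            candidate_cap=int(data.get("candidate_cap", 100_000)),
            max_so3_losses=int(data.get("max_so3_losses", 1)),
            verbosity=int(data.get("verbosity", 0)),
        )


def synthetic_fragment_ccs(fragment) -> float:
    """Reproducible synthetic CCS (Å^2) for a fragment ion.

    A smooth size trend (~mass^(2/3), roughly calibrated to the packaged
    values) plus a structure-keyed jitter so that isomeric fragments get
    distinct values; deterministic across runs and platforms.
    """
    key = "|".join(r.token() for r in fragment.residues) + f"|{fragment.series}"
    jitter = (zlib.crc32(key.encode()) % 2001 - 1000) / 1000.0  # [-1, 1)
    return round(2.3 * fragment.neutral_mass ** (2.0 / 3.0) + 8.0 * jitter, 1)


@dataclass
class Fixture:
    """Synthetic inputs plus the ground truth they encode."""

    truth: SaccharideSequence
    observations: list
    precursor: Observation
    registry: LibraryRegistry
    series: dict = field(default_factory=dict)

    def truth_record(self) -> dict:
        return {
            "sequence": format_sequence(self.truth),
            "tag": self.truth.tag.name,
            "label": self.truth.label,
            "neutral_mass": round(neutral_mass(self.truth), 4),
        }

    def observations_csv(self) -> str:
        lines = ["mz,charge,ccs_A2,intensity"]
        for o in self.observations:
            ccs = "" if o.ccs is None else f"{o.ccs:.2f}"
            inten = "" if o.intensity is None else f"{o.intensity:g}"
            lines.append(f"{o.mz:.4f},{o.charge},{ccs},{inten}")
        return "\n".join(lines) + "\n"


def make_fixture(
    truth: SaccharideSequence,
    registry: LibraryRegistry,
    noise: float = 0.0,
    seed: int = 0,
    series_set=("B", "Y"),
    charge: int = 1,
    precursor_charge: int = 2,
    auto_extend: bool = False,
    synthetic_label: str = "#SYN",
    make_series: bool = False,
    config: InstrumentConfig = DEFAULT_CONFIG,
) -> Fixture:
    """Observations (and optional ATD series) for a known truth.

    Fragment m/z values come from the fragmenter; CCS values come from
    registry entries whose fragment agrees residue-for-residue with the
    truth's, perturbed by a relative Gaussian ``noise``.  Fragments with
    no matching entry are skipped — the corresponding cleavage sites
    will simply be uncovered — unless ``auto_extend`` adds synthetic
    entries (under ``synthetic_label``) for every missing fragment.
    """
    rng = np.random.default_rng(seed)
    reg = registry.copy()
    resolved = []
    for e in reg.entries.values():
        f = reg.entry_fragment(e)
        if f is not None and e.ion != PRECURSOR:
            resolved.append((e, f))

    if auto_extend:
        reg.add_standard(
            StandardRecord(synthetic_label, truth.__class__(
                truth.residues, truth.tag, synthetic_label
            ), "synthetic fixture standard")
        )

    observations = []
    n_found = 0
    for frag in generate_fragments(
        truth, series_set=series_set, max_charge=1, max_so3_losses=0
    ):
        entry = None
        for e, lib_frag in resolved:
            if (lib_frag.series, lib_frag.index) != (frag.series, frag.index):
                continue
            if lib_frag.residues != frag.residues:
                continue
            if frag.series in ("Y", "Z") and lib_frag.tag.name != truth.tag.name:
                continue
            entry = e
            break
        if entry is None:
            if not auto_extend:
                continue
            entry = LibraryEntry(
                synthetic_label,
                frag.label,
                synthetic_fragment_ccs(frag),
                None,
                "synthetic",
            )
            if entry.key not in reg.entries:
                reg.add(entry)
        n_found += 1
        ccs = entry.ccs * (1.0 + (rng.normal(0.0, noise) if noise > 0 else 0.0))
        mz = (frag.neutral_mass - charge * 1.00727646688) / charge
        observations.append(Observation(mz=mz, charge=charge, ccs=ccs))
    if n_found == 0:
        raise LibraryError(
            "no fragment of the truth is present in the registry; "
            "pass auto_extend=True to fabricate synthetic entries"
        )
    prec = precursor_ion(truth, charge=precursor_charge)
    precursor = Observation(mz=prec.mz, charge=precursor_charge, ccs=None)

    series = {}
    if make_series:
        for obs in observations + [precursor]:
            if obs.ccs is None:
                continue
            ion_mass = obs.mz * obs.charge
            series[f"{obs.mz:.4f}"] = simulate_stepped_field(
                obs.ccs, obs.charge, ion_mass, config,
                noise=noise, seed=int(rng.integers(0, 2**31 - 1)),
            )
    return Fixture(truth, observations, precursor, reg, series)


def random_sequence(
    rng,
    dp: int,
    tag_name: str = "none",
    max_o_so3: int = 3,
    delta_nre: bool = True,
) -> SaccharideSequence:
    """Draw a grammar-valid uronic-first HS sequence of *dp* residues."""
    residues = []
    o_budget = int(rng.integers(0, max_o_so3 + 1))
    for i in range(dp):
        if i % 2 == 0:  # uronic position
            if i == 0 and delta_nre:
                kind = "DeltaHexA"
            else:
                kind = "GlcA" if rng.random() < 0.5 else "IdoA"
            sulf = set()
            if o_budget > 0 and rng.random() < 0.3:
                sulf.add("2S")
                o_budget -= 1
            residues.append(Residue(kind, None, frozenset(sulf)))
        else:
            n_state = "sulfo" if rng.random() < 0.6 else "acetyl"
            sulf = set()
            if o_budget > 0 and rng.random() < 0.4:
                sulf.add("6S")
                o_budget -= 1
            if o_budget > 0 and rng.random() < 0.1:
                sulf.add("3S")
                o_budget -= 1
            residues.append(Residue("GlcN", n_state, frozenset(sulf)))
    return SaccharideSequence(tuple(residues), TAGS.get(tag_name, NO_TAG))


def write_fixture(fixture: Fixture, out_dir) -> None:
    """Write observations.csv, truth.json and library.csv to a directory."""
    import pathlib

    from .library import write_library

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "observations.csv").write_text(fixture.observations_csv())
    (out / "truth.json").write_text(
        json.dumps(fixture.truth_record(), indent=1, sort_keys=True) + "\n"
    )
    write_library(fixture.registry, out / "library.csv")
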