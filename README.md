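# simms2

Shotgun ion-mobility mass-spectrometry sequencing of heparan sulfate
(HS) saccharides.

HS chains encode their biology in sulfation patterns (N-sulfo vs
N-acetyl glucosamine, 2-O-, 3-O- and 6-O-sulfates) and in the C5
epimerization of the uronic acid (GlcA vs IdoA). Mass spectrometry
alone cannot read this code: GlcA/IdoA and 3S/6S isomers are isobaric.
Drift-tube ion mobility adds a third, shape-sensitive observable — the
collision cross section in helium, ^DT CCS_He (Å²) — that separates
many of these isomers. `simms2` is a library and CLI for the resulting
sequencing strategy: fragment the unknown, measure the CCS of each
glycosidic fragment, and match fragments by mass *and* CCS against a
packaged library of fully defined standards. A match transfers the
standard's known residue sequence to the unknown's prefix (B/C ions)
or suffix (Y/Z ions); overlapping matches from several standards tile
the full chain.

The package provides, as importable modules behind one API:

- an HS sequence grammar, validation and monoisotopic mass model
  (`dUA-GlcNS-IdoA2S-GlcNS3S`, reducing-end tags R1/R2/R3);
- Domon–Costello B/C/Y/Z fragment generation with SO3-loss satellites,
  cross-checked by the exact complementarity B_i + Y_{n−i} = M;
- the stepped-field drift-tube chain: Gaussian ATD centroiding, the
  t_A-vs-1/V fit (slope L²/K, intercept t0) and the Mason–Schamp
  conversion Ω = (3ze/16N0)·sqrt(2π/(μ kB T))/K0, plus resolving-power
  and plate-number calculators and a synthetic ATD generator;
- a packaged CCS registry of 36 defined standards and two natural
  hexasaccharides, holding every published main-text precursor and
  fragment value as printed (integer Å²);
- the overlap sequencer: precursor-mass composition inference,
  exhaustive isomer enumeration (optionally constrained by a
  disaccharide-composition table), evidence matching with
  residue-for-residue agreement, coverage scoring and an honest
  unambiguous / ambiguous / insufficient verdict.

## Worked example: assigning a hexasaccharide from tetramer overlap

Four fragment ions of an unknown hexasaccharide were measured (m/z at
charge 1, with CCS): B2 496.0072 / 135 Å², B3 672.0393 / 160 Å²,
Y2 599.1070 / 156 Å², Y3 920.0894 / 213 Å², plus the precursor at
m/z 796.0644 (z = 2).

```python
import simms2 as s

reg = s.builtin_paper_library()
obs = [
    s.Observation(mz=496.0072, charge=1, ccs=135),
    s.Observation(mz=672.0393, charge=1, ccs=160),
    s.Observation(mz=599.1070, charge=1, ccs=156),
    s.Observation(mz=920.0894, charge=1, ccs=213),
]
prec = s.Observation(mz=796.0644, charge=2)

report = s.sequence(obs, reg, precursor=prec)
print(report.verdict_status, s.format_sequence(report.verdict_sequences[0]))
print(report.best.covered_sites)
for site, who in s.coverage_map(report, report.best.sequence).items():
    print(site, who)
```

prints

```
unambiguous GlcA-GlcNS6S-IdoA-GlcNS6S-GlcA-GlcNS6S-R1
(1, 2, 3, 4, 5)
1 [('#12', 'B2'), ('#12', 'B3'), ('#16', 'B2'), ('#16', 'B3')]
2 [('#12', 'B2'), ('#12', 'B3'), ('#16', 'B2'), ('#16', 'B3')]
3 [('#12', 'B3'), ('#14', 'Y3'), ('#16', 'B3'), ('#16', 'Y3')]
4 [('#14', 'Y2'), ('#14', 'Y3'), ('#16', 'Y2'), ('#16', 'Y3')]
5 [('#14', 'Y2'), ('#14', 'Y3'), ('#16', 'Y2'), ('#16', 'Y3')]
```

Reading this: out of 672 isomer candidates consistent with the
precursor mass, exactly one explains all four CCS-matched fragments.
The B-ion evidence comes from tetrasaccharide standard #12 (whose
non-reducing end matches the unknown's), the Y-ion evidence from
standard #14 (whose reducing end matches); their overlap covers all
five cleavage sites — the shotgun reconstruction in miniature. With no
CCS evidence at a GlcA/IdoA site the verdict would instead be
`ambiguous`, with the tied epimer variants listed.

The same operations are available from the shell:

```sh
simms2 mass "dUA-GlcNS"                   # 417.0577
simms2 resolve --delta 0.02 --rpp 0.75    # resolving power: 64
                                          # plate number: 22500
simms2 library query --ccs 135 --ccs-tol 0 --series B --index 2
simms2 sequence --obs obs.csv --precursor-mz 796.0644 --charge 2
simms2 simulate --ccs 242 --z 1 --mass 1500 --seed 7 --out atd.csv
simms2 ccs --atd atd.csv --mz 1500 --charge 1
```

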