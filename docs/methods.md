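# Methods

## The model

`endocharge` implements a minimal electrostatic model of why ApoE4–LDL
receptor complexes fail to release their receptor in acidifying
endosomes while ApoE3 complexes do.

Two kinds of domains enter the model:

* the **R112C domain** — the segment of the third amphipathic helix of
  the ApoE ligand-binding domain that carries the allele-defining
  position 112 (Cys in ApoE3, Arg in ApoE4) and runs alongside the
  receptor-binding stretch of helix 4;
* the seven **LDL-A repeats** (RP1–RP7) of the LDL receptor's
  N-terminal ligand-binding stalk — ~40-residue cysteine-rich repeats,
  each constrained by three internal disulfide bridges and rich in
  acidic `SDE`-motif residues.

Each domain is reduced to a point charge whose magnitude is its
Henderson–Hasselbalch net charge,

```
Z(pH) = Σ_b N_b / (1 + 10^(pH − pKa_b)) − Σ_a N_a / (1 + 10^(pKa_a − pH)),
```

summing over basic groups b ∈ {Arg, Lys, His, α-amino terminus} and
acidic groups a ∈ {Asp, Glu, Cys, Tyr, α-carboxyl terminus}.  Groups
titrate independently (no site–site coupling, no structure, no
dielectric screening, no temperature dependence).  Under this model Z
is strictly decreasing in pH, which the code exploits: isoelectric
points and curve crossings are unique and found by plain bisection.

The interaction statistic is the Coulomb-proportional charge product

```
α(pH) = Z_ligand(pH) · Z_repeat(pH)        [elementary-charge² units]
```

— positive α means electrostatic repulsion, negative α attraction.
The combined effect over the receptor stalk is the arithmetic mean of
α over the seven repeats; because the ligand factor is shared it
factorizes exactly as `mean α = Z_ligand · mean(Z_repeat)`, an identity
the tests assert to 1e−12.

The fate prediction evaluates each isoform's mean α at the
representative pH of each endocytic station (extracellular 7.5, very
early endosome 7.0–7.5, early endosome 6–7, late endosome 5.0–6.0),
classifies it against a neutrality threshold ε, and maps repulsive →
the ligand dissociates and the receptor recycles, neutral → the
complex remains bound, attractive → remains bound, or — in the late
endosome only — trapped and routed to lysosomal degradation.

## Sequence fixtures

The registry sequences are derived from the canonical mature human
ApoE (299 aa, signal peptide removed; C112/R158 defines the E3
isoform) and the N-terminal LDL-A region of the mature LDL receptor.
Both reference sequences ship in `data/reference.fasta`; the window
coordinates live in `data/config.yaml`, and
`domains.derive_builtins()` regenerates the registry from them (a test
asserts the shipped FASTA matches the derivation).

* **R112C window, mature 101–116** (`QARLGADMEDVCGRLV` for E3; C112R
  for E4).  The defining publication of this construct shows the
  segment only graphically, so the window is chosen structurally — the
  part of helix 3 opposite the receptor-binding residues 136–150 of
  helix 4 in the antiparallel four-helix bundle — and flagged
  `approximate: true` in the config.  The anchor quantities are
  insensitive to moving either bound by a few residues: every window
  in the scanned neighbourhood that keeps the same ionizable
  composition (2 Arg, 2 Asp, 1 Glu, the Cys, both termini) produces
  identical isoelectric points for both isoforms.
* **Repeat windows.**  Each repeat's core is fixed by its six
  conserved cysteines; the short flanks are fixed by the qualitative
  behaviour the reference curves display (RP7 the most positive repeat
  at every pH; RP1 the most negative above a single RP4/RP1 crossover
  near pH 4.6; RP4 the most negative below it).  The result is a
  uniform two-residue N-flank and one-residue C-flank, except RP1
  (which then coincides with the canonical LDL-A-1 domain annotation,
  mature 4–42) and RP4 (core plus one C-terminal residue).  These
  flanks are likewise recorded in the config as approximations.

Disulfide annotations mark all six cysteines of each repeat as
bridged.  The Cys at ApoE position 112 is the famous free thiol and is
never marked bridged.

## pKa tables and calibration

Six published pKa sets are registered: EMBOSS, Lehninger, Sillero,
Bjellqvist/ExPASy, Grimsley, and `protcalc_like` — a reconstruction of
the constants used by the classic "Protein Calculator" web tool
(N-term 8.0, C-term 3.1, D = E = 4.4, C 8.5, Y 10.0, H 6.5, K 10.0,
R 12.0), which is the kind of tool the reference curves were produced
with.  Because that tool's constants were never published alongside
the curves, `calibrate_table()` selects the registered set minimizing
the summed absolute deviation from five anchor pH values readable off
the reference curves (RP4/RP1 crossover 4.6; ApoE3×RP1 negativity
interval 4.25–4.75; ApoE4 mean-α negativity interval 4.5–6.0).  A
missing crossing is penalized by the full 14-unit pH span; ties break
by registry order.

The winner is `protcalc_like` (summed deviation 0.64), and it is
recorded as `default_pka_table` in `data/config.yaml` so ordinary runs
never re-calibrate.  Under it, four of the five anchors agree to
within 0.10 pH and the fifth — the upper end of the ApoE4 attraction
window — computes to 6.45 rather than 6.0.  That crossing is shallow
(|mean α| < 0.5 throughout pH 6–7, the "minimal interaction" regime),
so its read-off position is the least well-determined of the anchors;
`reproduce` writes the per-anchor deviations into `summary.json`
rather than hiding the discrepancy.  The Bjellqvist set is the runner-
up (every anchor within 0.20, summed deviation 0.74) and can be
selected with `--table bjellqvist`.  A side effect of the computed
crossover sitting at 4.70 instead of 4.6 is that RP4, not RP1, is the
most negative repeat on the two grid points between 4.60 and 4.70.

## Defaults and numerical choices

| parameter | default | units | rationale |
|---|---|---|---|
| pH grid | 4.0–8.0, step 0.05 (81 points) | pH | the range the reference curves cover |
| pKa table | `protcalc_like` | pH | calibration winner, recorded in config |
| `include_termini` | true | — | a pasted free peptide titrates both termini |
| `titrate_disulfide_cys` | true | — | naive-calculator behaviour; `--fixed-disulfides` gives the biophysically defensible alternative |
| ε (neutrality threshold) | 0.5 | charge² | operationalizes "minimal interaction"; with it the ApoE3 4.4–4.9 window and the ApoE4 5.6–7.1 window classify neutral, matching the narrative's minimal-interaction readings |
| bisection tolerance | 1e−4 | pH | all pI values and crossings |
| master seed | 20210510 | — | governs every randomized self-test |

Other numerical choices: curves between grid points are interpolated
linearly in pH, but crossing refinement always bisects the continuous
titration product, never the interpolant; interval endpoints that
coincide with the grid boundary mean the true crossing may lie outside
the computed range; when a curve has several disjoint negative
intervals the widest is returned and the rest are logged (the model
narrative assumes a single attraction window); `rank_repeats` breaks
exact ties by ascending repeat index; sequences whose charge never
changes sign raise a no-isoelectric-point error rather than returning
a boundary value.

Charges are dimensionless elementary-charge counts and α is their
product; no proportionality constant, distance or dielectric factor is
applied, so α orders interactions but is not an energy.

## Synthetic data and what the tests show

`synthetic.random_peptide` draws peptides of controlled length and
ionizable composition (each class count within one residue of its
target fraction, remainder glycine, deterministic per seed).  These
exercise every stage — counting, titration, products, interval
geometry — on inputs independent of the packaged fixtures.
`oracle_net_charge` recomputes Z as a deliberately naive per-residue
walk (no precomputed counts, no vectorization); the self-test sweeps
500 random peptides × 20 pH points and requires agreement with the
engine to 1e−9.

The generator emulates composition only: it produces no repeat
architecture, no disulfide constraints, no helical periodicity, and no
phylogenetic structure.  Passing tests therefore validate the
titration arithmetic and curve geometry, not the biological adequacy
of the point-charge reduction — the model's claims about real ApoE
and LDLR stand or fall with the independent-site, structure-free
assumptions above.

## Known limitations

* Point-charge, independent-site electrostatics: no distance or
  geometry, no charge–charge coupling, no Poisson–Boltzmann screening,
  no Ca²⁺ coordination by the repeats (which is known to matter for
  LDL-A folding), no glycosylation.
* The domain windows are graphically defined in the source material
  and therefore approximate; the config records them explicitly so
  they can be revised without touching code.
* ε converts "minimal interaction" into a hard threshold; fate labels
  near a boundary flip with ε, which is why ε is a config value
  surfaced in every report rather than a constant in logic.
* The compartment model is a static pH lookup; no kinetics, fluxes or
  steady-state receptor counts are computed.
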