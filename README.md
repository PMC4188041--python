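# rastriage

Structure-energy triage of RASopathy and cancer missense mutations, and a
mass-action network model of the Ras activation cycle.

RASopathies (Noonan, CFC, Costello, LEOPARD syndromes) are germline
developmental disorders caused by mutations in Ras/MAPK-pathway genes —
the same ~15 genes (PTPN11, SOS1, KRAS, BRAF, NF1, …) that are recurrently
mutated somatically in cancer. `rastriage` is a toolkit for asking, at the
level of protein structure energetics and network kinetics, *why the same
gene yields a developmental syndrome in one patient and a tumour in
another*. It is aimed at computational/systems biologists working with
precomputed force-field ΔΔG predictions (e.g. FoldX output), ortholog
alignments and in-vitro GTPase kinetics.

## What it computes

**Energy triage.** Each mutation carries a folding ΔΔG and optional
interface ΔΔG terms (kcal/mol, positive = destabilising). Terms are tiered
by magnitude — |ΔΔG| > 1.6 kcal/mol highly significant (2× the force-field
error SD), |ΔΔG| > 0.8 significant — and the dominant term above threshold
assigns a mechanistic class:

| class | mechanism (dominant term) |
|---|---|
| 1a | impaired domain–domain autoinhibition (intra-domain interface) |
| 1b | released inhibitory segment |
| 2 | perturbed protein–protein interaction |
| 3 | destabilised fold (folding ΔΔG) |
| 4 | altered localisation / half-life (literature evidence) |
| 5 | neutral (all terms sub-threshold, surface) |

plus `core_subthreshold` (buried, sub-threshold) and `not_modelled` (no 3D
coverage) buckets.

**Sequence triage.** For mutations without informative energies: Shannon
entropy H = −Σ pₐ log₂ pₐ of the mutated alignment column (conservation)
and the BLOSUM62 score of the substitution (chemical diverseness), each
thresholded at the disease-cohort mean; both criteria met → *likely*
disease-causing, one → *maybe*, none → *unlikely*. Also available as a
scikit-learn estimator (`SequenceTriage().fit(disease_X).predict(X)`).

**Ras-cycle model.** A seven-channel mass-action network —
GEF-catalysed exchange (RasD + GEF ⇌ RasD·GEF → RasT + GEF),
GAP-catalysed hydrolysis (RasT + GAP ⇌ RasT·GAP → RasD + GAP), the two
intrinsic conversions, and effector binding (RasT + EFF ⇌ RasT·EFF) — in
molecule units within a configurable reaction volume. Mutants substitute
fold changes of the five measured rate constants (k_GEF, k_GAP, intrinsic
exchange and hydrolysis, effector K_D). The readout is steady-state
RasT·EFF, the active-Ras–effector complex.

**Cohort statistics.** Welch's two-sample t-test (closed form) for the
germline-vs-somatic ΔΔG comparison and Pearson correlation of ΔΔG against
log₁₀ rate fold changes.

**Synthetic data.** `rastriage.synth` generates every input the pipeline
reads — catalogues, energy tables, MSAs with prescribed per-column
entropies, region maps, fold-change sets — as pure functions of a seed,
so the full pipeline runs and is tested entirely offline.

## Worked example

Classify one mutation (a Ras-like substitution that breaks the
GAP-binding interface while barely touching the fold):

```python
from rastriage import EnergyRecord, classify
from rastriage.energetics import InterfaceTerm, TermKind, Location

rec = EnergyRecord(
    gene="KRAS", position=12, wt_aa="G", mut_aa="V", has_structure=True,
    ddg_fold=0.9,
    interface_terms=(InterfaceTerm("RASA1", TermKind.INTER_PROTEIN, 2.7),),
    location=Location.SURFACE,
)
asg = classify(rec)
print(asg.klass.value, asg.tier.value, asg.driving_term)
```

prints

```
2 high ('inter_protein', 'RASA1', 2.7)
```

— class 2 (lost protein–protein interaction), highly significant, driven
by the 2.7 kcal/mol loss of the RASA1 interface: a GAP-insensitivity
mutation.

Simulate the packaged variants:

```bash
rastriage simulate --out sim.tsv
```

```
                       ras_t_eff  converged      residual
WT                    580.508574       True  5.994016e-11
oncogenic_reference  1039.069295       True  4.572787e-12
gap_loss             1018.894737       True  4.263256e-14
compensatory          999.377538       True  1.934522e-12
compensatory_mild     883.112354       True  1.014605e-12
```

`ras_t_eff` is the steady-state count of RasT·EFF complexes (out of 1200
effector molecules). The GAP-insensitive oncogenic reference nearly
saturates the effector; the partly compensatory variants — the same GAP
loss plus a weakened GEF-catalysed activation — land *between* wild type
and the pure GAP-loss variant, the quantitative signature of a milder,
RASopathy-like network deregulation.

Generate a full synthetic dataset:

```bash
rastriage synth --out data/
```

## Layout

- `rastriage.catalog` — catalogue parsing, de-duplication, origin
  summaries, domain/inter-domain region mapping
- `rastriage.energetics` — ΔΔG tiers, mechanistic classes, partition
  summaries, energy-table I/O
- `rastriage.seqtriage` — Shannon entropy, BLOSUM scores, mean
  thresholds, combined verdicts, `SequenceTriage` estimator
- `rastriage.rascycle` — the mass-action model, steady-state solver,
  fold-change parameterisation, variant comparison
- `rastriage.stats` — Welch/pooled t-test, rate–energy correlation,
  closed-form power
- `rastriage.synth` — synthetic-data generators
- `rastriage.cli` — `rastriage simulate` / `rastriage synth`

See `docs/methods.md` for the model details, parameter choices and known
limitations.
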