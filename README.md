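# gemctx

Multi-omics contextualization of genome-scale metabolic models (GEMs):
map transcript and protein abundances onto reactions through
gene-protein-reaction (GPR) rules, fuse the two layers by PCA into one
reaction-activity vector, extract a context-specific model with an
iMAT-style mixed-integer program, curate it (gap filling, leak/siphon
detection, element balancing), and simulate metabolic scenarios with
FBA / loopless FBA / FVA, including a prediction-accuracy statistic.

All optimisation runs on SciPy's HiGHS LP/MILP backend; no external
solver is required.

## Layout

| module | contents |
|---|---|
| `gemctx.model` | metabolites, reactions, GPR trees and parser, stoichiometric/element matrices, mass balance, JSON dialect I/O |
| `gemctx.sbml` | SBML Level 3 + FBC v2 subset reader/writer (libsbml) |
| `gemctx.preprocess` | omics tables: count filter, log2, validity filter, KNN imputation, z-score |
| `gemctx.integration` | GPR min/max mapping, PCA, transcript+protein fusion, signed-log threshold scaling |
| `gemctx.contextualize` | HIGH/MODERATE/LOW classification, iMAT MILP, context-model extraction, activity-derived bounds |
| `gemctx.curation` | dead ends, MILP gap filling against a universal database, leaks/siphons, minimal leakage modes, element balancing |
| `gemctx.simulate` | medium/concentration conversion, FBA, loopless FBA, FVA at a fixed objective, the four scenarios, prediction accuracy |
| `gemctx.synth` | deterministic toy models (chain/diamond/cycle-trap/random), the ~40-reaction astrocyte-mini model, paired synthetic omics with planted ground truth |
| `gemctx.workflow` | end-to-end pipeline glue |

## CLI

```bash
# generate a toy fixture with paired omics and ground truth
gemctx synth --topology random --n 24 --seed 7 \
    --out-model toy.json --out-transcripts t.tsv --out-proteins p.tsv \
    --out-groups groups.tsv --out-truth truth.txt

# map + fuse omics into a per-reaction activity table
gemctx integrate --model toy.json \
    --transcripts t.tsv --transcript-groups groups.tsv \
    --proteins p.tsv --protein-groups groups.tsv \
    --components 2 --out activity.tsv

# classify at the -500/+500 thresholds, solve iMAT, extract the context model
gemctx contextualize --model toy.json --activity activity.tsv \
    --low -500 --high 500 --eps 1.0 --out context.json

# consistency checks (add --universal udb.json to gap-fill)
gemctx curate --model context.json --report report.tsv

# scenarios and flux variability
gemctx synth --topology astrocyte-mini --out-model astro.json
gemctx simulate --model astro.json --medium dmem.tsv --scenario ischemia --out fluxes.tsv
gemctx fva --model astro.json --medium dmem.tsv --fix-objective 0.32 \
    --reactions EX_lac_e,EX_gln_e --out fva.tsv
```

Medium TSV is two columns (metabolite id, concentration in mM); omics TSV
is feature × sample with a separate two-column sample→group file; missing
values are `NA` or empty.

## Model JSON dialect

```json
{
  "schema_version": 1,
  "id": "model",
  "metabolites": [
    {"id": "glc_c", "name": "glucose", "compartment": "c",
     "formula": "C6H12O6", "charge": 0}
  ],
  "reactions": [
    {"id": "GLYC", "name": "", "stoichiometry": {"glc_c": -1.0, "pyr_c": 2.0},
     "lower_bound": 0.0, "upper_bound": 1000.0,
     "gpr": "HK1 and GAPDH and PKM", "is_exchange": false, "subsystem": ""}
  ],
  "objective": {"reaction": "GLYC", "sense": "max"}
}
```

Compartment codes are one of `c e g i l m n r x`.  Exchange reactions are
single-metabolite boundary reactions `M ->`; uptake is negative flux.
SBML I/O covers the FBC v2 subset (species formula/charge, parameter
bounds, gene-product associations, one maximisation objective); anything
outside the subset raises instead of being dropped.

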