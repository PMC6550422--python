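# cepsb

Construction, validation and coding-error audit of hospital-discharge-database
(HDD) detection algorithms for **complicated ectopic pregnancy with severe
bleeding (CEPSB)** — a maternal near-miss condition — plus a calibrated
synthetic cohort generator so that every stage is testable without access to
real hospital records.

A stay is a CEPSB case (gold standard, from chart review) when the ectopic
pregnancy is histologically confirmed and at least one of: tubal rupture,
hemoperitoneum ≥ 500 cc (inclusive), or active bleeding. Detection algorithms
are declarative conjunctions of scoped ICD-10/CCAM code-set clauses plus an
administrative eligibility filter; two algorithms ship as built-ins
(`predefined`, guideline-based; `pragmatic`, practice-based), and a derivation
stage reconstructs the practice-based rule from data (two-sided Fisher
screening, code-level LR+ > 4).

## Modules

| module | role |
| --- | --- |
| `cepsb.records` | domain types, code syntax, gold-standard classification, CSV/JSONL stay I/O |
| `cepsb.coding` | shared code sets and the nine-type coding-error taxonomy |
| `cepsb.engine` | declarative detection algorithms, built-ins, evaluation over cohorts |
| `cepsb.derivation` | per-code screening (Fisher exact, Haldane-corrected LR+) and selection |
| `cepsb.validity` | confusion matrices, Se/Sp with Wald (or Wilson) 95% CIs, LR+ with log-method CI, two-center comparisons |
| `cepsb.synthetic` | truth-labeled cohort generator, ideal coding, seeded error injection, calibrated default model |
| `cepsb.audit` | classify false negatives/positives into the error taxonomy, tabulate shares |
| `cepsb.cli` | `cepsb` command: `simulate`, `validate`, `derive`, `audit`, `report-all` |

## CLI

```bash
# synthetic cohort (370 stays, 52 cases, calibrated error model) + error log
cepsb simulate --seed 1 --out out/sim

# validity table (Se/Sp/LR+ with CIs) for the built-ins or a config file
cepsb validate --input out/sim/stays.csv --algorithm predefined \
    --algorithm pragmatic --format md --out out/validity

# data-driven algorithm derivation + screening report
cepsb derive --input out/sim/stays.csv --alpha 0.05 --lr-threshold 4 --out out/derived

# coding-error audit behind one algorithm's misses
cepsb audit --input out/sim/stays.csv --algorithm predefined --out out/audit

# everything end to end
cepsb report-all --seed 1 --out out/report
```

Every command writes a `manifest.json` (seed, config, output hashes); report
content carries no timestamps, so reruns are byte-identical.

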