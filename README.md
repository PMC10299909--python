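# pharmsel

Quantitative pharmacology of receptor selectivity, built around the question
of whether a ligand's preference for one receptor subtype over another is
driven by binding affinity or by efficacy. The package implements the full
analysis chain used to answer it:

- **`pharmsel.binding`** — radioligand saturation binding (global total +
  nonspecific fit with shared NS slope), one-/two-site competition fits with
  AICc model selection, and Cheng–Prusoff conversion of IC50s to pKi.
- **`pharmsel.operational`** — three-parameter logistic potency fits and the
  operational model of agonism (Basal, Em, logKA, logτ) with KA optionally
  constrained to binding-derived pKi, shared-Em/Basal panel fitting, and
  expression-corrected efficacy τ_C (τ ∝ receptor density).
- **`pharmsel.ternary`** — exact mass-action equilibrium of the
  ligand/receptor/G-protein ternary complex (vectorized fixed-point solver
  with a guaranteed bisection fallback), prediction of radioligand
  displacement curves across a G-protein titration, global fitting of
  (pK_L, α, pK_G), and conversion of affinities to per-edge binding free
  energies with exact thermodynamic-cycle closure.
- **`pharmsel.trajstate`** — geometric features from MD coordinate tables
  (Cα–Cα distances, χ1 dihedrals), threshold state classifiers
  (channel-open, active, TM6-outward, tail-vertical) with time-based
  equilibration masks, per-simulation state frequencies, 30-ns moving
  averages and conditional (grouped) fractions.
- **`pharmsel.stats`** — seeded percentile bootstrap CIs of the mean
  (default 68%) and the Mann–Whitney U test with an exact enumeration path
  for small samples.
- **`pharmsel.synthetic`** — ground-truth generators for every input:
  noisy operational dose-response curves, saturation/competition binding
  curves, and two-state Markov feature traces with known occupancies.
- **`pharmsel.tables` / `pharmsel.cli`** — schema-validated delimited-text
  I/O (comma separator, `.` decimal, `#` provenance headers) and a
  subcommand CLI tying the stages together.

## CLI

```bash
pharmsel simulate --kind dose-response --out out/ --seed 1
pharmsel fit-operational --input out/dose_response.csv --log-ka -7 \
    --expression-a 1000 --expression-b 2000 --out out/op.json
pharmsel simulate --kind binding --out out/ --seed 1
pharmsel fit-competition --input out/binding_curve.csv --sites auto --out out/comp.json
pharmsel fit-ternary --config ternary.yaml --out out/ternary.json
pharmsel simulate --kind markov --out out/ --seed 1
pharmsel traj-states --input out/feature_series.csv --state channel_open \
    --group condA --out out/freq.csv
pharmsel compare-groups --input freqs.csv --group-a condA --group-b condB \
    --out out/cmp.json
pharmsel full-report --out out/report --seed 1
```

Exit codes: 0 success, 2 configuration error, 3 data error, 4 numerical
failure. Every output carries a provenance header (tool version, config
hash, seed) and each run appends to a `manifest.jsonl`.

`full-report` generates packaged synthetic fixtures with known truth and
runs every stage end to end, producing a single summary table (logτ, τ_C,
pKi high/low, log α, ΔΔG, per-condition channel-open frequencies).

## Conventions

- All affinities/potencies are carried as negative log10 molar (pKd, pKi,
  pIC50, pEC50); concentrations as log10 molar.
- Dihedrals are degrees on (−180, 180]; classifier thresholds are strict
  inequalities; equilibration exclusion windows are specified in ns and
  applied through the time axis.
- Free energies use ΔG = −RT·ln(10)·pK (association, 1 M standard state);
  cooperativity coupling energy ΔΔG = −RT·ln α. Temperature defaults to
  310.15 K and is selectable.
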