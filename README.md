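# mrscreen

Two-sample Mendelian randomization (MR) screening of many exposures against a
single outcome, from GWAS summary statistics only.

The package implements the full screening pipeline used in metabolome-wide MR
studies of a binary disease outcome:

* **`mrscreen.sumstats_io`** — read/validate tab-delimited GWAS summary
  statistics, harmonize exposure and outcome effects to a shared effect allele
  (allele swaps, strand complements, palindromic-variant policies), write
  stable results tables.
* **`mrscreen.instrument_selection`** — instrument selection: association
  p-value filter (default p < 1e-5), greedy LD clumping (r² ≤ 0.1 within
  ±500 kb, LD supplied as a pairwise r² table), weak-instrument exclusion
  (single-SNP F = (β/se)² < 10), and removal of outcome-associated variants
  (p < 1e-5).
* **`mrscreen.mr_estimators`** — the four causal-effect estimators on the
  log-odds scale: IVW (fixed or multiplicative random effects; the primary
  method), MR-Egger with its intercept test, the bootstrap weighted median,
  and MR-PRESSO (global RSS test, per-variant outlier test, outlier-corrected
  estimate, distortion test).
* **`mrscreen.sensitivity`** — Cochran's Q under the IVW and Egger fits,
  leave-one-out influence series, and the Steiger directionality test.
* **`mrscreen.pipeline_screen`** — orchestration across exposures, Bonferroni
  control, and the classification rule: `not_significant` / `potential`
  (IVW p < 0.05) / `robust` (additionally ≥ 2 of Egger/WM/PRESSO at p < 0.05
  with sign-consistent IVW/Egger/WM estimates) / `strong` (robust and IVW
  p < α/m).
* **`mrscreen.synthetic_data`** — a summary-statistic simulator with known
  ground truth (causal effect, balanced/directional pleiotropy, InSIDE
  violation, case/control imbalance, allele scrambling, LD decoys) plus a
  Monte-Carlo operating-characteristics harness.
* **`mrscreen.examples`** — a bundled worked example: the printed
  per-metabolite results of a published 486-metabolite screen against
  idiopathic pulmonary fibrosis (23 IVW-significant hits), used to exercise
  the classification and Steiger rules on real printed numbers.

## Command-line interface

```sh
# simulate a dataset with known truth
mrscreen simulate --k 30 --theta 0.4 --h2 0.3 --n-decoys 10 --seed 1 --out sim/

# instrument selection for one exposure
mrscreen select-iv --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
    --ld sim/ld.tsv --pval 1e-5 --r2 0.1 --window-kb 500 --fmin 10 \
    --out harmonized.tsv

# estimators and diagnostics on the harmonized table
mrscreen mr --harmonized harmonized.tsv --methods ivw,egger,wm,presso \
    --seed 1 --out mr.tsv
mrscreen sensitivity --harmonized harmonized.tsv --nexp 7000 --nout 198014 \
    --out sensitivity.json

# full screen: one TSV per exposure in a directory, one shared outcome
mrscreen screen --exposures exposures/ --outcome outcome.tsv --ld ld.tsv \
    --config config.yaml --out results/
```

Summary-statistics TSVs use the headers
`snp_id chrom pos effect_allele other_allele eaf beta se pval n`
(override with `column_map` in the API); LD tables use
`snp_id_1 snp_id_2 r2`; the screen config YAML mirrors
`mrscreen.ScreenConfig` fields.

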