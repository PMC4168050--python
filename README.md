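# nodentropy

Quantifying the tissue specificity, developmental timing and expression
strength of a nodule-specific gene family from a transcriptome compendium.

## The problem

Legumes house nitrogen-fixing rhizobia inside root nodules, where the
symbiotic cells of *Medicago truncatula* express hundreds of
nodule-specific cysteine-rich (NCR) peptide genes that drive bacteroid
differentiation. Establishing that such a family is expressed
*exclusively* in nodules — in no other organ, under no stress, and not as
part of nodule senescence — requires mining a large probe-set × condition
expression compendium (organs, time courses, dissected nodule zones,
laser-captured cell types, treatment contrasts) with a reproducible set of
statistics. `nodentropy` packages that analysis for anyone asking the
same question of any organ-specific gene family:

* **Tissue specificity by Shannon entropy.** Conditions are pooled into
  `N` tissue classes (the reference panel has `N = 10`: leaf, petiole,
  stem, bud, flower, seed, pod, root, nodule, mycorrhiza). For gene *g*
  with mean signal `W_t` in tissue *t*, the relative expression is
  `P_t = W_t / Σ_t W_t` and the entropy is

  ```
  E_g = − Σ_t  P_t · log2(P_t),        0·log2(0) := 0
  ```

  `E_g` runs from 0 (single-tissue expression) to `log2(N)` (uniform;
  3.32 bits for `N = 10`). Genes are ranked by increasing entropy and the
  `k` most specific selected.
* **Temporal activation waves.** Over a nodule time course (days post
  inoculation, dpi), each gene's signal is referenced to the mature
  14 dpi stage; genes are assigned to wave 1/2/3 by the first dpi
  (4, 6, or 10–14) at which they pass an activation rule, and classified
  as maintained or declining in older nodules.
* **Zone profiles and clustering.** Five hand-dissected zone samples
  (I meristem … IV senescence) yield per-gene profiles
  `log2(zone / five-zone mean)`, clustered by average-linkage (UPGMA)
  under Euclidean or correlation (1 − r) distance with deterministic
  tie-breaking.
* **Screens and QC.** Welch t-test screens (senescent zone IV vs fixation
  zone III, uninfected vs infected cells, senescence induction),
  per-gene maximal-signal statistics, flagging of family members with
  relaxed specificity, and marker-based detection of cross-contaminated
  samples.

Because the original compendium is a network resource, the package ships
a synthetic-compendium generator that emulates its structure with fully
known planted truth (family membership, waves, relaxed genes, the
contaminated sample), so the entire pipeline is testable offline and
recovery rates are measurable.

## Worked example

A full synthetic run — simulate, entropy, waves, zones, screens, QC —
from the command line:

```sh
nodentropy run --seed 1 --outdir demo_run
```

writes every stage's TSV tables plus `summary.json`. Key fields of the
summary for seed 1 (500 genes, 65 of them the planted nodule-specific
family, 84 conditions):

```json
"entropy": {"n_tissues": 10, "max_entropy": 3.321928, "k": 100,
            "family_in_selected": 64, "family_recovery": 0.984615,
            "median_family_rank": 33.0, "low_entropy_odds_ratio": 470.644},
"waves":   {"family_wave_counts": {"1": 12, "2": 29, "3": 24},
            "wave_recovery": 0.984615},
"screens": {"zone_III_vs_IV": {"n_family_flagged_higher_in_IV": 0},
            "uc_vs_ic": {"top_hit": "NCR0061", "top_fold": 10.206},
            "senescence": {"family": {"frac_down": 1.0},
                           "senescence_marker": {"frac_up": 1.0}}},
"qc":      {"contamination_flags": ["mycorrhiza_r3"],
            "relaxed_flagged": ["NCR0061", "NCR0062", "NCR0063",
                                "NCR0064", "NCR0065"]}
```

Reading: 64/65 planted family genes fall inside the 100 lowest-entropy
genes (median specificity rank 33 of 500; the odds ratio of family
membership in that low-entropy set is ≈471). Wave labels are recovered
for 98% of family genes. No family gene is significantly higher in the
senescent zone IV than in the fixation zone III, every family gene drops
under senescence induction while all senescence markers rise, the one
planted uninfected-cell-biased gene tops the UC/IC screen at ≈10-fold,
the cross-contaminated mycorrhiza sample is the unique contamination
flag, and exactly the five planted relaxed-specificity genes are flagged.

The same stages are available as library functions
(`nodentropy.shannon_entropy`, `assign_waves`, `two_group_screen`, …) and
as individual subcommands (`simulate`, `entropy`, `waves`, `zones`,
`screens`, `qc`).

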