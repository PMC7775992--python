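# dynfc

Time-resolved functional connectivity metastate analysis for task fMRI
ROI time series, with a fully synthetic cohort generator so the entire
pipeline is testable without any imaging data.

The pipeline, end to end:

1. **QC** (`dynfc.qc`) — participant motion exclusion from FD/DVARS
   confound traces (exclude if >25% of volumes have FD > 0.25 mm or
   DVARS > 4%, or mean FD > 0.2), cohort-wide node-dropout masking
   (mean signal intensity z ≤ −1.64 in any participant), and OLS removal
   of HRF-convolved task-event regressors.
2. **Coupling** (`dynfc.coupling`) — multiplication of temporal
   derivatives (MTD): SD-normalised first differences multiplied
   pairwise, averaged over non-overlapping 15-TR windows (a 179-volume
   run gives 11 windows; three runs give 33).
3. **Communities** (`dynfc.communities`) — multilayer (time-linked)
   modularity maximisation (greedy Louvain on the multislice quality,
   γ = ω = 1, ordinal inter-layer coupling), plus flexibility,
   allegiance, recruitment/integration coefficients and community
   counts.
4. **Cartography** (`dynfc.cartography`) — per-window participation
   coefficients and module degree z-scores, 10 × 10 cartographic
   profiles, k-means (k = 2) labelling of windows as
   integrated/segregated within participant, and the per-participant
   mean integrated FC network averaged over runs and detection
   repetitions (100 by default).
5. **NBS** (`dynfc.nbs`) — edge-wise GLMs (ANCOVA for group, multiple
   regression for symptom-change associations), supra-threshold
   connected-component extraction over an F-threshold sweep (6–28),
   Freedman–Lane permutation FWE inference (5,000 permutations,
   α = .025), Cohen's f² effect sizes and annotated sub-network reports.
6. **Synthetic cohorts** (`dynfc.synthetic`) — multi-run BOLD cohorts
   with window-aligned integrated/segregated regime truth, BIDS-style
   events and confounds, phenotypes, and a planted
   sub-network ↔ symptom-change association for validating recovery.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (windowing
counts, brute-force graph-metric oracles, exhaustive-search modularity
optimality, metastate recovery from synthetic truth, NBS null
calibration over 200 cohorts, planted sub-network recovery, invariance
suite, and full-pipeline determinism). The whole suite runs in a couple
of minutes.

## CLI

```sh
# simulate a cohort directory (TSV/CSV/JSON, all plain text)
dynfc simulate --n-participants 12 --n-nodes 20 --seed 7 --out cohort/

# full pipeline from a cohort spec
dynfc all --seed 7 --simulate-spec spec.yaml --config config.yaml --out out/

# or stage by stage (each stage re-loads the previous stage's artifacts)
dynfc qc --input cohort/ --out qc/
dynfc coupling --input qc/cleaned --out windows/
dynfc communities --input qc/cleaned --out partitions/
dynfc metastates --input qc/cleaned --config config.yaml --out meta/
dynfc nbs --networks meta/integrated_networks --pheno cohort/phenotype.csv \
          --analysis panss_positive_change --out nbs.json
dynfc report --summaries meta/metastate_summaries.csv \
             --pheno cohort/phenotype.csv --out report.json
dynfc sweep --spec spec.yaml --axes '{"window_length_tr": [10, 15, 20]}' \
            --out sweep.csv
```

`config.yaml` keys mirror `dynfc.pipeline.PipelineConfig` (window
length/offset, CP bins, γ/ω, repetitions, NBS thresholds/permutations/α,
motion and dropout thresholds, root seed); unknown keys are rejected.
All randomness flows from the one root seed, so reruns are numerically
identical.

## Input formats

- time series: TSV, volumes × nodes, header = node ids
- events: BIDS-style TSV (`onset`, `duration`, `trial_type`)
- confounds: TSV (`framewise_displacement`, `std_dvars`; fMRIPrep
  naming, first-row NaN tolerated)
- node metadata: TSV (`node_id`, `x`, `y`, `z`, `system`)
- phenotype: CSV, one row per participant

Outputs are TSV adjacency matrices, CSV summaries and JSON
reports/manifests.
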