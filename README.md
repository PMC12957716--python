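# hippnet

Longitudinal hippocampal-subfield atrophy, co-atrophy networks, and
centrality-based hub analysis.

## What this is for

In people converting from mild cognitive impairment (MCI) to Alzheimer's
disease, the hippocampus does not shrink as a single unit: its subfields
(CA1–CA4, dentate gyrus, subiculum, presubiculum, parasubiculum, molecular
layer, fimbria, HATA, tail, fissure — each split into head/body where the
segmentation supports it, 19 regions per hemisphere, 38 in all) atrophy at
different rates and in correlated groups.  `hippnet` implements the full
analysis chain for two-visit subfield volume tables:

1. **Change scores** — per subject and region,
   `change (%) = 100 · (V_followup − V_baseline) / V_baseline`, and the same
   percentage change for the MMSE cognitive score.
2. **Paired tests** — per-subfield paired *t*-tests of baseline vs.
   follow-up volume, and a paired test of per-subject left- vs.
   right-hemisphere mean change (hemispheric asymmetry).
3. **Cognition associations** — partial Pearson correlations between each
   subfield's volume change and MMSE decline, adjusting for baseline age,
   sex, education band, and APOE ε4 allele count
   (`t = r·√(df/(1−r²))`, `df = n − k − 2`).
4. **Structural covariance network** — the 38×38 matrix of pairwise
   covariate-adjusted partial correlations between subfield changes;
   entries with `p ≥ α` (default 0.05) are zeroed, giving the adjacency
   matrix of an undirected weighted graph whose edge weights are the
   signed partial correlations.
5. **Centrality and hubs** — degree `D_i = Σ_j a_ij` (binary indicator),
   unnormalized betweenness `B_i = Σ_{x<y} g_xiy / g_xy`, closeness
   `C_i = (N−1) / Σ_j l_ij` (Wasserman–Faust on disconnected graphs), and
   eigenvector centrality `E_i = (1/λ) Σ_j a_ij E_j` with λ the largest
   adjacency eigenvalue; nodes in the top-k (default 5) of **all four**
   metrics form the consensus hub set.

Because two-visit subfield volume tables from clinical cohorts are
access-restricted, the package ships a first-class synthetic cohort
generator (`hippnet.cohort`) whose defaults emulate a 258-subject MCI-to-AD
cohort: age 75.1 ± 7.17 y, 39.53 % female, MMSE 26.40 ± 1.93 declining by
−12.9 % (SD 13.8), hemisphere-mean atrophy −6.35 % (left) and −5.47 %
(right) over two years, with latent-factor co-atrophy structure.  Every
stage of the pipeline is tested against this generator and against
independent brute-force oracles.

## Worked example

```bash
hippnet run-all --outdir demo --seed 1
```

prints

```
{
  "n_subjects": 258,
  "n_edges": 632,
  "lambda_max": 35.00317907981155,
  "consensus_hubs": [
    "CA1 body L",
    "HATA R",
    "Subiculum body R"
  ]
}
manifest: demo/manifest.json
```

632 of the 703 possible subfield pairs show a significant co-atrophy
partial correlation at α = 0.05 — a dense network, as expected when a
global atrophy process drives most regions — and three subfields sit in
the top five of all four centrality metrics simultaneously.  `demo/`
contains one artifact per stage: the simulated cohort and its resolved
configuration, `changes.csv`, `atrophy_tests.tsv` (all 38 subfields
significant at p < 0.001 under the default atrophy means), `asymmetry.tsv`
(left mean −6.36 % vs. right −5.49 %, p ≈ 8×10⁻¹²), `associations.tsv`
(Pearson r up to ≈ 0.19 with significance stars), the full `correlation_r`
/ `correlation_p` matrices, `adjacency.csv` + `edges.tsv`, `centrality.csv`
(Table of D, B, C, E per subfield), `hubs.json`, and a `manifest.json`
that reproduces the run exactly.

The same stages are available as library calls
(`generate_cohort`, `compute_change_table`, `subfield_atrophy_report`,
`associate_cognition`, `pairwise_partial_correlations`,
`threshold_network`, `compute_centrality_profile`, `consensus_hubs`) and
as individual CLI subcommands (`simulate`, `changes`, `ttest`,
`associate`, `network`, `centrality`).

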