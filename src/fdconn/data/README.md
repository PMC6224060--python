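# Packaged reference tables

Small delimited tables transcribed from the published reference study of
resting-state functional connectivity across the lifespan (133 healthy
subjects, 94 Harvard-Oxford cortical nodes). They serve two purposes:

1. the atlas node table (`atlas.tsv`) and the grouping schemes
   (`table1.csv`, `table9.csv`) are part of the pipeline contract;
2. the remaining tables are *fixtures*: published summary outputs used to
   validate selection rules (link frequencies, centrality indices,
   principal/secondary vertex sets) without access to the original scans.

| file | content |
|---|---|
| `atlas.tsv` | 94 Harvard-Oxford cortical nodes: id, hemisphere, region name (1–47 left, 48–94 right) |
| `table1.csv` | cohort composition: 14 age groups × sex, totals 51 M / 82 F / 133 |
| `table3_male.csv`, `table3_female.csv` | emerging links and their frequency over the 14 groups per sex (row order as printed) |
| `table4_male.csv` | per-group intensities of the male emerging links |
| `table5_female.csv` | per-group intensities of the female emerging links |
| `table6_male.csv`, `table6_female.csv` | centrality index per node, per sex |
| `table9.csv` | merged 7-group scheme with per-sex counts |
| `table10.csv` | published global-analysis p-values (documented expectation only; not reproducible without the scans) |
| `table11.csv` | published local-analysis p-values for the two flagged groups (documented expectation only) |

## Corrections

- `table4_male.csv`, link 28–75 at group M7: the source prints `45`, an
  obvious decimal-point typo for `0.45` (every other intensity lies in
  [0, 1]); packaged as `0.45`.

## Notes

- `table3_female.csv` preserves the printed row order, in which the
  frequency-11 link 1–48 precedes the frequency-12 link 69–78; consumers
  should not assume the file is strictly sorted.
- The published comparison between degree-distance-weighted and pure
  correlation matrices used a data-derived threshold of 0.1116 selecting
  four links (31–78, 59–89, 59–93, 12–42); this is a documented
  expectation, not reproducible from these tables.
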