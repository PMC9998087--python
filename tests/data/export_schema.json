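{
 "validation": [
  "problem"
 ],
 "architecture": [
  "animal_id",
  "condition",
  "window",
  "metric",
  "value"
 ],
 "stats_main": [
  "window",
  "metric",
  "F",
  "df1",
  "df2",
  "p",
  "epsilon",
  "method",
  "n_complete",
  "error"
 ],
 "stats_posthoc": [
  "window",
  "metric",
  "condition",
  "n_pairs",
  "t",
  "df",
  "p_raw",
  "p_adj",
  "d",
  "tested"
 ],
 "transitions": [
  "condition",
  "from",
  "to",
  "kind",
  "observed_diff",
  "p_value",
  "significant",
  "cohens_d",
  "p_bonferroni",
  "n_animals"
 ]
}
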