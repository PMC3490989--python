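[
 {
  "name": "growth_reference_synthetic",
  "path": "growth_reference_synthetic.csv",
  "sha256": "adcf0af209363d91c75a11b747c5039229b1797b5b5c72ed6638acc070e1feb5"
 },
 {
  "name": "toy_cohort_synthetic",
  "path": "toy_cohort_synthetic.csv",
  "sha256": "fc7fd65094f4041ebc85602750415422b4bac9db651012634b715b8d1f2406ca"
 },
 {
  "name": "prevalence_by_cohort",
  "path": "prevalence_by_cohort.csv",
  "sha256": "3f054e13202773d9998dd34f86a053226f5dd661938c86772a9e9300609b75fb"
 },
 {
  "name": "stunting_by_income_quintile",
  "path": "stunting_by_income_quintile.csv",
  "sha256": "357eec9b9ef89c0597465ce5e98ff21b923c6157fbce97d6bf34a61dfcef0980"
 },
 {
  "name": "overweight_by_income_quintile",
  "path": "overweight_by_income_quintile.csv",
  "sha256": "dcbea672763a34c8e14de5b5276f3cb0dbf87c63bb7e1987db83a04283124184"
 }
]
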