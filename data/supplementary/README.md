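# Study supplementary tables (not distributed)

The published study's supplementary tables are deposited on Zenodo and
are **not** redistributed with this repository. The reproduction tests in
`tests/test_acceptance.py` look for them here under the following names
and schemas (CSV with header):

- `si5_reference_fauna.csv` — African reference fauna:
  `species,weight_kg,e_kcal,h_hr,c_hr,p_fail`
- `si6_species_list.csv` — European target species list:
  `species,common_name,weight_kg`
- `si2_ctu_table.csv` — combined CTU table:
  `ctu,suit_reindeer,suit_boar,suit_red_deer,suit_elk,suit_horse,
   nisp_reindeer,nisp_boar,nisp_red_deer,nisp_elk,nisp_horse,
   mean_spd,mean_warm_t`
- `si4_faunal_records.csv` — zooarchaeological records with raw labels:
  `assemblage_id,technocomplex,...`

When the files are absent those reproduction tests fail with an
explanatory message; every other test runs on synthetic data generated at
test time.
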