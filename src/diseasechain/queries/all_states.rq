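# (a1) every abnormal state in the dataset
PREFIX dont: <http://diseasechain.example.org/ontology#>
SELECT DISTINCT ?state WHERE {
  ?state a dont:Abnormal_State .
}
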