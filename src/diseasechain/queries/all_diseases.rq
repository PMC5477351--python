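# (d1) every disease in the dataset
PREFIX dont: <http://diseasechain.example.org/ontology#>
SELECT DISTINCT ?disease WHERE {
  ?disease a dont:Disease .
}
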