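# (a2) all causes of a selected abnormal state
PREFIX dont: <http://diseasechain.example.org/ontology#>
SELECT DISTINCT ?cause WHERE {
  dont:__ID__ dont:hasCause ?cause .
}
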