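# (d4) derived-chain states of a selected disease, aggregated over its
# super diseases
PREFIX dont: <http://diseasechain.example.org/ontology#>
SELECT DISTINCT ?state WHERE {
  dont:__ID__ dont:subDiseaseOf* ?disease .
  ?disease dont:hasDerivedState ?state .
}
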