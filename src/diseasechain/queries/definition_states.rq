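# (d5) all states appearing in the definition of a selected disease:
# the union of (d3) and (d4)
PREFIX dont: <http://diseasechain.example.org/ontology#>
SELECT DISTINCT ?state WHERE {
  dont:__ID__ dont:subDiseaseOf* ?disease .
  ?disease (dont:hasCoreState|dont:hasDerivedState) ?state .
}
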