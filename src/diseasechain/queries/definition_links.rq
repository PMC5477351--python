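# (d6) all causal relationships among the definition states of a
# selected disease
PREFIX dont: <http://diseasechain.example.org/ontology#>
SELECT DISTINCT ?x ?p ?y WHERE {
  dont:__ID__ dont:subDiseaseOf* ?d1 .
  ?d1 (dont:hasCoreState|dont:hasDerivedState) ?x .
  dont:__ID__ dont:subDiseaseOf* ?d2 .
  ?d2 (dont:hasCoreState|dont:hasDerivedState) ?y .
  ?x ?p ?y .
  FILTER(?p IN (dont:hasCause, dont:hasResult, dont:hasProbableCause, dont:hasProbableResult))
}
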