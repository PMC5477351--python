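# (d2) all super diseases of a selected disease
PREFIX dont: <http://diseasechain.example.org/ontology#>
SELECT DISTINCT ?super WHERE {
  dont:__ID__ dont:subDiseaseOf+ ?super .
}
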