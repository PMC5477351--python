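# (a3) the general causal chain through a selected abnormal state:
# follow all causal properties recursively in both directions
PREFIX dont: <http://diseasechain.example.org/ontology#>
SELECT DISTINCT ?state WHERE {
  dont:__ID__ (dont:hasCause|dont:hasResult|dont:hasProbableCause|dont:hasProbableResult)* ?state .
}
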