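# morm — multi-ontology concept relatedness in biomedical knowledge networks

`morm` builds a hybrid **biomedical knowledge network** (BMKN) — a typed,
weighted, directed graph `G = (V, E, C, S)` whose concepts come from several
ontologies (diseases, symptoms, genes, chemicals, ...) — and discovers
*implicit* relatedness between concepts that are not directly linked: diseases
that share symptoms and get misdiagnosed for one another, diseases related
through common gene-product properties, chemicals indirectly tied to a
disease. It is aimed at researchers exploring candidate relationships across
ontologies such as DO, SYMP and GO combined with literature-derived links.

## The model

Every concept `v` belongs to exactly one ontology (`Φ(v)`), every edge has a
relation type (`Ψ(e)`), a confidence `C(e) ∈ [0,1]` and a significance
`S(e) ∈ [0,1]`. Edges within one ontology are **intra**-relationships, edges
across ontologies **inter**-relationships. Around an *anchor concept* the
engine computes an indexed family of concept sets, for each ontology `t`:

```
 iO_t^j = ⎧ i-1O_t^j ∪ iO_t^(j-1)                        i = j
          ⎨ iO_t^(j-1)·R_intra ∪ iO_t^(j-1)              i < j
          ⎩ ⋃_{k≠t} (i-1O_k^(i-1)·R_inter) ∪ i-1O_t^j    i > j
```

grounded at `O_t^0` (the anchor's forward intra neighbors in its own
ontology, its forward inter neighbors elsewhere). `·R_intra` / `·R_inter`
are one-step forward neighbor operators. The diagonal `iO_t^i` is the
relatedness set after `i` full steps; the union over ontologies, with the
induced edges, is the **relatedness network** (RN). The **interesting set**

```
F(i) = iO_t^i − 0O_t^i
```

removes everything reachable by intra expansion alone, leaving exactly the
concepts connected to the anchor through cross-ontology paths — the implicit
candidates. Link masks `R(t, c, s)` prune traversal per relation type
(include flag, strict confidence/significance thresholds); corpus-derived
edges are weighted by max-normalized TF-IDF co-occurrence (confidence) and
mean publication impact factor (significance).

## Worked example

The bundled two-ontology fixture reproduces the classic misdiagnosis
scenario: Lupus (anchor `D0`) has the symptom *Painful Swollen Joint*
(`S2`), which is near *Joint Swelling* (`S3`), a symptom of *Rheumatoid
Arthritis* (`D11`).

```python
from morm import AnchorSpec, fig3_fixture, initial_sets, interesting_set, relatedness_network

net = fig3_fixture()
anchor = AnchorSpec("D0", steps=2)

print(sorted(initial_sets(net, anchor)["D"]))          # ['D1', 'D2']
print(sorted(initial_sets(net, anchor)["S"]))          # ['S1', 'S2']

rn = relatedness_network(net, anchor)
print(len(rn.nodes), len(rn.edges))                    # 13 14

f2 = interesting_set(net, anchor, 2, "D")
print(sorted(f2))                                      # ['D10', 'D11', 'D12', 'D9']
print(net.concept("D11").label)                        # Rheumatoid Arthritis
print(rn.has_path("D0", "S2", "S3", "D11"))            # True
```

After two expansion steps the disease-side relatedness set holds eight
diseases, but the interesting set `F(2)` keeps only the four reachable
*exclusively* through symptom-mediated paths — including Rheumatoid
Arthritis via the chain Lupus → Painful Swollen Joint → Joint Swelling →
Rheumatoid Arthritis.

The same machinery is available from the shell:

```bash
morm simulate --kind fig3 --seed 1 --out net.json
morm expand --bmkn net.json --anchor D0 --steps 2 --out rn.json
morm prune  --bmkn net.json --anchor D0 --mask "has_symptom:0:0:0,symptom_of:0:0:0" --out sweep.tsv
```

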