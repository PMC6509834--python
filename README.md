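# leukotype

Genus-differentia knowledge bases of immunophenotype-defined cell classes,
with a bespoke sound-and-complete reasoner, deterministic OWL export, and
classification of patient marker data.

The package ships a built-in knowledge base encoding the EGIL
immunophenotypic classification of acute leukemias (B-lineage ALL stages
B-I–B-IV, T-lineage ALL stages T-I–T-IV with TCR subgroups, and the AML
lineages). Each class is defined by a named parent (genus) plus a
conjunction of disjunctive marker clauses (differentia), e.g.
`CD19+ and/or CD79a+ and/or CD22+` for B-lineage ALL. The reasoner decides
entailment and satisfiability over a four-valued marker lattice
(absent / present / high / low, with high and low entailing present),
re-derives the class hierarchy from the axioms, and sorts patient samples
into matching classes under open- or closed-world policies.

## Command-line interface

```sh
# validate the built-in EGIL knowledge base (exit 1 on error findings)
leukotype validate

# export the KB to OWL functional syntax and print class/axiom statistics
leukotype build --out egil.ofn

# classify a patient CSV (columns: sample_id,marker,location,status
# or percent_positive; percent values are thresholded at 20%, inclusive)
leukotype classify samples.csv --policy open --out report.csv

# generate seeded synthetic samples for a class
leukotype simulate --class T-III --n 5 --seed 7 --out sim.csv
```

`classify` reports, per sample, the *definite* classes (every defining
clause witnessed by a measured status), the *compatible* classes (not
contradicted), and the most specific definite classes. Under
`--policy closed`, unmeasured markers count as absent when falsifying a
clause; satisfying a clause always requires a measured value. The optional
`--precedence` flag resolves ties along the declared maturation-stage
chains (latest stage wins).

## Knowledge-base format

A KB is one YAML document: a marker dictionary (labels, synonyms) plus an
ordered list of class records (`id`, `label`, `genus`, `defining`,
`clauses`, optional `typical_profile` and `lineage_text`). Each clause is a
list of `[marker, location, status]` triples read as a disjunction; the
clause list is a conjunction. The shipped file
`src/leukotype/data/egil_table1.yaml` documents the schema in its header
and is the source of `builtin_egil_kb()`. Cytoplasmic high/low literals are
rejected: the relation vocabulary (has_plasma_membrane_part,
lacks_plasma_membrane_part, has_high/low_plasma_membrane_amount,
has_cytoplasm_part, lacks_cytoplasm_part, lacks_part) has no relation for
them.

## OWL export

`leukotype build` (or `leukotype.owlio.export_ontology`) writes OWL
functional-style syntax with deterministic IRI minting, so identical KBs
export byte-identically. Defining classes become equivalence axioms
`Class ≡ Genus ⊓ (clause …)` where a multi-literal clause renders as
`ObjectUnionOf` of existential restrictions; negative literals use the
"lacks" relations rather than complements, keeping the export EL-friendly.
`load_ontology_stats` counts named classes (split native vs imported by IRI
prefix) in functional-syntax or RDF/XML files; import closures are never
resolved over the network.

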