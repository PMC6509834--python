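import random

import pytest

from oracles import oracle_entails, oracle_is_satisfiable, oracle_transitive_reduction

from conftest import random_phenotype

from leukotype.kb import loads_kb
from leukotype.model import (
    ExpressionStatus,
    Location,
    MarkerLiteral,
    Phenotype,
    UnknownClassError,
    make_phenotype,
)
from leukotype.pipeline import PatientSample
from leukotype.reasoner import (
    MarkerWorld,
    UniverseMismatchError,
    classify_hierarchy,
    classify_instance,
    entails,
    is_satisfiable,
    literal_implies,
    satisfies,
    subsumes,
)


def lit(kb, name, location, status):
    return MarkerLiteral(
        kb.resolve_marker(name), Location(location), ExpressionStatus(status)
    )


class TestLiteralImplies:
    def test_high_implies_present(self, kb):
        assert literal_implies(
            lit(kb, "CD10", "surface", "high"), lit(kb, "CD10", "surface", "present")
        )

    def test_locations_are_distinct(self, kb):
        assert not literal_implies(
            lit(kb, "CD3", "surface", "present"), lit(kb, "CD3", "cytoplasmic", "present")
        )

    def test_absent_does_not_imply_present(self, kb):
        assert not literal_implies(
            lit(kb, "CD19", "surface", "absent"), lit(kb, "CD19", "surface", "present")
        )

    def test_reflexive(self, kb):
        a = lit(kb, "CD19", "surface", "low")
        assert literal_implies(a, a)


class TestSatisfies:
    def test_high_satisfies_present_clause(self, kb):
        phenotype = kb.classes["B-ALL"].differentia
        world = MarkerWorld.of(
            {
                ("CD19", "surface"): "high",
                ("CD79a", "surface"): "absent",
                ("CD22", "surface"): "absent",
            }
        )
        assert satisfies(world, phenotype)

    def test_trivial_phenotype_always_satisfied(self):
        assert satisfies(MarkerWorld.of({}), Phenotype.trivial())

    def test_absent_falsifies_positive_unit_clause(self, kb):
        phenotype = make_phenotype([[("CD10", "surface", "present")]], kb)
        assert not satisfies(MarkerWorld.of({("CD10", "surface"): "absent"}), phenotype)

    def test_universe_mismatch(self, kb):
        phenotype = make_phenotype([[("CD10", "surface", "present")]], kb)
        with pytest.raises(UniverseMismatchError):
            satisfies(MarkerWorld.of({}), phenotype)


class TestEntailsAndSatisfiable:
    def test_unit_entails_disjunction(self, kb):
        p = make_phenotype([[("CD19", "surface", "present")]], kb)
        q = kb.classes["B-ALL"].differentia
        assert entails(p, q)
        assert not entails(q, p)

    def test_trivial_cases(self, kb):
        trivial = Phenotype.trivial()
        cd10 = make_phenotype([[("CD10", "surface", "present")]], kb)
        assert entails(trivial, trivial)
        assert entails(cd10, trivial)
        assert not entails(trivial, cd10)

    def test_direct_contradiction_unsatisfiable(self, kb):
        p = make_phenotype(
            [[("CD19", "surface", "present")], [("CD19", "surface", "absent")]], kb
        )
        assert not is_satisfiable(p)
        # an unsatisfiable phenotype entails anything
        assert entails(p, make_phenotype([[("GPA", "surface", "present")]], kb))

    def test_aml_m0_expansion_satisfiable(self, kb):
        assert is_satisfiable(kb.expand("AML-M0"))

    def test_unit_propagation_prunes_disjuncts(self, kb):
        p = make_phenotype(
            [
                [("CD19", "surface", "present"), ("CD22", "surface", "present")],
                [("CD19", "surface", "absent")],
            ],
            kb,
        )
        q = make_phenotype([[("CD22", "surface", "present")]], kb)
        assert entails(p, q)

    def test_resolution_style_entailment(self, kb):
        # requires reasoning beyond clause subsumption + unit propagation
        p = make_phenotype(
            [
                [("CD19", "surface", "present"), ("CD22", "surface", "present")],
                [("CD19", "surface", "absent"), ("CD22", "surface", "present")],
            ],
            kb,
        )
        q = make_phenotype([[("CD22", "surface", "present")]], kb)
        assert entails(p, q) == oracle_entails(p, q) == True  # noqa: E712

    def test_high_low_split_entails_present(self, kb):
        p = make_phenotype(
            [[("CD10", "surface", "high"), ("CD10", "surface", "low")]], kb
        )
        q = make_phenotype([[("CD10", "surface", "present")]], kb)
        assert entails(p, q)
        assert not entails(q, p)

    def test_tautological_clause_entailed_by_anything(self, kb):
        q = make_phenotype(
            [[("CD10", "surface", "present"), ("CD10", "surface", "absent"),
              ("CD10", "surface", "high"), ("CD10", "surface", "low")]],
            kb,
        )
        assert entails(Phenotype.trivial(), q)

    def test_agreement_with_oracle_on_random_pairs(self):
        rng = random.Random(20240901)
        for _ in range(150):
            p = random_phenotype(rng)
            q = random_phenotype(rng)
            assert entails(p, q) == oracle_entails(p, q)
            assert is_satisfiable(p) == oracle_is_satisfiable(p)

    def test_monotonicity_in_premises(self):
        rng = random.Random(7)
        for _ in range(80):
            p = random_phenotype(rng)
            q = random_phenotype(rng)
            extra = random_phenotype(rng, max_clauses=1)
            if entails(p, q):
                assert entails(p.conjoin(extra), q)


class TestSubsumes:
    def test_genus_chain_subsumption(self, kb):
        assert subsumes("B-ALL", "B-II", kb)
        assert subsumes("ALL", "B-II", kb)

    def test_siblings_incomparable(self, kb):
        # frozen from the brute-force oracle: CD10+ and cyIg mu+ are independent
        assert oracle_entails(kb.expand("B-II"), kb.expand("B-III")) is False
        assert oracle_entails(kb.expand("B-III"), kb.expand("B-II")) is False
        assert not subsumes("B-II", "B-III", kb)
        assert not subsumes("B-III", "B-II", kb)

    def test_reflexive(self, kb):
        for cid in ("B-II", "AML-mega", "abnormal-cell"):
            assert subsumes(cid, cid, kb)

    def test_transitive_on_satisfiable_classes(self, kb):
        defining = kb.defining_ids()
        holds = {
            (a, b): subsumes(a, b, kb) for a in defining for b in defining
        }
        for (a, b), ab in holds.items():
            for c in defining:
                if ab and holds[(b, c)]:
                    assert holds[(a, c)], (a, b, c)

    def test_unknown_class(self, kb):
        with pytest.raises(UnknownClassError):
            subsumes("B-II", "nope", kb)


MINI_KB_HEADER = """\
name: rand
version: "1"
roots: [root]
markers:
  - {id: A, label: A}
  - {id: B, label: B}
  - {id: C, label: C}
classes:
  - {id: root, label: root, genus: null, defining: false}
"""


def mini_kb_doc(class_lines):
    return MINI_KB_HEADER + class_lines


class TestClassifyHierarchy:
    def test_builtin_layout(self, kb):
        result = classify_hierarchy(kb)
        edges = set(result.direct_edges)
        for child in ("B-I", "B-II", "B-III", "B-IV"):
            assert (child, "B-ALL") in edges
        for child in ("T-I", "T-II", "T-III", "T-IV"):
            assert (child, "T-ALL") in edges
        assert ("T-IVa", "T-IV") in edges and ("T-IVb", "T-IV") in edges
        assert result.equivalence_groups == ()
        assert result.asserted_only == ()

    def test_every_class_reachable_from_root(self, kb):
        result = classify_hierarchy(kb)
        children = {}
        for child, parent in result.direct_edges:
            children.setdefault(parent, []).append(child)
        seen = set()
        stack = list(kb.roots)
        while stack:
            node = stack.pop()
            seen.add(node)
            stack.extend(children.get(node, []))
        grouped = {cid for group in result.equivalence_groups for cid in group}
        assert seen | grouped >= set(kb.classes)

    def test_duplicate_definition_forms_equivalence_group(self):
        doc = mini_kb_doc(
            "  - {id: x, label: x, genus: root, defining: true,\n"
            "     clauses: [[[A, surface, present]]]}\n"
            "  - {id: y, label: y, genus: root, defining: true,\n"
            "     clauses: [[[A, surface, present]]]}\n"
        )
        kb = loads_kb(doc, strict=False)
        result = classify_hierarchy(kb)
        assert result.equivalence_groups == (frozenset({"x", "y"}),)

    def test_random_kbs_match_oracle_reduction(self):
        rng = random.Random(99)
        statuses = ["present", "absent", "high", "low"]
        for _ in range(25):
            lines = []
            n = rng.randint(2, 5)
            for i in range(n):
                clauses = []
                for _ in range(rng.randint(1, 2)):
                    size = rng.randint(1, 2)
                    literals = ", ".join(
                        f"[{m}, surface, {rng.choice(statuses)}]"
                        for m in rng.sample(["A", "B", "C"], size)
                    )
                    clauses.append(f"[{literals}]")
                lines.append(
                    f"  - {{id: c{i}, label: c{i}, genus: root, defining: true,\n"
                    f"     clauses: [{', '.join(clauses)}]}}"
                )
            kb = loads_kb(mini_kb_doc("\n".join(lines) + "\n"), strict=False)
            ids = [f"c{i}" for i in range(n)]
            sat = {cid for cid in ids if oracle_is_satisfiable(kb.expand(cid))}
            relation = {
                (c, p)
                for c in sat
                for p in sat
                if c != p and oracle_entails(kb.expand(c), kb.expand(p))
            }

            def rep(cid):
                return min(
                    [cid]
                    + [d for d in sat if (cid, d) in relation and (d, cid) in relation]
                )

            rep_relation = {
                (rep(c), rep(p)) for c, p in relation if rep(c) != rep(p)
            }
            expected = oracle_transitive_reduction(sorted({rep(c) for c in sat}), rep_relation)
            got = {
                (c, p)
                for c, p in classify_hierarchy(kb).direct_edges
                if c in sat and p in sat
            }
            assert expected == got


def sample_of(mapping):
    measurements = {}
    for token, status in mapping.items():
        if token.startswith("cy"):
            key = (token[2:], Location.CYTOPLASMIC)
        else:
            key = (token, Location.SURFACE)
        measurements[key] = ExpressionStatus(status)
    return PatientSample(sample_id="S", measurements=measurements)


class TestClassifyInstance:
    def test_b2_worked_example(self, kb):
        result = classify_instance(
            sample_of({"CD19": "present", "CD10": "present"}), kb, policy="open"
        )
        assert result.most_specific_definite == ("B-II",)
        assert "B-ALL" in result.definite and "ALL" in result.definite

    def test_t3_worked_example(self, kb):
        result = classify_instance(
            sample_of({"CD3": "present", "CD1a": "present"}), kb, policy="open"
        )
        assert result.most_specific_definite == ("T-III",)

    def test_empty_sample_open_world(self, kb):
        result = classify_instance(PatientSample("E", {}), kb, policy="open")
        assert result.definite == frozenset()
        assert set(kb.defining_ids()) <= result.compatible

    def test_falsified_classes_not_compatible(self, kb):
        result = classify_instance(
            sample_of({"CD3": "present", "CD1a": "present"}), kb, policy="open"
        )
        assert "T-IV" not in result.compatible  # requires CD1a-

    def test_invariants(self, kb):
        result = classify_instance(
            sample_of({"CD19": "present", "CD10": "present", "GPA": "absent"}), kb
        )
        assert result.definite <= result.compatible
        assert set(result.most_specific_definite) <= result.definite
        for cid in result.definite:  # upward closure
            for other in kb.asserted_ancestors(cid):
                assert other in result.definite

    def test_closed_world_uses_absence(self, kb):
        # B-I needs measured negatives; closed world falsifies CD10+ siblings
        result = classify_instance(
            sample_of({"CD19": "present", "CD10": "absent",
                       "cyIgM": "absent", "sIg": "absent"}),
            kb,
            policy="closed",
        )
        assert result.most_specific_definite == ("B-I",)

    def test_measured_plain_present_does_not_witness_high(self, kb):
        doc = mini_kb_doc(
            "  - {id: hi, label: hi, genus: root, defining: true,\n"
            "     clauses: [[[A, surface, high]]]}\n"
        )
        mini = loads_kb(doc, strict=False)
        result = classify_instance(sample_of({"A": "present"}), mini, policy="open")
        assert "hi" not in result.definite
        assert "hi" in result.compatible
        high = classify_instance(sample_of({"A": "high"}), mini, policy="open")
        assert "hi" in high.definite

    def test_unknown_marker_policies(self, kb):
        sample = sample_of({"CD19": "present", "CD99x": "present"})
        with pytest.warns(UserWarning):
            result = classify_instance(sample, kb, on_unknown_marker="skip")
        assert "B-ALL" in result.definite
        from leukotype.model import UnknownMarkerError

        with pytest.raises(UnknownMarkerError):
            classify_instance(sample, kb, on_unknown_marker="error")

    def test_stage_precedence_policy(self, kb):
        # CD10+ and cyIg mu+ satisfy both B-II and B-III; precedence keeps B-III
        sample = sample_of({"CD19": "present", "CD10": "present", "cyIgM": "present"})
        plain = classify_instance(sample, kb, policy="open")
        assert plain.most_specific_definite == ("B-II", "B-III")
        ranked = classify_instance(sample, kb, policy="open", stage_precedence=True)
        assert ranked.most_specific_definite == ("B-III",)

    def test_bad_policy(self, kb):
        with pytest.raises(ValueError):
            classify_instance(PatientSample("S", {}), kb, policy="magic")
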