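"""Variant notation, reference edits, haplotree and haplogroup calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harimau import ValidationError
from harimau.mito import (Haplotree, HaplotreeNode, VariantToken, aplp_call,
                          apply_variants, assign_haplogroup, demo_reference,
                          diff_to_reference, format_variant_token,
                          parse_variant_token)


class TestVariantTokens:
    @pytest.mark.parametrize("text,kind,pos", [
        ("C10132T", "SNP", 10132),
        ("GCA513G", "deletion", 513),
        ("T310TC", "insertion", 310),
        ("A302ACC", "insertion", 302),
        ("CAA16179C", "deletion", 16179),
    ])
    def test_parse_classifies_and_roundtrips(self, text, kind, pos):
        tok = parse_variant_token(text)
        assert tok.kind == kind
        assert tok.pos == pos
        assert format_variant_token(tok) == text

    @pytest.mark.parametrize("bad", ["", "123", "C-5T", "X100Y", "C10132"])
    def test_malformed_tokens_rejected(self, bad):
        with pytest.raises(ValidationError):
            parse_variant_token(bad)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.sampled_from("ACGT"), st.integers(1, 16569), st.sampled_from("ACGT"))
    def test_parse_format_roundtrip_property(self, ref_allele, pos, alt):
        text = f"{ref_allele}{pos}{alt}"
        assert format_variant_token(parse_variant_token(text)) == text


class TestApplyDiff:
    def test_empty_variant_list_is_identity(self, ref):
        assert apply_variants(ref, []) == ref.sequence
        assert diff_to_reference(ref.sequence, ref) == []

    def test_single_snp_changes_one_position(self, ref):
        pos = 150
        alt = "T" if ref.base(pos) != "T" else "A"
        tok = VariantToken(ref=ref.base(pos), pos=pos, alt=alt)
        genome = apply_variants(ref, [tok])
        diffs = [i for i, (a, b) in enumerate(zip(genome, ref.sequence)) if a != b]
        assert diffs == [pos - 1]

    def test_reference_allele_mismatch_names_position(self, ref):
        wrong = "A" if ref.base(99) != "A" else "C"
        with pytest.raises(ValidationError, match="99"):
            apply_variants(ref, [VariantToken(ref=wrong, pos=99, alt="T")])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_apply_then_diff_recovers_tokens(self, seed):
        ref = demo_reference()
        rng = np.random.default_rng(seed)
        toks = []
        used = set()
        for _ in range(rng.integers(1, 8)):
            pos = int(rng.integers(10, len(ref) - 10))
            if any(abs(pos - p) < 8 for p in used):
                continue
            used.add(pos)
            r = ref.base(pos)
            kind = rng.integers(0, 3)
            if kind == 0:  # SNP
                alt = "ACGT"[(("ACGT".index(r)) + int(rng.integers(1, 4))) % 4]
                toks.append(VariantToken(ref=r, pos=pos, alt=alt))
            elif kind == 1:  # insertion
                ins = "".join(rng.choice(list("ACGT"), rng.integers(1, 3)))
                toks.append(VariantToken(ref=r, pos=pos, alt=r + ins))
            else:  # deletion
                seg = ref.sequence[pos - 1:pos + int(rng.integers(1, 3))]
                toks.append(VariantToken(ref=seg, pos=pos, alt=seg[0]))
        genome = apply_variants(ref, toks)
        back = diff_to_reference(genome, ref)
        # compare by the genomes they produce (tokens may normalize to
        # different-but-equivalent left-aligned forms)
        assert apply_variants(ref, back) == genome

    def test_printed_deletion_roundtrips(self, ref):
        seg = ref.sequence[512:515]
        tok = VariantToken(ref=seg, pos=513, alt=seg[0])
        genome = apply_variants(ref, [tok])
        back = diff_to_reference(genome, ref)
        assert apply_variants(ref, back) == genome
        assert sum(len(t.ref) - len(t.alt) for t in back) == 2


def toy_tree():
    t = lambda s: parse_variant_token(s)
    nodes = {
        "root": HaplotreeNode("root", None),
        "X": HaplotreeNode("X", "root", [t("A100G"), t("C200T")]),
        "X1": HaplotreeNode("X1", "X", [t("G300A")]),
        "X1a": HaplotreeNode("X1a", "X1", [t("T400C")]),
        "Y": HaplotreeNode("Y", "root", [t("C500T"), t("A600G")]),
    }
    return Haplotree(nodes=nodes)


class TestHaplotree:
    def test_demo_tree_structure(self, tree):
        assert tree.root == "MT"
        assert [n.name for n in tree.path("B4a1a")] == \
            ["MT", "N", "R", "B4", "B4a", "B4a1", "B4a1a"]
        n_diag = {v.pos for v in tree.nodes["N"].variants}
        assert n_diag == {8701, 9540, 10398, 10873, 15301}
        assert {v.pos for v in tree.nodes["R"].variants} == {12705, 16223}
        assert {v.pos for v in tree.nodes["M"].variants} == {489, 10400, 14783, 15043}

    def test_tree_tsv_roundtrip(self, tree, tmp_path):
        p = tmp_path / "tree.tsv"
        tree.to_tsv(p)
        back = Haplotree.from_tsv(p)
        assert set(back.nodes) == set(tree.nodes)
        for name in tree.nodes:
            assert [str(v) for v in back.nodes[name].variants] == \
                [str(v) for v in tree.nodes[name].variants]

    def test_cycle_and_multiroot_rejected(self):
        t = lambda s: parse_variant_token(s)
        with pytest.raises(ValidationError):
            Haplotree(nodes={"a": HaplotreeNode("a", "b", [t("A1G")]),
                             "b": HaplotreeNode("b", "a", [t("C2T")])})


class TestAssignHaplogroup:
    def test_exact_path_gives_node_with_no_extras(self, tree):
        call = assign_haplogroup(tree.path_variants("B4a1a"), tree)
        assert call.node == "B4a1a"
        assert call.extras == [] and call.missing == 0

    def test_macro_R_with_private_substitutions(self, tree):
        extras = [parse_variant_token(t) for t in
                  "C150T A189G T310TC T450C A3397G G3483A C3600A A5484G "
                  "C6164T A7271G T9833C G9966A C10777T G11150A T14178C "
                  "T14311C A15766G T16304C".split()]
        call = assign_haplogroup(tree.path_variants("R") + extras, tree)
        assert call.node == "R"
        assert len(call.extras) == 18

    def test_macro_M_with_private_substitutions(self, tree):
        extras = [parse_variant_token(t) for t in
                  "C151T T152C T310TC GCA513G C3817T T4336C T4823C G8592A "
                  "A9285G G11176A C12378T G15172A T16229C C16294T T16311C".split()]
        call = assign_haplogroup(tree.path_variants("M") + extras, tree)
        assert call.node == "M"
        assert len(call.extras) == 15

    def test_empty_tree_rejected(self):
        with pytest.raises(ValidationError):
            assign_haplogroup([], _empty_tree())

    def test_simulated_node_recovery_over_whole_tree(self, tree):
        for node in tree.nodes:
            if node == tree.root:
                continue
            call = assign_haplogroup(tree.path_variants(node), tree)
            assert call.node == node
            assert call.extras == []

    def test_child_diagnostic_descends_not_jumps(self):
        tree = toy_tree()
        base = tree.path_variants("X")
        call = assign_haplogroup(base + [parse_variant_token("G300A")], tree)
        assert call.node == "X1"
        # adding a child diagnostic never moves the call to an unrelated clade
        assert call.node not in ("Y",)

    def test_missing_diagnostic_counts_against_depth(self):
        tree = toy_tree()
        # only one of X's two diagnostics: X scores 1-1=0, root scores 0: tie
        call = assign_haplogroup([parse_variant_token("A100G")], tree)
        assert call.node == "root"
        assert call.ambiguous


def _empty_tree():
    class Dummy:
        nodes = {}
    return Dummy()


class TestAPLP:
    def _geno(self, tree, panel, label, fail=()):
        by_node = {}
        for s in panel.sites:
            by_node.setdefault(s.haplogroup, []).append(s)
        geno = {}
        for node in (n.name for n in tree.path(label)[1:]):
            s = by_node[node][0]
            if s.position not in fail:
                geno[s.position] = s.alt
        return geno

    @pytest.mark.parametrize("label", ["R", "M", "B4a", "E", "N9a", "Y2", "B4c", "M7", "N"])
    def test_published_screen_outcomes(self, tree, panel, label):
        assert aplp_call(self._geno(tree, panel, label), panel, tree) == label

    def test_all_sites_failed_gives_nd(self, tree, panel):
        assert aplp_call({}, panel, tree) == "N.D."

    def test_derived_N_and_R_sites_give_R(self, tree, panel):
        by_pos = panel.by_position()
        geno = {p: by_pos[p].alt for p in (8701, 9540, 10398, 10873, 15301,
                                           12705, 16223) if p in by_pos}
        # panel carries one site per node; coverage of the N and R sites
        geno = {p: a for p, a in geno.items()}
        assert aplp_call(geno, panel, tree) == "R"

    def test_contradicted_site_blocks_descent(self, tree, panel):
        geno = self._geno(tree, panel, "B4a")
        by_node = {s.haplogroup: s for s in panel.sites}
        s = by_node["B4a"]
        geno[s.position] = s.ref  # ancestral allele observed
        assert aplp_call(geno, panel, tree) == "B4"

    def test_unknown_site_rejected(self, tree, panel):
        with pytest.raises(ValidationError):
            aplp_call({1: "A"}, panel, tree)
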