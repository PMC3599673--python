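import random

import pytest

from condl.corpus import Sentence
from condl.deppath import (
    DegeneratePairError,
    DepParse,
    Token,
    default_keywords,
    find_candidates,
    load_keywords,
    read_conllu,
    shortest_dep_path,
    write_conllu,
)
from condl.ner import Mention


def _sent(text: str) -> Sentence:
    return Sentence("d", 0, text, 0, len(text))


def _mention(text: str, surface: str, etype: str = "gene", norm: str | None = None) -> Mention:
    start = text.index(surface)
    return Mention("d", 0, start, start + len(surface), surface, etype, norm or surface)


def _parse(rows) -> DepParse:
    return DepParse("d", 0, tuple(Token(i + 1, *r) for i, r in enumerate(rows)))


ACTIVE = _parse(
    [
        ("IL6", "_", 2, "nsubj"),
        ("activates", "activate", 0, "root"),
        ("STAT3", "_", 2, "dobj"),
        (".", ".", 2, "punct"),
    ]
)


class TestFindCandidates:
    KW = {"activate", "bind"}

    def test_keyword_plus_two_genes(self):
        text = "IL6 activates STAT3."
        ms = [_mention(text, "IL6"), _mention(text, "STAT3")]
        pairs = find_candidates(_sent(text), ms, self.KW)
        assert len(pairs) == 1
        assert pairs[0].pair_kind == "gene_gene"
        assert pairs[0].keyword == "activates"

    def test_no_keyword_no_candidates(self):
        text = "IL6 and STAT3 were measured."
        ms = [_mention(text, "IL6"), _mention(text, "STAT3")]
        assert find_candidates(_sent(text), ms, self.KW) == []

    def test_same_norm_id_is_not_a_pair(self):
        text = "IL6 activates IL6."
        ms = [
            Mention("d", 0, 0, 3, "IL6", "gene", "IL6"),
            Mention("d", 0, 14, 17, "IL6", "gene", "IL6"),
        ]
        assert find_candidates(_sent(text), ms, self.KW) == []

    def test_gene_vaccine_pair(self):
        text = "RB51 activates IL6."
        ms = [
            _mention(text, "RB51", "vaccine_specific", "VO:1"),
            _mention(text, "IL6"),
        ]
        pairs = find_candidates(_sent(text), ms, self.KW)
        assert [p.pair_kind for p in pairs] == ["gene_vaccine"]

    def test_vaccine_vaccine_not_paired(self):
        text = "RB51 binds SC602."
        ms = [
            _mention(text, "RB51", "vaccine_specific", "VO:1"),
            _mention(text, "SC602", "vaccine_specific", "VO:2"),
        ]
        assert find_candidates(_sent(text), ms, self.KW) == []

    @pytest.mark.parametrize(
        "token", ["binds", "binding", "activated", "induces", "suppresses"]
    )
    def test_light_stemming_matches_inflections(self, token):
        text = f"IL6 {token} STAT3."
        ms = [_mention(text, "IL6"), _mention(text, "STAT3")]
        assert len(find_candidates(_sent(text), ms, default_keywords())) == 1

    def test_empty_keywords_rejected(self):
        with pytest.raises(ValueError):
            find_candidates(_sent("x"), [], set())


class TestReadConllu:
    def test_blocks_and_tokens(self, tmp_path):
        p = tmp_path / "p.conllu"
        write_conllu([ACTIVE, _parse([("Hi", "hi", 0, "root")])], p)
        parses = read_conllu(p)
        assert len(parses) == 2
        assert parses[0].tokens[1].lemma == "activate"
        assert sum(t.head == 0 for t in parses[0].tokens) == 1

    def test_dangling_head_rejected(self, tmp_path):
        p = tmp_path / "p.conllu"
        p.write_text(
            "# doc_id = d\n# sent_index = 0\n"
            "1\tA\t_\t_\t_\t_\t9\tnsubj\t_\t_\n"
            "2\tB\t_\t_\t_\t_\t0\troot\t_\t_\n\n"
        )
        with pytest.raises(ValueError, match="head"):
            read_conllu(p)

    def test_missing_root_rejected(self, tmp_path):
        p = tmp_path / "p.conllu"
        p.write_text(
            "# doc_id = d\n# sent_index = 0\n1\tA\t_\t_\t_\t_\t1\tdep\t_\t_\n\n"
        )
        with pytest.raises(ValueError, match="root"):
            read_conllu(p)

    def test_multiword_lines_skipped(self, tmp_path):
        p = tmp_path / "p.conllu"
        p.write_text(
            "# doc_id = d\n# sent_index = 0\n"
            "1-2\tdont\t_\t_\t_\t_\t_\t_\t_\t_\n"
            "1\tdo\tdo\t_\t_\t_\t0\troot\t_\t_\n"
            "2\tnot\tnot\t_\t_\t_\t1\tadvmod\t_\t_\n\n"
        )
        assert len(read_conllu(p)[0].tokens) == 2

    def test_keyword_file_loading(self, tmp_path):
        p = tmp_path / "kw.txt"
        p.write_text("bind\n# a comment\nactivate  # trailing\n\n")
        kw = load_keywords(p)
        assert "bind" in kw and "activate" in kw


class TestShortestDepPath:
    text = "IL6 activates STAT3."
    a = _mention(text, "IL6")
    b = _mention(text, "STAT3")

    def test_subject_verb_object_path(self):
        dep = shortest_dep_path(ACTIVE, self.a, self.b, self.text)
        assert dep.sequence == ("ENTITYA", "nsubj<", "activate", "dobj>", "ENTITYB")

    def test_reverse_flips_direction_markers(self):
        fwd = shortest_dep_path(ACTIVE, self.a, self.b, self.text)
        rev = shortest_dep_path(ACTIVE, self.b, self.a, self.text)
        flip = {"<": ">", ">": "<"}
        flipped = tuple(e[:-1] + flip[e[-1]] for e in reversed(rev.edge_tokens))
        assert fwd.edge_tokens == flipped
        assert rev.node_tokens[1:-1] == fwd.node_tokens[1:-1][::-1]

    def test_degenerate_pair_rejected(self):
        text = "IL6R binds X."
        a = Mention("d", 0, 0, 4, "IL6R", "gene", "IL6R")
        b = Mention("d", 0, 0, 3, "IL6", "gene", "IL6")
        parse = _parse(
            [("IL6R", "_", 2, "nsubj"), ("binds", "bind", 0, "root"), ("X", "_", 2, "dobj")]
        )
        with pytest.raises(DegeneratePairError):
            shortest_dep_path(parse, a, b, text)

    def test_other_entities_become_entityx(self):
        text = "IL6 binds TNF via STAT3."
        parse = _parse(
            [
                ("IL6", "_", 2, "nsubj"),
                ("binds", "bind", 0, "root"),
                ("TNF", "_", 2, "dobj"),
                ("via", "via", 5, "case"),
                ("STAT3", "_", 2, "obl"),
                (".", ".", 2, "punct"),
            ]
        )
        a, b = _mention(text, "IL6"), _mention(text, "STAT3")
        other = [_mention(text, "TNF")]
        dep = shortest_dep_path(parse, a, b, text, other)
        assert "tnf" not in dep.node_tokens
        assert dep.sequence == ("ENTITYA", "nsubj<", "bind", "obl>", "ENTITYB")

    def test_chain_length_matches_bfs_oracle(self):
        # 4-token chain: each token heads the previous
        text = "a b c d"
        parse = _parse(
            [("a", "a", 2, "dep"), ("b", "b", 3, "dep"), ("c", "c", 4, "dep"), ("d", "d", 0, "root")]
        )
        a = Mention("d", 0, 0, 1, "a", "gene", "A")
        b = Mention("d", 0, 6, 7, "d", "gene", "D")
        dep = shortest_dep_path(parse, a, b, text)
        assert len(dep.edge_tokens) == 3

    def test_random_trees_match_bfs_distance_oracle(self):
        """Path length equals tree distance from an independent BFS on 200
        random trees of up to 10 nodes."""
        rng = random.Random(1)
        for _ in range(200):
            n = rng.randint(2, 10)
            # random tree: token i+1 attaches to a random earlier token
            heads = [0] + [rng.randint(1, i) for i in range(1, n)]
            forms = [f"w{i}" for i in range(n)]
            parse = _parse(
                [(forms[i], forms[i], heads[i], "dep") for i in range(n)]
            )
            text = " ".join(forms)
            i, j = rng.sample(range(n), 2)

            def pos(k):
                start = sum(len(forms[t]) + 1 for t in range(k))
                return start, start + len(forms[k])

            a = Mention("d", 0, *pos(i), forms[i], "gene", "A")
            b = Mention("d", 0, *pos(j), forms[j], "gene", "B")
            dep = shortest_dep_path(parse, a, b, text)

            # independent BFS oracle over the undirected tree
            adj = {k: set() for k in range(n)}
            for k, h in enumerate(heads):
                if h:
                    adj[k].add(h - 1)
                    adj[h - 1].add(k)
            dist = {i: 0}
            frontier = [i]
            while frontier:
                nxt = []
                for u in frontier:
                    for v in adj[u]:
                        if v not in dist:
                            dist[v] = dist[u] + 1
                            nxt.append(v)
                frontier = nxt
            assert len(dep.edge_tokens) == dist[j]
            assert dep.sequence[0] == "ENTITYA" and dep.sequence[-1] == "ENTITYB"
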