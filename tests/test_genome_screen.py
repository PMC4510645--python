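"""Gene tables, Nan cluster detection, pathway calls and screen summary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sialoscreen.genome_screen import (
    CANONICAL_ROLES,
    ClusterError,
    GeneTableError,
    StrainScreenResult,
    classify_pathway,
    detect_gene_cluster,
    load_gene_table,
    summarize_genome_screen,
)
from sialoscreen import synthetic_data as synth

from conftest import exhaustive_cluster_oracle


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

class TestLoadGeneTable:
    def _write_tsv(self, tmp_path, rows):
        df = pd.DataFrame(rows, columns=["strain", "replicon", "locus_index",
                                         "protein_id", "strand"])
        p = tmp_path / "genes.tsv"
        df.to_csv(p, sep="\t", index=False)
        return p

    def test_simple_tsv(self, tmp_path):
        rows = [("s1", "r1", i, f"p{i}", "+") for i in range(1, 6)]
        loci = load_gene_table(self._write_tsv(tmp_path, rows))
        assert len(loci) == 5
        assert [l.locus_index for l in loci] == [1, 2, 3, 4, 5]

    def test_gff3_rank_rule(self, tmp_path):
        gff = "\n".join([
            "##gff-version 3",
            "ctg1\t.\tCDS\t900\t1100\t.\t+\t0\tID=gA",
            "ctg1\t.\tCDS\t100\t300\t.\t-\t0\tID=gB",
            "ctg1\t.\tCDS\t500\t700\t.\t+\t0\tID=gC",
        ])
        p = tmp_path / "g.gff3"
        p.write_text(gff)
        loci = load_gene_table(p, strain_id="s1")
        order = {l.protein_id: l.locus_index for l in loci}
        assert order == {"gB": 1, "gC": 2, "gA": 3}

    def test_two_replicons_indexed_independently(self, tmp_path):
        rows = [("s1", "r1", i, f"a{i}", "+") for i in (1, 2, 3)]
        rows += [("s1", "r2", i, f"b{i}", "+") for i in (1, 2, 3)]
        loci = load_gene_table(self._write_tsv(tmp_path, rows))
        assert len(loci) == 6
        by_rep = {}
        for l in loci:
            by_rep.setdefault(l.replicon_id, []).append(l.locus_index)
        assert by_rep == {"r1": [1, 2, 3], "r2": [1, 2, 3]}

    def test_sparse_indices_renormalised(self, tmp_path):
        rows = [("s1", "r1", i, f"p{i}", "+") for i in (10, 20, 35)]
        loci = load_gene_table(self._write_tsv(tmp_path, rows))
        assert [l.locus_index for l in loci] == [1, 2, 3]

    def test_duplicate_index_rejected(self, tmp_path):
        rows = [("s1", "r1", 1, "p1", "+"), ("s1", "r1", 1, "p2", "+")]
        with pytest.raises(GeneTableError):
            load_gene_table(self._write_tsv(tmp_path, rows))

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        pd.DataFrame({"strain": ["s"], "replicon": ["r"]}).to_csv(p, sep="\t", index=False)
        with pytest.raises(GeneTableError):
            load_gene_table(p)


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------

def mk(rep_idx_roles):
    return [(rep, idx, frozenset(roles)) for rep, idx, roles in rep_idx_roles]


class TestDetectCluster:
    def test_span_exactly_window(self):
        loci = mk([("r1", 10, {"NanA"}), ("r1", 12, {"NanK"}), ("r1", 24, {"NanE1"})])
        assert detect_gene_cluster(loci, window=15) == [("r1", 10, 24)]

    def test_span_one_over_window(self):
        loci = mk([("r1", 10, {"NanA"}), ("r1", 12, {"NanK"}), ("r1", 25, {"NanE1"})])
        assert detect_gene_cluster(loci, window=15) == []

    def test_roles_across_replicons_never_cluster(self):
        loci = mk([("r1", 1, {"NanA"}), ("r1", 2, {"NanK"}), ("r2", 3, {"NanE1"})])
        assert detect_gene_cluster(loci, window=15) == []

    def test_intervening_genes_permitted(self):
        loci = mk([("r1", 1, {"NanA"}), ("r1", 5, set()), ("r1", 8, {"NanK"}),
                   ("r1", 9, set()), ("r1", 11, {"NanE1"})])
        assert detect_gene_cluster(loci, window=15) == [("r1", 1, 11)]

    def test_window_smaller_than_roles_rejected(self):
        with pytest.raises(ClusterError):
            detect_gene_cluster([], required_roles=CANONICAL_ROLES, window=2)

    def test_one_gene_with_all_roles(self):
        loci = mk([("r1", 7, {"NanA", "NanK", "NanE1"})])
        assert detect_gene_cluster(loci, window=15) == [("r1", 7, 7)]

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.data())
    def test_agrees_with_exhaustive_oracle(self, data):
        n = data.draw(st.integers(5, 50))
        roles = ["NanA", "NanK", "NanE1"]
        loci = []
        for idx in range(1, n + 1):
            r = data.draw(st.sampled_from(["", "NanA", "NanK", "NanE1", "NanA,NanK"]))
            rep = data.draw(st.sampled_from(["r1", "r2"]))
            loci.append((rep, idx, frozenset(r.split(",")) - {""}))
        window = data.draw(st.integers(3, 20))
        got = detect_gene_cluster(loci, window=window)
        want = exhaustive_cluster_oracle(loci, CANONICAL_ROLES, window)
        assert got == want

    def test_permuting_rows_does_not_change_calls(self):
        rng = np.random.default_rng(3)
        loci = mk([("r1", 3, {"NanA"}), ("r1", 9, {"NanK"}), ("r1", 15, {"NanE1"}),
                   ("r2", 2, {"NanA", "NanK", "NanE1"})])
        base = detect_gene_cluster(loci, window=15)
        for _ in range(10):
            perm = [loci[i] for i in rng.permutation(len(loci))]
            assert detect_gene_cluster(perm, window=15) == base


# ---------------------------------------------------------------------------
# Pathway classification
# ---------------------------------------------------------------------------

def _loci(strain, n=20, rep="r1"):
    from sialoscreen.genome_screen import GeneLocus

    return [GeneLocus(strain, rep, i, f"{strain}_{rep}_p{i}") for i in range(1, n + 1)]


class _FakeCall:
    def __init__(self, call, has_sialidase=False, has_cbm40=False):
        from sialoscreen.domain_architecture import Call

        self.call = Call(call)
        self.has_sialidase = has_sialidase
        self.has_cbm40 = has_cbm40


class TestClassifyPathway:
    def test_clustered_strain_with_it_protein(self):
        loci = _loci("s1")
        roles = {"s1_r1_p2": {"NanA"}, "s1_r1_p4": {"NanK"}, "s1_r1_p9": {"NanE1"},
                 "s1_r1_p15": {"sialidase", "I-domain"}}
        calls = {"s1_r1_p15": _FakeCall("IT_SIALIDASE", has_sialidase=True)}
        res = classify_pathway("s1", roles, loci, calls)
        assert res.canonical_clustered and res.canonical_unclustered
        assert res.has_it_sialidase
        assert not res.bacteroides_type

    def test_bacteroides_type_only(self):
        loci = _loci("s2")
        roles = {"s2_r1_p1": {"NanA"}, "s2_r1_p8": {"NanE2"}, "s2_r1_p19": {"RokA"}}
        res = classify_pathway("s2", roles, loci, {})
        assert res.bacteroides_type
        assert not res.canonical_clustered and not res.canonical_unclustered

    def test_no_hits_all_false(self):
        res = classify_pathway("s3", {}, _loci("s3"), {})
        assert not (res.has_it_sialidase or res.canonical_clustered
                    or res.canonical_unclustered or res.bacteroides_type)

    def test_roka_model_missing_two_component_rule(self, caplog):
        roles = {"s4_r1_p1": {"NanA"}, "s4_r1_p8": {"NanE2"}}
        with caplog.at_level("WARNING"):
            res = classify_pathway("s4", roles, _loci("s4"), {}, roka_available=False)
        assert res.bacteroides_type
        assert any("RokA" in r.message for r in caplog.records)

    def test_clustered_implies_unclustered_on_random_fixtures(self):
        spec = synth.GenomeTableSpec(seed=2)
        loci, roles, _ = synth.make_genome_table(spec)
        strains = sorted({l.strain_id for l in loci})
        for s in strains:
            res = classify_pathway(s, roles[s], [l for l in loci if l.strain_id == s], {})
            assert not res.canonical_clustered or res.canonical_unclustered


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

def _strain(i, it=False, clustered=False, unclustered=None, bact=False, cbm=None,
            species=""):
    return StrainScreenResult(
        strain_id=f"s{i}", species=species, has_it_sialidase=it,
        canonical_clustered=clustered,
        canonical_unclustered=clustered if unclustered is None else unclustered,
        bacteroides_type=bact,
        it_cbm40_flags=cbm if cbm is not None else ([True] if it else []))


class TestSummary:
    def test_headline_percentages(self):
        results = []
        i = 0
        for _ in range(457):  # IT with canonical cluster
            results.append(_strain(i, it=True, clustered=True)); i += 1
        for _ in range(3):    # IT with Bacteroides-type pathway
            results.append(_strain(i, it=True, bact=True)); i += 1
        for _ in range(28):   # IT without any pathway
            results.append(_strain(i, it=True)); i += 1
        for _ in range(2967):  # pathway-positive, not IT
            results.append(_strain(i, clustered=True)); i += 1
        while i < 8126:
            results.append(_strain(i)); i += 1
        rep = summarize_genome_screen(results)
        assert rep["n_strains"] == 8126
        assert rep["n_it_positive"] == 488
        assert rep["pct_it_positive"] == 6
        assert rep["pct_it_with_cluster"] == 94
        assert rep["n_pathway_positive"] == 3427
        assert rep["pct_pathway_it_positive"] == 13

    def test_zero_it_positive_no_division_errors(self):
        rep = summarize_genome_screen([_strain(i) for i in range(10)])
        assert rep["pct_it_positive"] == 0
        assert rep["pct_it_with_cluster"] == 0
        assert rep["pct_it_with_cbm40"] == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_genome_screen([])

    def test_cbm40_fraction(self):
        results = [_strain(i, it=True, cbm=[i % 4 != 3]) for i in range(100)]
        rep = summarize_genome_screen(results)
        assert rep["pct_it_with_cbm40"] == 75

    def test_nane1_violations_counted(self):
        good = _strain(0, bact=True)
        bad = _strain(1, bact=True)
        bad.domain_hits = {"NanE1": {"p9"}}
        rep = summarize_genome_screen([good, bad])
        assert rep["n_nane1_violations"] == 1
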