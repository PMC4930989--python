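"""File formats and the two-stage missing-data QC filter."""

import numpy as np
import pytest

import coastcline as cc
from coastcline.core import MISSING
from coastcline.gio import FormatError, write_genotypes_structure


def _table(G, mitos=None, sites=None):
    G = np.asarray(G)
    n, L = G.shape
    return cc.GenotypeTable(
        individual_ids=tuple(f"i{k}" for k in range(n)),
        sites=tuple(sites or ["X"] * n),
        mitotypes=np.array(mitos or ["N"] * n, dtype=object),
        loci=tuple(f"L{j}" for j in range(L)),
        G=G,
        site_coords={"X": (-33.0, -71.0), "Y": (-40.0, -73.0)},
    )


class TestGenotypeCsv:
    def test_small_fixture_round_trip(self, tmp_path):
        t = _table([[0, 1], [2, MISSING], [1, 1]], mitos=["N", "S", "U"])
        path = tmp_path / "g.csv"
        cc.write_genotypes(t, path)
        back = cc.read_genotypes(path, "csv")
        assert back.G.shape == (3, 2)
        assert np.array_equal(back.G, t.G)
        assert tuple(back.mitotypes) == ("N", "S", "U")
        assert back.site_coords["X"] == (-33.0, -71.0)

    def test_na_token_reads_as_missing(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("id,site,lat,lon,mitotype,L0\n" "a,X,-33,-71,N,NA\n")
        t = cc.read_genotypes(path, "csv")
        assert t.G[0, 0] == MISSING

    def test_ragged_row_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("id,site,lat,lon,mitotype,L0,L1\n" "a,X,-33,-71,N,0\n")
        with pytest.raises(FormatError, match=":2"):
            cc.read_genotypes(path, "csv")

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("id,site,lat,lon,mitotype,L0\n"
                        "a,X,-33,-71,N,0\na,X,-33,-71,N,1\n")
        with pytest.raises(FormatError, match="duplicate"):
            cc.read_genotypes(path, "csv")

    def test_bad_genotype_code_rejected(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("id,site,lat,lon,mitotype,L0\n" "a,X,-33,-71,N,7\n")
        with pytest.raises(FormatError):
            cc.read_genotypes(path, "csv")


class TestStructureFormat:
    def test_round_trip_preserves_missing(self, tmp_path):
        t = _table([[0, 1, 2], [2, MISSING, 1]])
        path = tmp_path / "g.str"
        write_genotypes_structure(t, path)
        back = cc.read_genotypes(path, "structure_two_row")
        assert np.array_equal(back.G, t.G)

    def test_hand_built_fixture_with_missing_codes(self, tmp_path):
        path = tmp_path / "g.str"
        path.write_text(
            "ind1 pop1 1 -9\n"
            "ind1 pop1 2 -9\n"
            "ind2 pop2 1 1\n"
            "ind2 pop2 1 2\n"
        )
        t = cc.read_genotypes(path, "structure_two_row")
        assert t.G[0, 0] == 1          # one reference allele (1/2)
        assert t.G[0, 1] == MISSING
        assert t.G[1, 0] == 2          # 1/1
        assert t.G[1, 1] == 1          # 1/2
        assert t.sites == ("pop1", "pop2")

    def test_odd_row_count_rejected(self, tmp_path):
        path = tmp_path / "g.str"
        path.write_text("ind1 pop1 1 1\n")
        with pytest.raises(FormatError):
            cc.read_genotypes(path, "structure_two_row")

    def test_unknown_allele_code_rejected(self, tmp_path):
        path = tmp_path / "g.str"
        path.write_text("ind1 pop1 3\nind1 pop1 1\n")
        with pytest.raises(FormatError):
            cc.read_genotypes(path, "structure_two_row")


class TestQC:
    def test_locus_threshold_is_strictly_greater_than(self):
        # 4 individuals x 4 loci with missing fractions 0, .25, .5, .75
        G = np.zeros((4, 4), dtype=int)
        G[0, 1] = MISSING
        G[0:2, 2] = MISSING
        G[0:3, 3] = MISSING
        t = _table(G)
        out, rep = cc.apply_qc(t)
        assert list(rep.loci_removed) == ["L3"]     # 0.75 > 0.5 removed
        assert out.n_loci == 3                      # 0.50 retained (not >)

    def test_individual_threshold_on_remaining_loci(self):
        # 10 loci survive; one individual misses 3 of them (0.30 > 0.25)
        G = np.zeros((4, 10), dtype=int)
        G[0, :3] = MISSING
        t = _table(G)
        out, rep = cc.apply_qc(t)
        assert list(rep.individuals_removed) == ["i0"]
        assert out.n_individuals == 3

    def test_no_missing_data_is_identity(self):
        t = _table(np.ones((3, 4), dtype=int))
        out, rep = cc.apply_qc(t)
        assert out.G.shape == (3, 4)
        assert not rep.loci_removed and not rep.individuals_removed

    def test_loci_then_individuals_order_matters(self):
        # Individual i0 misses only entries in a bad locus; once that locus is
        # dropped first, i0 is clean.  Filtering individuals first would
        # remove i0 (3/4 missing > 0.25).
        G = np.zeros((4, 4), dtype=int)
        G[0, 0] = MISSING
        G[1, 0] = MISSING
        G[2, 0] = MISSING
        G[0, 1] = MISSING
        G[0, 2] = MISSING
        t = _table(G)
        out, rep = cc.apply_qc(t)
        assert list(rep.loci_removed) == ["L0"]     # 0.75 missing
        # over remaining loci L1..L3 individual i0 misses 2/3 = 0.67 > 0.25
        assert list(rep.individuals_removed) == ["i0"]

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 3, size=(20, 15))
        G[rng.random(G.shape) < 0.3] = MISSING
        t = _table(G)
        once, _ = cc.apply_qc(t)
        twice, rep2 = cc.apply_qc(once)
        assert np.array_equal(once.G, twice.G)
        assert not rep2.loci_removed and not rep2.individuals_removed

    def test_all_loci_removed_is_an_error(self):
        t = _table(np.full((4, 2), MISSING))
        with pytest.raises(ValueError):
            cc.apply_qc(t)


class TestVariableLoci:
    @pytest.mark.parametrize(
        "column, variable",
        [([0, 0, 0, 0], False),      # all homozygous reference: monomorphic
         ([0, 0, 1, 0], True),       # one het implies both alleles
         ([2, 2, 2, 2], False),
         ([MISSING, 0, 2, 0], True)],
    )
    def test_single_locus_cases(self, column, variable):
        t = _table(np.array(column).reshape(-1, 1))
        assert cc.count_variable_loci(t) == int(variable)

    def test_mixed_fixture_counts_variable_loci(self):
        G = np.array([
            [0, 2, 0, 1, 2],
            [0, 2, 1, 1, 2],
            [0, 2, 2, 0, 1],
        ])
        assert cc.count_variable_loci(_table(G)) == 3  # loci 0 and 1 monomorphic


class TestConnectivityIO:
    def test_identity_matrix_round_trip(self, grid5, tmp_path):
        conn = cc.ConnectivityMatrix(grid5, np.eye(5))
        path = tmp_path / "c.tsv"
        cc.write_connectivity(conn, path)
        back = cc.read_connectivity(path, grid=grid5)
        assert np.allclose(back.C, np.eye(5))

    def test_row_sum_above_one_rejected(self, grid5, tmp_path):
        path = tmp_path / "c.tsv"
        ids = "\t".join(grid5.site_ids)
        rows = []
        for i, s in enumerate(grid5.site_ids):
            vals = [0.0] * 5
            vals[i] = 1.2 if i == 0 else 0.5
            rows.append(s + "\t" + "\t".join(map(str, vals)))
        path.write_text("site\t" + ids + "\n" + "\n".join(rows) + "\n")
        with pytest.raises(FormatError):
            cc.read_connectivity(path, grid=grid5)

    def test_negative_entry_rejected(self, grid5, tmp_path):
        path = tmp_path / "c.tsv"
        C = np.eye(5)
        C[0, 1] = -0.1
        ids = "\t".join(grid5.site_ids)
        rows = [s + "\t" + "\t".join(map(str, C[i]))
                for i, s in enumerate(grid5.site_ids)]
        path.write_text("site\t" + ids + "\n" + "\n".join(rows) + "\n")
        with pytest.raises(FormatError):
            cc.read_connectivity(path, grid=grid5)


class TestClineIO:
    def test_count_round_trip(self, grid5, tmp_path):
        obs = cc.LineageCline(grid5, np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
                              n=np.full(5, 4), count_north=[0, 1, 2, 3, 4],
                              source="mitochondrial")
        path = tmp_path / "cl.csv"
        cc.write_observed_cline(obs, path)
        back = cc.read_observed_cline(path)
        assert np.allclose(back.f, obs.f)
        assert np.array_equal(back.count_north, obs.count_north)

    def test_count_exceeding_n_rejected(self, tmp_path):
        path = tmp_path / "cl.csv"
        path.write_text("site,lat,lon,n,count_north\n" "a,-40,-73,10,12\n")
        with pytest.raises(FormatError):
            cc.read_observed_cline(path)

    def test_assignment_probability_variant(self, tmp_path):
        path = tmp_path / "cl.csv"
        path.write_text("site,lat,lon,mean_assign_north\n"
                        "a,-40,-73,0.25\nb,-39,-73,0.75\n")
        cl = cc.read_observed_cline(path)
        assert cl.source == "nuclear_assignment"
        assert np.allclose(cl.f, [0.25, 0.75])
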