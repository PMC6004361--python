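"""Pool-seq Fst formula, filters and candidate annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sibqtl import bsa
from sibqtl.bsa import GeneFeature, PoolSiteCounts


def pc(site, nA=0, nC=0, nG=0, nT=0, contig="c1", pos=100):
    return PoolSiteCounts(site, contig, pos, nA, nC, nG, nT)


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((10, 0, 0, 0), (1, 0, 0, 0)),
            ((5, 5, 0, 0), (0.5, 0.5, 0, 0)),
            ((9, 0, 1, 0), (0.9, 0, 0.1, 0)),
        ],
    )
    def test_examples(self, counts, expected):
        f = bsa.allele_frequencies(pc("s", *counts))
        np.testing.assert_allclose(f, expected)
        assert f.sum() == pytest.approx(1.0)

    def test_zero_depth_undefined(self):
        with pytest.raises(ZeroDivisionError):
            bsa.allele_frequencies(pc("s"))


class TestSitePi:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ((1, 0, 0, 0), 0.0),               # monomorphic
            ((0.5, 0.5, 0, 0), 0.5),
            ((0.25, 0.25, 0.25, 0.25), 0.75),  # 1 - 4/16
        ],
    )
    def test_examples(self, freqs, expected):
        assert bsa.site_pi(np.array(freqs)) == pytest.approx(expected)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            bsa.site_pi(np.array([0.5, 0.2, 0, 0]))


class TestSiteFst:
    def test_identical_pools_zero(self):
        r = bsa.site_fst(pc("s", nA=5, nC=5), pc("s", nA=5, nC=5))
        assert r.fst == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_one(self):
        r = bsa.site_fst(pc("s", nA=50), pc("s", nC=50))
        assert r.pi_within == pytest.approx(0.0)
        assert r.pi_total == pytest.approx(0.5)
        assert r.fst == pytest.approx(1.0)

    def test_worked_value(self):
        """Hand evaluation for 0.9-vs-0.1 frequency pools: Pi each 0.18,
        Pi_within 0.18, Pi_total 0.5, Fst 0.64."""
        r = bsa.site_fst(pc("s", nA=45, nC=5), pc("s", nA=5, nC=45))
        assert r.pi_pool1 == pytest.approx(0.18, abs=1e-12)
        assert r.pi_pool2 == pytest.approx(0.18, abs=1e-12)
        assert r.pi_within == pytest.approx(0.18, abs=1e-12)
        assert r.pi_total == pytest.approx(0.5, abs=1e-12)
        assert r.fst == pytest.approx(0.64, abs=1e-12)

    def test_monomorphic_undefined(self):
        r = bsa.site_fst(pc("s", nA=30), pc("s", nA=20))
        assert np.isnan(r.fst)

    def test_symmetry(self, rng):
        for _ in range(50):
            c1 = rng.integers(0, 60, 4)
            c2 = rng.integers(0, 60, 4)
            if c1.sum() == 0 or c2.sum() == 0:
                continue
            a = bsa.site_fst(pc("s", *c1), pc("s", *c2))
            b = bsa.site_fst(pc("s", *c2), pc("s", *c1))
            assert a.fst == pytest.approx(b.fst, nan_ok=True)

    @settings(derandomize=True, max_examples=200)
    @given(
        c1=st.lists(st.integers(0, 200), min_size=4, max_size=4),
        c2=st.lists(st.integers(0, 200), min_size=4, max_size=4),
    )
    def test_bounded(self, c1, c2):
        """0 <= Fst <= 1 for any counts (concavity of Pi under unweighted
        frequency averaging), nan only at joint monomorphism."""
        if sum(c1) == 0 or sum(c2) == 0:
            return
        r = bsa.site_fst(pc("s", *c1), pc("s", *c2))
        if np.isnan(r.fst):
            assert r.pi_total == pytest.approx(0.0, abs=1e-12)
        else:
            assert -1e-12 <= r.fst <= 1 + 1e-12


def _random_pool_tables(rng, n_sites=60, low=0, high=80):
    rows1, rows2 = [], []
    for i in range(n_sites):
        c1 = rng.integers(low, high, 4)
        c2 = rng.integers(low, high, 4)
        base = {"site_id": f"s{i}", "contig": "c1", "pos": 10 * (i + 1), "ref": "A"}
        rows1.append({**base, "nA": c1[0], "nC": c1[1], "nG": c1[2], "nT": c1[3]})
        rows2.append({**base, "nA": c2[0], "nC": c2[1], "nG": c2[2], "nT": c2[3]})
    return pd.DataFrame(rows1), pd.DataFrame(rows2)


class TestScan:
    def test_worked_site_retained(self):
        p1 = pd.DataFrame(
            [{"site_id": "s", "contig": "c1", "pos": 5, "ref": "A",
              "nA": 45, "nC": 5, "nG": 0, "nT": 0}]
        )
        p2 = pd.DataFrame(
            [{"site_id": "s", "contig": "c1", "pos": 5, "ref": "A",
              "nA": 5, "nC": 45, "nG": 0, "nT": 0}]
        )
        hits = bsa.scan(p1, p2)
        assert len(hits) == 1
        assert hits.fst.iloc[0] == pytest.approx(0.64)

    def test_low_coverage_dropped(self):
        p1 = pd.DataFrame(
            [{"site_id": "s", "contig": "c1", "pos": 5, "ref": "A",
              "nA": 50, "nC": 0, "nG": 0, "nT": 0}]
        )
        p2 = pd.DataFrame(
            [{"site_id": "s", "contig": "c1", "pos": 5, "ref": "A",
              "nA": 0, "nC": 15, "nG": 0, "nT": 0}]
        )
        # fst would be 1 but pool2 depth 15 <= 20
        assert len(bsa.scan(p1, p2)) == 0

    def test_monomorphic_excluded(self):
        p1, p2 = _random_pool_tables(np.random.default_rng(0), n_sites=1)
        p1.loc[0, ["nA", "nC", "nG", "nT"]] = [40, 0, 0, 0]
        p2.loc[0, ["nA", "nC", "nG", "nT"]] = [40, 0, 0, 0]
        assert len(bsa.scan(p1, p2)) == 0

    def test_disjoint_sites_error(self):
        p1, p2 = _random_pool_tables(np.random.default_rng(0), n_sites=4)
        p2["site_id"] = p2["site_id"] + "_other"
        with pytest.raises(ValueError):
            bsa.scan(p1, p2)

    def test_brute_force_oracle(self, rng):
        """Scan results equal a direct per-site recomputation of the printed
        formula with explicit filter checks."""
        p1, p2 = _random_pool_tables(rng, n_sites=120)
        hits = bsa.scan(p1, p2, min_fst=0.2, min_coverage=20)
        expected = {}
        for i in range(len(p1)):
            c1 = p1.loc[i, ["nA", "nC", "nG", "nT"]].to_numpy(float)
            c2 = p2.loc[i, ["nA", "nC", "nG", "nT"]].to_numpy(float)
            d1, d2 = c1.sum(), c2.sum()
            m1 = np.where(c1 >= 4, c1, 0.0)
            m2 = np.where(c2 >= 4, c2, 0.0)
            if m1.sum() == 0 or m2.sum() == 0:
                continue
            if ((m1 > 0) | (m2 > 0)).sum() < 2:
                continue
            f1, f2 = m1 / m1.sum(), m2 / m2.sum()
            pi1 = 1 - (f1**2).sum()
            pi2 = 1 - (f2**2).sum()
            fm = (f1 + f2) / 2
            pit = 1 - (fm**2).sum()
            if pit <= 0:
                continue
            fst = (pit - (pi1 + pi2) / 2) / pit
            if fst > 0.2 and d1 > 20 and d2 > 20:
                expected[p1.loc[i, "site_id"]] = fst
        assert set(hits.site_id) == set(expected)
        for rec in hits.itertuples(index=False):
            assert rec.fst == pytest.approx(expected[rec.site_id], abs=1e-12)

    def test_sorted_and_subset(self, rng):
        p1, p2 = _random_pool_tables(rng, n_sites=200)
        hits = bsa.scan(p1, p2, min_fst=0.05)
        assert set(hits.site_id) <= set(p1.site_id)
        assert (hits.fst.to_numpy()[:-1] >= hits.fst.to_numpy()[1:] - 1e-15).all()
        assert (hits.fst > 0.05).all()
        assert (hits.depth1 > 20).all() and (hits.depth2 > 20).all()


class TestAnnotation:
    def test_overlap_inclusive_boundaries(self):
        feats = [GeneFeature("g1", "c1", 90, 110, "exon")]
        hits = pd.DataFrame(
            {"site_id": ["a", "b"], "contig": ["c1", "c1"], "pos": [100, 89],
             "fst": [0.8, 0.9]}
        )
        mapped, genes = bsa.annotate_candidates(hits, feats)
        assert list(mapped.site_id) == ["a"]
        assert genes == ["g1"]

    def test_non_coding_excluded(self):
        feats = [GeneFeature("g1", "c1", 90, 110, "other")]
        hits = pd.DataFrame(
            {"site_id": ["a"], "contig": ["c1"], "pos": [100], "fst": [0.8]}
        )
        mapped, genes = bsa.annotate_candidates(hits, feats)
        assert len(mapped) == 0 and genes == []

    def test_29_sites_in_23_genes(self):
        """Synthetic hit set mirroring the study's cardinality: 29 SNPs
        anchored in 23 genes yields a candidate list of 23."""
        feats, rows = [], []
        s = 0
        # first 6 genes carry 2 SNPs each, the rest 1 (6*2 + 17 = 29)
        for g in range(23):
            start = 1000 * (g + 1)
            feats.append(GeneFeature(f"g{g}", "c1", start, start + 500, "exon"))
            for _ in range(2 if g < 6 else 1):
                rows.append(
                    {"site_id": f"s{s}", "contig": "c1", "pos": start + 10 + s,
                     "fst": 0.7}
                )
                s += 1
        assert s == 29
        mapped, genes = bsa.annotate_candidates(pd.DataFrame(rows), feats)
        assert len(mapped) == 29
        assert len(genes) == 23

    def test_malformed_feature_rejected(self):
        with pytest.raises(ValueError, match="gX"):
            GeneFeature("gX", "c1", 100, 90, "exon")


class TestFeatureIO:
    def test_bed_roundtrip_coordinates(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("c1\t89\t110\tg1:exon\t0\t+\nc2\t0\t50\tg2:promoter\t0\t-\n")
        feats = bsa.read_features_bed(str(p))
        assert feats[0].start == 90 and feats[0].end == 110
        assert feats[0].feature_kind == "exon"
        assert feats[1].start == 1 and feats[1].gene_id == "g2"

    def test_gff3(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text(
            "##gff-version 3\n"
            "c1\tsrc\texon\t90\t110\t.\t+\t.\tgene_id=g1\n"
            "c1\tsrc\tpromoter\t10\t89\t.\t+\t.\tID=g1.prom;Parent=g1\n"
        )
        feats = bsa.read_features_gff3(str(p))
        assert feats[0].start == 90 and feats[0].end == 110
        assert feats[1].feature_kind == "promoter"
        assert feats[1].gene_id == "g1"
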