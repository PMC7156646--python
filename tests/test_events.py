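"""Splicing-event generation, inclusion quantification, differential tests."""

import numpy as np
import pandas as pd
import pytest

from isoribo import events as ev
from isoribo import simulate as sim
from isoribo.annotation import GeneModel, IsoformModel
from isoribo.errors import DataError

from _oracles import event_keys, oracle_events


def make_iso(tid, gene_id, exons, strand="+", chrom="chr1"):
    n = sum(e - s for s, e in exons)
    return IsoformModel(
        transcript_id=tid, gene_id=gene_id, chrom=chrom, strand=strand,
        exons=sorted(exons), orf=(0, n), cdna="A" * n,
    )


def make_gene(gid, chains, strand="+"):
    isoforms = [
        make_iso(tid, gid, exons, strand=strand) for tid, exons in chains.items()
    ]
    return GeneModel(gene_id=gid, chrom="chr1", strand=strand, isoforms=isoforms)


class FakeAnnotation:
    def __init__(self, genes):
        self.genes = {g.gene_id: g for g in genes}


def events_of(gene, **kw):
    return ev.generate_events(FakeAnnotation([gene]), **kw)


class TestHandExamples:
    def test_se(self):
        gene = make_gene("G", {
            "T1": [(0, 100), (200, 300), (400, 500)],
            "T2": [(0, 100), (400, 500)],
        })
        evs = events_of(gene)
        assert len(evs) == 1
        e = evs[0]
        assert e.etype == "SE"
        assert e.inclusion == frozenset({"T1"})
        assert e.total == frozenset({"T1", "T2"})
        assert e.alt_exon == (200, 300)
        assert e.region == (200, 300)

    def test_a3_plus_strand(self):
        gene = make_gene("G", {
            "T1": [(0, 100), (200, 400)],
            "T2": [(0, 100), (230, 400)],
        })
        evs = events_of(gene)
        assert [e.etype for e in evs] == ["A3"]
        e = evs[0]
        assert e.inclusion == frozenset({"T1"})  # longer exon = inclusion form
        assert e.region == (200, 230)

    def test_a3_becomes_a5_on_minus(self):
        gene = make_gene("G", {
            "T1": [(0, 100), (200, 400)],
            "T2": [(0, 100), (230, 400)],
        }, strand="-")
        evs = events_of(gene)
        assert [e.etype for e in evs] == ["A5"]

    def test_a5_plus_strand(self):
        gene = make_gene("G", {
            "T1": [(0, 100), (300, 400)],
            "T2": [(0, 150), (300, 400)],
        })
        evs = events_of(gene)
        assert [e.etype for e in evs] == ["A5"]
        e = evs[0]
        assert e.inclusion == frozenset({"T2"})
        assert e.region == (100, 150)

    def test_a5_becomes_a3_on_minus(self):
        gene = make_gene("G", {
            "T1": [(0, 100), (300, 400)],
            "T2": [(0, 150), (300, 400)],
        }, strand="-")
        assert [e.etype for e in events_of(gene)] == ["A3"]

    def test_mx(self):
        gene = make_gene("G", {
            "T1": [(0, 100), (200, 300), (500, 600)],
            "T2": [(0, 100), (350, 450), (500, 600)],
        })
        evs = events_of(gene)
        assert [e.etype for e in evs] == ["MX"]
        e = evs[0]
        assert e.inclusion == frozenset({"T1"})  # genomically first exon
        assert e.alt_exon == (200, 300)

    def test_no_mx_when_an_isoform_has_both(self):
        gene = make_gene("G", {
            "T1": [(0, 100), (200, 300), (500, 600)],
            "T2": [(0, 100), (350, 450), (500, 600)],
            "T3": [(0, 100), (200, 300), (350, 450), (500, 600)],
        })
        assert not [e for e in events_of(gene) if e.etype == "MX"]

    def test_ri(self):
        gene = make_gene("G", {
            "T1": [(0, 100), (200, 300)],
            "T2": [(0, 300)],
        })
        evs = events_of(gene)
        assert [e.etype for e in evs] == ["RI"]
        e = evs[0]
        assert e.inclusion == frozenset({"T2"})  # retention = inclusion form
        assert e.region == (100, 200)

    def test_af(self):
        gene = make_gene("G", {
            "T1": [(0, 50), (200, 300)],
            "T2": [(80, 130), (200, 300)],
        })
        evs = events_of(gene)
        assert [e.etype for e in evs] == ["AF"]
        assert evs[0].total == frozenset({"T1", "T2"})

    def test_af_becomes_al_on_minus(self):
        gene = make_gene("G", {
            "T1": [(0, 50), (200, 300)],
            "T2": [(80, 130), (200, 300)],
        }, strand="-")
        assert [e.etype for e in events_of(gene)] == ["AL"]

    def test_al(self):
        gene = make_gene("G", {
            "T1": [(0, 100), (200, 250)],
            "T2": [(0, 100), (300, 350)],
        })
        assert [e.etype for e in events_of(gene)] == ["AL"]

    def test_orf_overlap_filter(self):
        # alternative exon outside every ORF -> filtered by default
        iso1 = make_iso("T1", "G", [(0, 100), (200, 300), (400, 500)])
        iso2 = make_iso("T2", "G", [(0, 100), (400, 500)])
        iso1.orf = (0, 99)     # ORF confined to the first exon
        iso2.orf = (0, 99)
        gene = GeneModel("G", "chr1", "+", [iso1, iso2])
        assert events_of(gene) == []
        assert len(events_of(gene, require_orf_overlap=False)) == 1

    def test_single_isoform_gene_yields_nothing(self):
        gene = make_gene("G", {"T1": [(0, 100), (200, 300)]})
        assert events_of(gene) == []


class TestOracleAgreement:
    def test_random_genes(self):
        rng = np.random.default_rng(42)
        for k in range(60):
            strand = "+" if k % 2 == 0 else "-"
            gene = sim.random_gene(
                rng, f"G{k}", int(rng.integers(2, 5)), strand=strand
            )
            got = event_keys(events_of(gene, require_orf_overlap=False))
            expected = oracle_events(gene)
            assert got == expected, f"gene {k} ({strand})"


class TestMicroexons:
    def se_gene(self, exon_len):
        return make_gene("G", {
            "T1": [(0, 100), (200, 200 + exon_len), (400, 500)],
            "T2": [(0, 100), (400, 500)],
        })

    @pytest.mark.parametrize(
        "length,micro,short",
        [(51, True, False), (52, False, False), (27, True, True), (28, True, False)],
    )
    def test_boundaries(self, length, micro, short):
        evs = ev.flag_microexons(events_of(self.se_gene(length)))
        assert len(evs) == 1
        assert evs[0].microexon is micro
        assert evs[0].short_microexon is short

    def test_non_se_never_flagged(self):
        gene = make_gene("G", {
            "T1": [(0, 100), (200, 210)],
            "T2": [(0, 100), (300, 310)],
        })
        evs = ev.flag_microexons(events_of(gene))
        assert all(not e.microexon for e in evs)


class TestInclusion:
    def event(self):
        gene = make_gene("G", {
            "T1": [(0, 100), (200, 300), (400, 500)],
            "T2": [(0, 100), (400, 500)],
        })
        return events_of(gene)

    def test_psi_formula(self):
        evs = self.event()
        table = pd.DataFrame({"s1": {"T1": 30.0, "T2": 10.0}})
        psi, den = ev.compute_event_inclusion(evs, table)
        assert psi.iloc[0, 0] == pytest.approx(0.75)
        assert den.iloc[0, 0] == pytest.approx(40.0)

    def test_low_denominator_is_nan(self):
        evs = self.event()
        table = pd.DataFrame({"s1": {"T1": 0.04, "T2": 0.05}})
        psi, den = ev.compute_event_inclusion(evs, table)
        assert np.isnan(psi.iloc[0, 0])

    def test_scaling_invariance(self):
        evs = self.event()
        t1 = pd.DataFrame({"s1": {"T1": 30.0, "T2": 10.0}})
        t2 = t1 * 17.0
        psi1, _ = ev.compute_event_inclusion(evs, t1)
        psi2, _ = ev.compute_event_inclusion(evs, t2)
        pd.testing.assert_frame_equal(psi1, psi2)

    def test_missing_isoform_contributes_zero(self):
        evs = self.event()
        table = pd.DataFrame({"s1": {"T1": 30.0}})
        psi, den = ev.compute_event_inclusion(evs, table)
        assert psi.iloc[0, 0] == pytest.approx(1.0)
        assert den.iloc[0, 0] == pytest.approx(30.0)


def null_psi(rng, n_events, n_reps, sd=0.05, prefix="E"):
    base = rng.uniform(0.2, 0.8, n_events)
    mk = lambda: pd.DataFrame(
        np.clip(base[:, None] + rng.normal(0, sd, (n_events, n_reps)), 0, 1),
        index=[f"{prefix}{i}" for i in range(n_events)],
        columns=[f"r{j}" for j in range(n_reps)],
    )
    return mk(), mk()


class TestDifferential:
    def test_needs_two_replicates(self):
        p1 = pd.DataFrame({"r1": {"E0": 0.5}})
        with pytest.raises(DataError):
            ev.differential_inclusion(p1, p1)

    def test_null_type_one_error_near_alpha(self):
        rng = np.random.default_rng(9)
        p1, p2 = null_psi(rng, 400, 3)
        res = ev.differential_inclusion(p1, p2, min_effect=0.0)
        rate = (res["pval"] < 0.05).mean()
        # binomial 95% band around 0.05 with n=400
        assert 0.05 - 2.0 * np.sqrt(0.05 * 0.95 / 400) <= rate <= \
            0.05 + 2.0 * np.sqrt(0.05 * 0.95 / 400) + 0.01

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(10)
        p1, p2 = null_psi(rng, 300, 3, sd=0.02)
        p1.loc["E0"] = np.clip(0.3 + rng.normal(0, 0.02, 3), 0, 1)
        p2.loc["E0"] = np.clip(0.7 + rng.normal(0, 0.02, 3), 0, 1)
        res = ev.differential_inclusion(p1, p2)
        assert res.loc["E0", "significant"]
        assert res.loc["E0", "dpsi"] == pytest.approx(0.4, abs=0.05)

    def test_nan_rows_excluded_and_counted(self):
        rng = np.random.default_rng(11)
        p1, p2 = null_psi(rng, 50, 3)
        p1.iloc[0, 0] = np.nan
        res = ev.differential_inclusion(p1, p2)
        assert res.attrs["n_excluded"] == 1
        assert "E0" not in res.index

    def test_significance_needs_effect_size(self):
        rng = np.random.default_rng(12)
        p1, p2 = null_psi(rng, 200, 3, sd=0.001)
        p2.loc["E0"] += 0.05  # tiny but consistent shift
        res = ev.differential_inclusion(p2.clip(0, 1), p1, min_effect=0.1)
        assert not res.loc["E0", "significant"]  # |dpsi| <= min_effect


class TestConservedMatching:
    def test_exact_mapping(self):
        g_a = make_gene("GA", {
            "T1": [(0, 100), (200, 300), (400, 500)],
            "T2": [(0, 100), (400, 500)],
        })
        g_b = make_gene("GB", {
            "U1": [(0, 100), (1200, 1300), (1400, 1500)],
            "U2": [(0, 100), (1400, 1500)],
        })
        evs_a = events_of(g_a)
        evs_b = events_of(g_b)
        coord_map = pd.DataFrame(
            [["chr1", 201, 300, "chr1", 1201, 1300]],
            columns=["ca", "sa", "ea", "cb", "sb", "eb"],
        )
        pairs, stats = ev.match_conserved_events(evs_a, evs_b, coord_map)
        assert len(pairs) == 1
        assert pairs[0][0].event_id == evs_a[0].event_id
        assert pairs[0][1].event_id == evs_b[0].event_id

    def test_direction_concordance(self):
        g_a = make_gene("GA", {
            "T1": [(0, 100), (200, 300), (400, 500)],
            "T2": [(0, 100), (400, 500)],
        })
        evs = events_of(g_a)
        pairs = [(evs[0], evs[0])]
        da = pd.Series({evs[0].event_id: 0.3})
        db = pd.Series({evs[0].event_id: 0.2})
        assert ev.direction_concordance(pairs, da, db) == 1.0
        db = pd.Series({evs[0].event_id: -0.2})
        assert ev.direction_concordance(pairs, da, db) == 0.0


class TestIoe:
    def test_round_trip(self, tmp_path, small_sim):
        cfg, annotation, truth = small_sim
        evs = ev.flag_microexons(ev.generate_events(annotation))
        path = tmp_path / "ev.ioe"
        ev.write_ioe(evs, path, header_lines=["x"])
        back = ev.read_ioe(path)
        assert len(back) == len(evs)
        for a, b in zip(evs, back):
            assert a.event_id == b.event_id
            assert a.inclusion == b.inclusion
            assert a.total == b.total
            assert a.microexon == b.microexon
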