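"""Translation-calling metrics, calibration, and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isoribo import calling as cl
from isoribo.calling import (
    CalibrationThresholds,
    calibrate_thresholds,
    classify_orfs,
    compute_periodicity,
    compute_pme,
    summarize_gene_isoform_status,
)
from isoribo.errors import DataError
from isoribo.psite import OrfProfile


def profile_from_frames(f0, f1, f2, codons=10, orf_id="O1"):
    """An OrfProfile with the requested total weight per frame."""
    counts = np.zeros(codons * 3)
    counts[0::3] = f0 / codons
    counts[1::3] = f1 / codons
    counts[2::3] = f2 / codons
    return OrfProfile(orf_id, counts)


class TestPME:
    def test_even_counts_give_one(self):
        assert compute_pme([2, 2, 2, 2]) == 1.0

    def test_single_spike_gives_zero(self):
        assert compute_pme([8, 0, 0, 0]) == 0.0

    def test_half_split_gives_half(self):
        assert compute_pme([4, 4, 0, 0]) == 0.5

    def test_single_region_is_one(self):
        assert compute_pme([5]) == 1.0

    def test_zero_reads_raise(self):
        with pytest.raises(DataError):
            compute_pme([0, 0, 0])

    def test_permutation_invariance_1000_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            v = rng.integers(0, 50, size=rng.integers(2, 30))
            if v.sum() == 0:
                v[0] = 1
            assert compute_pme(v) == pytest.approx(
                compute_pme(rng.permutation(v)), abs=1e-12
            )

    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=40).filter(sum))
    def test_bounds(self, v):
        assert 0.0 <= compute_pme(v) <= 1.0 + 1e-12

    def test_profile_codon_binning(self):
        # 4 codons, all weight evenly split across codons -> PME 1
        prof = OrfProfile("O1", np.tile([1.0, 0.0, 0.0], 4))
        assert compute_pme(prof) == 1.0
        # all weight in one codon -> PME 0
        counts = np.zeros(12)
        counts[0] = 9.0
        assert compute_pme(OrfProfile("O1", counts)) == 0.0


class TestPeriodicity:
    def test_frame_90_5_5(self):
        assert compute_periodicity(profile_from_frames(90, 5, 5)) == pytest.approx(0.9)

    def test_uniform_frames(self):
        assert compute_periodicity(profile_from_frames(5, 5, 5)) == pytest.approx(1 / 3)

    def test_zero_reads_raise(self):
        with pytest.raises(DataError):
            compute_periodicity(OrfProfile("O1", np.zeros(9)))


class TestCalibration:
    def test_exact_quantile_on_grid(self):
        # 21 values 0.80..1.00: (n-1)*q = 20*0.1 = 2 -> exactly the 3rd value
        vals = [0.80 + 0.01 * i for i in range(21)]
        thr = calibrate_thresholds(vals, vals, coverage_fraction=0.90)
        assert thr.periodicity_min == pytest.approx(0.82)
        assert thr.pme_min == pytest.approx(0.82)

    def test_interpolated_quantile(self):
        # 20 values 0.80..0.99: h = 19*0.1 = 1.9 -> 0.81 + 0.9*0.01
        vals = [0.80 + 0.01 * i for i in range(20)]
        thr = calibrate_thresholds(vals, vals, coverage_fraction=0.90)
        assert thr.periodicity_min == pytest.approx(0.819)

    def test_coverage_holds_on_controls(self):
        rng = np.random.default_rng(3)
        per = rng.uniform(0.5, 1.0, 500)
        pme = rng.uniform(0.5, 1.0, 500)
        thr = calibrate_thresholds(per, pme, coverage_fraction=0.90)
        frac = np.mean((per >= thr.periodicity_min) & (pme >= thr.pme_min))
        # one-sided marginal quantiles: each margin keeps >= 90%
        assert np.mean(per >= thr.periodicity_min) >= 0.90 - 1e-9
        assert np.mean(pme >= thr.pme_min) >= 0.90 - 1e-9
        assert frac <= 1.0

    def test_too_few_controls_raise(self):
        with pytest.raises(DataError):
            calibrate_thresholds([0.9] * 5, [0.9] * 5, min_controls=20)

    def test_json_round_trip(self, tmp_path):
        thr = CalibrationThresholds(0.5, 0.6, 0.9, ["a", "b"])
        thr.to_json(tmp_path / "t.json")
        assert CalibrationThresholds.from_json(tmp_path / "t.json") == thr


class TestClassification:
    def make(self, n_reads):
        return profile_from_frames(n_reads * 0.9, n_reads * 0.05, n_reads * 0.05)

    def test_filters_exact_bookkeeping(self):
        thr = CalibrationThresholds(0.5, 0.5)
        profiles = {
            "lowreads": self.make(9),     # 9 reads -> not_evaluated
            "lowtpm": self.make(100),     # TPM 0.1 -> not_evaluated (<= rule)
            "ok": self.make(100),
            "edge": self.make(10),        # exactly 10 reads -> evaluated
        }
        tpm = pd.Series({"lowreads": 5.0, "lowtpm": 0.1, "ok": 5.0, "edge": 5.0,
                         "noprofile": 5.0})
        calls = classify_orfs(profiles, tpm, thr).set_index("orf_id")
        assert calls.loc["lowreads", "status"] == "not_evaluated"
        assert calls.loc["lowtpm", "status"] == "not_evaluated"
        assert calls.loc["noprofile", "status"] == "not_evaluated"
        assert calls.loc["ok", "status"] == "translated"
        assert calls.loc["edge", "status"] == "translated"
        assert (calls["status"] == "not_evaluated").sum() == 3

    def test_threshold_decides(self):
        profiles = {"a": self.make(100)}  # periodicity 0.9, even codons
        tpm = pd.Series({"a": 5.0})
        lo = classify_orfs(profiles, tpm, CalibrationThresholds(0.85, 0.5))
        hi = classify_orfs(profiles, tpm, CalibrationThresholds(0.95, 0.5))
        assert lo.iloc[0]["status"] == "translated"
        assert hi.iloc[0]["status"] == "not_translated"

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        profiles = {
            f"o{i}": OrfProfile(f"o{i}", rng.random(30) + 0.01) for i in range(50)
        }
        tpm = pd.Series(5.0, index=list(profiles))
        counts = []
        for t in np.linspace(0.0, 1.0, 11):
            calls = classify_orfs(profiles, tpm, CalibrationThresholds(t, 0.0))
            counts.append((calls["status"] == "translated").sum())
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestRecoveryProperty:
    def test_sensitivity_tracks_calibration_and_nulls_rejected(self):
        """Joint sensitivity is bounded by the per-metric calibration level.

        With both thresholds at the (1 - coverage_fraction) quantile of the
        positive class, each metric alone passes ~coverage_fraction of
        positives, so the AND rule passes between coverage_fraction^2 and
        coverage_fraction. Bursty frame-uniform nulls are far from both
        thresholds and are rejected almost surely.
        """
        rng = np.random.default_rng(1301)
        n_codons, reads = 100, 200
        profiles, labels = {}, {}
        for i in range(500):
            translated = bool(rng.random() < 0.5)
            alpha = 50.0 if translated else 0.15
            bias = 0.9 if translated else 1 / 3
            codon_p = rng.dirichlet(np.full(n_codons, alpha))
            codons = rng.choice(n_codons, size=reads, p=codon_p)
            u = rng.random(reads)
            frames = np.where(u < bias, 0, np.where(u < bias + (1 - bias) / 2, 1, 2))
            counts = np.zeros(n_codons * 3)
            np.add.at(counts, codons * 3 + frames, 1.0)
            profiles[f"o{i}"] = OrfProfile(f"o{i}", counts)
            labels[f"o{i}"] = translated
        pos = [o for o, t in labels.items() if t]
        neg = [o for o, t in labels.items() if not t]
        thr = calibrate_thresholds(
            [compute_periodicity(profiles[o]) for o in pos],
            [compute_pme(profiles[o]) for o in pos],
            coverage_fraction=0.90,
        )
        calls = classify_orfs(
            profiles, pd.Series(10.0, index=sorted(profiles)), thr
        ).set_index("orf_id")
        called = calls["status"] == "translated"
        sensitivity = called[pos].mean()
        specificity = (~called[neg]).mean()
        assert 0.90**2 - 0.03 <= sensitivity <= 0.90 + 0.03
        assert specificity >= 0.95


class TestGeneSummary:
    def test_rank_labels(self, small_sim):
        cfg, annotation, truth = small_sim
        ids = [i.transcript_id for i in annotation.isoforms()]
        tpm = pd.Series(np.linspace(10, 5, len(ids)), index=sorted(ids))
        calls = pd.DataFrame(
            {"orf_id": sorted(ids), "status": "translated"}
        )
        summary = summarize_gene_isoform_status(calls, tpm, annotation)
        for gid, grp in summary.groupby("gene_id"):
            gene = annotation.genes[gid]
            if len(gene.isoforms) == 1:
                assert list(grp["label"]) == ["single"]
            else:
                assert set(grp["label"]) <= {"main", "secondary", "other"}
                assert (grp["label"] == "main").sum() == 1
                top = grp.loc[grp["tpm_rank"] == 1, "transcript_id"].iloc[0]
                assert tpm[top] == max(tpm[t] for t in grp["transcript_id"])

    def test_untranslated_unlabeled(self, small_sim):
        cfg, annotation, truth = small_sim
        ids = sorted(i.transcript_id for i in annotation.isoforms())
        tpm = pd.Series(1.0, index=ids)
        calls = pd.DataFrame({"orf_id": ids, "status": "not_translated"})
        summary = summarize_gene_isoform_status(calls, tpm, annotation)
        assert (summary["label"] == "").all()
        assert (summary["n_translated_in_gene"] == 0).all()
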