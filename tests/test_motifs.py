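"""PWM handling, threshold calibration, scanning, enrichment, deviations."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from multifate import motifs as mot
from multifate import synthetic

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


def enumeration_threshold(scores: np.ndarray, bg: np.ndarray, p: float) -> float:
    """Independent brute-force oracle: enumerate all 4^w words."""
    w = scores.shape[1]
    vals: dict[float, float] = {}
    for word in itertools.product(range(4), repeat=w):
        s = round(sum(scores[b, j] for j, b in enumerate(word)), 10)
        pr = float(np.prod([bg[b] for b in word]))
        vals[s] = vals.get(s, 0.0) + pr
    ks = sorted(vals)
    tail, thr = 0.0, None
    for k in reversed(ks):
        tail += vals[k]
        if tail <= p:
            thr = k
    return ks[-1] + 1e-9 if thr is None else thr


@pytest.fixture(scope="module")
def jaspar_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("motifs") / "motifs.jaspar"
    path.write_text(
        ">MA0001.1 TESTA\n"
        "A [ 10 0 0 5 ]\n"
        "C [ 0 10 0 5 ]\n"
        "G [ 0 0 10 0 ]\n"
        "T [ 0 0 0 0 ]\n"
        ">MA0002.1 TESTB\n"
        "A [ 1 2 3 4 5 ]\n"
        "C [ 4 3 2 1 0 ]\n"
        "G [ 0 0 0 0 0 ]\n"
        "T [ 0 0 0 0 0 ]\n"
    )
    return path


class TestReadWrite:
    def test_jaspar_counts_become_stochastic(self, jaspar_file):
        pwms = mot.read_motifs(jaspar_file, "jaspar")
        assert [p.id for p in pwms] == ["MA0001.1", "MA0002.1"]
        for p in pwms:
            np.testing.assert_allclose(p.probs.sum(axis=0), 1.0, atol=1e-9)

    def test_zero_count_column_uniform(self, tmp_path):
        path = tmp_path / "z.jaspar"
        path.write_text(
            ">Z1 z\nA [ 5 0 5 5 ]\nC [ 5 0 0 0 ]\nG [ 0 0 5 0 ]\nT [ 0 0 0 5 ]\n"
        )
        (pwm,) = mot.read_motifs(path, "jaspar")
        np.testing.assert_allclose(pwm.probs[:, 1], 0.25)

    def test_round_trip(self, jaspar_file, tmp_path):
        pwms = mot.read_motifs(jaspar_file, "jaspar")
        out = tmp_path / "rt.jaspar"
        mot.write_motifs(out, pwms)
        back = mot.read_motifs(out, "jaspar", pseudocount=0.0)
        for a, b in zip(pwms, back):
            np.testing.assert_allclose(a.probs, b.probs, atol=1e-9)

    def test_malformed_width_rejected(self):
        with pytest.raises(ValueError, match="width"):
            mot.PWM(id="w", probs=np.full((4, 2), 0.25))


class TestLogOdds:
    def test_uniform_pwm_uniform_background_zero(self):
        pwm = mot.PWM(id="u", probs=np.full((4, 6), 0.25))
        np.testing.assert_allclose(mot.to_logodds(pwm), 0.0, atol=1e-12)

    def test_deterministic_column_near_log2_four(self):
        probs = np.full((4, 4), 1e-12)
        probs[0] = 1.0 - 3e-12
        pwm = mot.PWM(id="d", probs=probs / probs.sum(0))
        lo = mot.to_logodds(pwm)
        assert lo.max() == pytest.approx(np.log2(4.0), abs=0.05)
        assert np.isfinite(lo).all()

    def test_invalid_background_rejected(self):
        pwm = mot.PWM(id="u", probs=np.full((4, 4), 0.25))
        with pytest.raises(ValueError):
            mot.to_logodds(pwm, np.array([0.5, 0.5, 0.0, 0.0]))


class TestThreshold:
    @pytest.mark.parametrize("gc", [0.5, 0.6])
    def test_matches_enumeration_width3(self, gc):
        rng = np.random.default_rng(42)
        bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        lo = mot.to_logodds(mot.PWM(id="t4", probs=rng.dirichlet(np.ones(4), size=4).T), bg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = mot.pvalue_threshold(lo, bg, p=0.01)
        assert got == pytest.approx(enumeration_threshold(lo, bg, 0.01), abs=1e-9)

    def test_p_equal_one_passes_everything(self):
        rng = np.random.default_rng(1)
        lo = rng.normal(size=(4, 5))
        t = mot.pvalue_threshold(lo, p=1.0)
        assert t <= lo.min(axis=0).sum() + 1e-9

    def test_impossible_p_warns_and_blocks_all(self):
        lo = np.zeros((4, 4))
        lo[0] = 1.0
        with pytest.warns(UserWarning):
            t = mot.pvalue_threshold(lo, p=1e-9)
        assert t > lo.max(axis=0).sum()

    def test_coarser_binning_is_more_conservative(self):
        rng = np.random.default_rng(3)
        pfm = rng.dirichlet(np.ones(4) * 0.4, size=8).T
        lo = mot.to_logodds(mot.PWM(id="b", probs=pfm / pfm.sum(0)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fine = mot.pvalue_threshold(lo, p=1e-3, bin_fraction=1e-3)
            coarse = mot.pvalue_threshold(lo, p=1e-3, bin_fraction=2e-3)
        assert coarse >= fine - 1e-12

    def test_binned_threshold_is_conservative_vs_exact(self):
        rng = np.random.default_rng(4)
        pfm = rng.dirichlet(np.ones(4) * 0.4, size=7).T
        lo = mot.to_logodds(mot.PWM(id="c", probs=pfm / pfm.sum(0)))
        bg = np.full(4, 0.25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            binned = mot.pvalue_threshold(lo, bg, p=1e-3, bin_fraction=1e-3)
        # true tail at the binned threshold must stay below p
        tail = 0.0
        for word in itertools.product(range(4), repeat=7):
            s = sum(lo[b, j] for j, b in enumerate(word))
            if s >= binned:
                tail += 0.25 ** 7
        assert tail <= 1e-3 + 1e-12


class TestScan:
    def test_planted_consensus_recovered(self):
        pfms = synthetic.builtin_motif_pfms()
        pwm = mot.PWM(id="POU2F1_like", probs=pfms["POU2F1_like"])
        lo = mot.to_logodds(pwm)
        thr = mot.pvalue_threshold(lo, p=5e-5)
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 120))
        seq = seq[:17] + "ATGCAAAT" + seq[25:]
        hits = mot.scan({"pk": seq}, lo, thr, "POU2F1_like")
        assert any(h.offset == 17 and h.strand == "+" for h in hits)

    def test_strand_symmetry(self):
        pfms = synthetic.builtin_motif_pfms()
        lo = mot.to_logodds(mot.PWM(id="g", probs=pfms["GATA3_like"]))
        thr = mot.pvalue_threshold(lo, p=5e-5)
        rng = np.random.default_rng(5)
        seqs = {f"p{i}": "".join(rng.choice(list("ACGT"), 300)) for i in range(30)}
        fwd = mot.scan(seqs, lo, thr)
        rc = mot.scan({k: revcomp(v) for k, v in seqs.items()}, lo, thr)
        assert len(fwd) == len(rc)
        flipped = {(h.peak_id, len(seqs[h.peak_id]) - h.offset - 8,
                    "-" if h.strand == "+" else "+") for h in fwd}
        assert flipped == {(h.peak_id, h.offset, h.strand) for h in rc}

    def test_short_sequence_no_hits(self):
        lo = np.zeros((4, 8))
        assert mot.scan({"s": "ACG"}, lo, -1.0) == []

    def test_n_positions_skipped(self):
        lo = np.zeros((4, 4))
        hits = mot.scan({"s": "ACGTNACGT"}, lo, 0.0)
        assert all("N" not in "ACGTNACGT"[h.offset:h.offset + 4] for h in hits)

    def test_background_hit_rate_calibrated(self):
        pfms = synthetic.builtin_motif_pfms()
        pwm = mot.PWM(id="h", probs=pfms["ARE_FOXA1_hybrid"])
        lo = mot.to_logodds(pwm)
        p = 5e-5
        thr = mot.pvalue_threshold(lo, p=p)
        rng = np.random.default_rng(6)
        n_pos = 0
        n_hits = 0
        for i in range(400):
            seq = "".join(rng.choice(list("ACGT"), 2500))
            hits = mot.scan({"s": seq}, lo, thr)
            n_hits += len(hits)
            n_pos += 2 * (2500 - pwm.width + 1)
        assert n_hits / n_pos <= 2 * p


class TestBinomialZ:
    def test_worked_example(self):
        assert mot.binomial_z(100, 30, 0.2) == pytest.approx(2.5, abs=1e-12)

    def test_centered_zero(self):
        assert mot.binomial_z(50, 10, 0.2) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_C(self):
        zs = [mot.binomial_z(100, c, 0.3) for c in range(0, 101)]
        assert (np.diff(zs) > 0).all()

    def test_sqrt2_scaling(self):
        z1 = mot.binomial_z(100, 30, 0.2)
        z2 = mot.binomial_z(200, 60, 0.2)
        assert z2 == pytest.approx(z1 * np.sqrt(2), rel=1e-12)

    def test_invalid_p_rejected(self):
        for bad in (0.0, 1.0):
            with pytest.raises(ValueError):
                mot.binomial_z(10, 5, bad)

    def test_normal_approximation_of_exact_tail(self):
        """Z should approximate the exact binomial upper-tail quantile."""
        from scipy.stats import binom, norm

        N, C, p = 1000, 250, 0.2
        z = mot.binomial_z(N, C, p)
        exact_tail = binom.sf(C - 1, N, p)
        # continuity: Phi(-z) within a factor ~2 of the exact tail
        assert 0.3 < norm.sf(z) / exact_tail < 3.0


class TestClusterEnrichment:
    def _membership(self, rng, n_cluster=100, n_bg=900, cluster_rate=0.6,
                    bg_rate=0.05):
        peaks = [f"p{i}" for i in range(n_cluster + n_bg)]
        memb = pd.DataFrame(False, index=peaks, columns=["m1", "m2"])
        memb.loc[peaks[:n_cluster], "m1"] = rng.random(n_cluster) < cluster_rate
        memb.loc[peaks[n_cluster:], "m1"] = rng.random(n_bg) < bg_rate
        memb["m2"] = rng.random(len(peaks)) < 0.2
        clusters = pd.Series("bg", index=peaks)
        clusters.iloc[:n_cluster] = "c1"
        return memb, clusters

    def test_planted_motif_ranks_first(self):
        wins = 0
        for seed in range(20):
            memb, clusters = self._membership(np.random.default_rng(seed))
            table = mot.cluster_enrichment(memb, clusters)
            top = table[table.cluster_id == "c1"].iloc[0]
            wins += top["motif_id"] == "m1"
        assert wins >= 19

    def test_cluster_equal_background_null(self):
        rng = np.random.default_rng(0)
        peaks = [f"p{i}" for i in range(500)]
        memb = pd.DataFrame(
            rng.random((500, 10)) < 0.3, index=peaks,
            columns=[f"m{j}" for j in range(10)],
        )
        clusters = pd.Series("all", index=peaks)
        table = mot.cluster_enrichment(memb, clusters, background=peaks)
        assert (table["Z"].abs() < 1e-9).all()  # cluster IS the background

    def test_p_zero_flagged(self):
        peaks = ["p0", "p1"]
        memb = pd.DataFrame({"m": [False, False]}, index=peaks)
        clusters = pd.Series("c", index=peaks)
        table = mot.cluster_enrichment(memb, clusters)
        assert table["flagged"].all()
        assert table["Z"].isna().all()

    def test_empty_background_rejected(self):
        memb = pd.DataFrame({"m": [True]}, index=["p0"])
        with pytest.raises(ValueError):
            mot.cluster_enrichment(memb, pd.Series("c", index=["p0"]), background=[])


@pytest.fixture(scope="module")
def planted():
    cfg = synthetic.SimConfig(
        seed=8, n_cells_per_lineage={"basal": 100, "L1": 200, "L2": 100},
        n_genes=120, n_peaks=400, signature_size=15,
    )
    rna, atac, seqs, truth = synthetic.gen_multiome(cfg)
    memb = pd.DataFrame(False, index=list(atac.var_names),
                        columns=list(synthetic.MOTIF_CONSENSUS))
    for pk, m, off, strand in truth.planted_motif_sites:
        memb.loc[pk, m] = True
    rng = np.random.default_rng(0)
    for m in memb.columns:  # sprinkle background membership
        memb.loc[rng.choice(atac.var_names, 20, replace=False), m] = True
    return atac, memb, truth


class TestDeviations:
    def test_planted_lineage_has_top_mean_deviation(self, planted):
        atac, memb, truth = planted
        dev = mot.deviation_scores(atac, memb, n_background=20, seed=0)
        for motif, lineage in [("POU2F1_like", "L1"), ("ARE_canonical", "L2"),
                               ("TRP63_like", "basal")]:
            means = {
                l: dev.z.loc[truth.lineage_labels == l, motif].mean()
                for l in ("basal", "L1", "L2")
            }
            assert max(means, key=means.get) == lineage

    def test_determinism(self, planted):
        atac, memb, truth = planted
        d1 = mot.deviation_scores(atac, memb, n_background=15, seed=3)
        d2 = mot.deviation_scores(atac, memb, n_background=15, seed=3)
        pd.testing.assert_frame_equal(d1.z, d2.z)

    def test_null_model_deviations_centered(self):
        rng = np.random.default_rng(9)
        X = rng.poisson(1.0, size=(2000, 300)).astype(float)
        peaks = [f"p{i}" for i in range(300)]
        memb = pd.DataFrame(
            rng.random((300, 5)) < 0.2, index=peaks,
            columns=[f"m{j}" for j in range(5)],
        )
        dev = mot.deviation_scores(X, memb, n_background=20, seed=0)
        assert np.abs(dev.z.mean(axis=0)).max() < 0.1

    def test_small_motif_excluded(self, planted):
        atac, memb, truth = planted
        memb2 = memb.copy()
        memb2["tiny"] = False
        memb2.iloc[0, -1] = True
        dev = mot.deviation_scores(atac, memb2, n_background=15, seed=0)
        assert "tiny" in dev.excluded
        assert "tiny" not in dev.z.columns


class TestSpearmanSelect:
    def test_planted_pair_selected_anticorrelated_rejected(self, small_multiome):
        cfg, (rna, atac, seqs, truth) = small_multiome
        from multifate import lineage as lin

        memb = pd.DataFrame(False, index=list(atac.var_names),
                            columns=list(synthetic.MOTIF_CONSENSUS))
        for pk, m, off, strand in truth.planted_motif_sites:
            memb.loc[pk, m] = True
        rng = np.random.default_rng(1)
        for m in memb.columns:
            memb.loc[rng.choice(atac.var_names, 15, replace=False), m] = True
        dev = mot.deviation_scores(atac, memb, n_background=15, seed=0)
        expr = pd.DataFrame(lin.normalize_expression(rna.X),
                            index=rna.obs_names, columns=rna.var_names)
        m2g = {"ARE_FOXA1_hybrid": truth.signatures["L1"][0],
               "POU2F1_like": truth.signatures["L1"][1],
               "GATA3_like": truth.signatures["L1"][2],
               "ARE_canonical": truth.signatures["L2"][0],
               "TRP63_like": truth.signatures["basal"][0]}
        table = mot.spearman_select(dev, expr, m2g, seed=0)
        sel = dict(zip(table.motif_id, table.selected))
        assert sel["POU2F1_like"] and sel["ARE_canonical"]
        # anti-correlated pairing: L1 motif against a basal gene
        m2g_bad = dict(m2g)
        m2g_bad["POU2F1_like"] = truth.signatures["basal"][1]
        table2 = mot.spearman_select(dev, expr, m2g_bad, seed=0)
        row = table2[table2.motif_id == "POU2F1_like"].iloc[0]
        assert row["rho"] < 0 and not row["selected"]

    def test_constant_gene_dropped(self, small_multiome):
        cfg, (rna, atac, seqs, truth) = small_multiome
        rng = np.random.default_rng(2)
        memb = pd.DataFrame(
            rng.random((atac.n_vars, 2)) < 0.2, index=list(atac.var_names),
            columns=["mA", "mB"],
        )
        dev = mot.deviation_scores(atac, memb, n_background=12, seed=0)
        expr = pd.DataFrame(
            {"flat": np.zeros(atac.n_obs), "var": rng.normal(size=atac.n_obs)},
            index=list(atac.obs_names),
        )
        table = mot.spearman_select(dev, expr, {"mA": "flat", "mB": "var"}, seed=0)
        assert "mA" not in set(table.motif_id)

    def test_shuffled_expression_rarely_selected(self, small_multiome):
        cfg, (rna, atac, seqs, truth) = small_multiome
        rng = np.random.default_rng(3)
        memb = pd.DataFrame(
            rng.random((atac.n_vars, 8)) < 0.15, index=list(atac.var_names),
            columns=[f"m{j}" for j in range(8)],
        )
        dev = mot.deviation_scores(atac, memb, n_background=12, seed=0)
        n_sel, n_test = 0, 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            expr = pd.DataFrame(
                r.normal(size=(atac.n_obs, 8)), index=list(atac.obs_names),
                columns=[f"g{j}" for j in range(8)],
            )
            table = mot.spearman_select(
                dev, expr, {f"m{j}": f"g{j}" for j in range(8)}, seed=seed)
            n_sel += int(table["selected"].sum())
            n_test += len(table)
        assert n_sel <= 0.05 * n_test + 2
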