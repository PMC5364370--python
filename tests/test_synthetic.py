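import dataclasses

import numpy as np
import pandas as pd
import pytest

from chromcascade import synthetic as synth
from chromcascade.core import MARKS


class TestConfigValidation:
    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="frac_induced"):
            synth.SimulationConfig(frac_induced=1.4)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            synth.SimulationConfig(attenuation_weights=(1.0, 0.5, 0.0, 0.2, 0.1))

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            synth.SimulationConfig(nb_dispersion=-0.1)


class TestSimulateCounts:
    def test_seeded_reproducibility(self, small_config):
        c1, t1 = synth.simulate_counts(small_config)
        c2, t2 = synth.simulate_counts(small_config)
        for mark in small_config.marks:
            pd.testing.assert_frame_equal(c1[mark].counts, c2[mark].counts)
        np.testing.assert_array_equal(t1.base_induction, t2.base_induction)

    def test_different_seed_differs(self, small_config):
        c1, _ = synth.simulate_counts(small_config)
        c2, _ = synth.simulate_counts(small_config.with_seed(99))
        assert not c1[MARKS[0]].counts.equals(c2[MARKS[0]].counts)

    def test_null_config_has_unit_expected_ratio(self, small_config):
        """With frac_induced=0 the expected TPA/rest mean ratio is 1."""
        cfg = dataclasses.replace(small_config, frac_induced=0.0, n_tss=2000)
        counts, truth = synth.simulate_counts(cfg)
        assert (truth.base_induction == 0).all()
        for mark in cfg.marks[:2]:
            cm = counts[mark].select(background="WT")
            rest = cm.condition_mean("FCS", 0)
            stim = cm.condition_mean("TPA", 30)
            d = truth.distortions[mark]
            rest_d = d[[c for c in cm.counts if "FCS0" in c]].mean()
            stim_d = d[[c for c in cm.counts if "TPA30" in c]].mean()
            ratio = (stim.mean() / stim_d) / (rest.mean() / rest_d)
            assert ratio == pytest.approx(1.0, abs=0.02)

    def test_nb_moments_match_planted(self):
        """Monte-Carlo check: per-region replicate means and variances
        follow NB(mu, mu + alpha*mu^2) within MC error."""
        cfg = synth.SimulationConfig(n_tss=5000, nb_dispersion=0.05, seed=3)
        counts, truth = synth.simulate_counts(cfg)
        mark = cfg.marks[0]
        cols = [c for c in counts[mark].counts if c.startswith("WT_FCS0")]
        k = counts[mark].counts[cols].to_numpy(dtype=float)
        d = truth.distortions[mark][cols].to_numpy()
        mu = truth.base_mean[:, None] * d[None, :]
        z = (k - mu) / np.sqrt(mu + cfg.nb_dispersion * mu**2)
        # standardized residuals: mean 0 within 3 MC standard errors
        se = 1.0 / np.sqrt(z.size)
        assert abs(z.mean()) < 3 * se * 1.5
        assert z.std() == pytest.approx(1.0, abs=0.05)

    def test_nested_mark_ordering_invariant(self, small_sim):
        """Planted per-mark log2 FCs are non-increasing along the mark
        order for every induced region and every background."""
        _, truth = small_sim
        for bg in ("WT", "TKO", "TKO+Elk1"):
            lfc = truth.mark_log2fc(bg, time=30.0)
            assert (np.diff(lfc, axis=1) <= 1e-12).all()

    def test_dependent_regions_flat_in_tko(self, small_sim):
        _, truth = small_sim
        dep_mask = np.isin(truth.dependence_class,
                           ("dependent-not-restored", "restored-any-Elk1",
                            "restored-requires-phospho+FW"))
        lfc_tko = truth.mark_log2fc("TKO", time=30.0)
        assert np.all(lfc_tko[dep_mask] == 0.0)

    def test_planted_class_fractions(self):
        cfg = synth.SimulationConfig(n_tss=4000, seed=5)
        _, truth = synth.simulate_counts(cfg)
        cls = pd.Series(truth.dependence_class)
        induced = cls != "none"
        assert induced.mean() == pytest.approx(cfg.frac_induced, abs=0.01)
        dep = cls.isin(["dependent-not-restored", "restored-any-Elk1",
                        "restored-requires-phospho+FW"])
        assert (dep.sum() / induced.sum()) == pytest.approx(0.8, abs=0.01)
        restored = cls.isin(["restored-any-Elk1", "restored-requires-phospho+FW"])
        assert (restored.sum() / dep.sum()) == pytest.approx(0.6, abs=0.01)
        assert ((cls == "restored-requires-phospho+FW").sum()
                / restored.sum()) == pytest.approx(0.9, abs=0.01)


class TestSimulateRna:
    def test_invariant_genes_satisfy_selection_criteria(self, small_sim):
        _, truth = small_sim
        intronic, _ = synth.simulate_rna(truth)
        inv_counts = intronic.counts.loc[truth.gene_ids[truth.invariant]]
        assert (inv_counts.mean(axis=1) >= 6).all()
        assert (truth.rna_log2fc[truth.invariant] == 0).all()

    def test_intronless_genes_have_zero_intronic_reads(self, small_sim):
        _, truth = small_sim
        intronic, orf = synth.simulate_rna(truth)
        no_intron = truth.gene_ids[~truth.has_intron]
        assert (intronic.counts.loc[no_intron] == 0).all().all()
        assert (orf.counts.loc[no_intron].sum(axis=1) > 0).all()

    def test_noise_free_single_mark_coupling(self, small_config):
        """With zero coupling noise and beta=1 on one mark only, the
        planted RNA log2 FC equals that mark's planted log2 FC."""
        cfg = dataclasses.replace(
            small_config,
            rna_coupling=synth.RnaCoupling(betas=(0, 0, 0, 0, 1.0), noise_sd=0.0))
        _, truth = synth.simulate_counts(cfg)
        lfc = truth.mark_log2fc("WT", 30.0)[:, 4]
        keep = ~truth.invariant
        np.testing.assert_allclose(truth.rna_log2fc[keep], lfc[keep])


class TestSimulateCoverage:
    def test_no_induction_tracks_identical(self, small_config):
        cfg = dataclasses.replace(small_config, frac_induced=0.0)
        _, truth = synth.simulate_counts(cfg)
        tracks, _ = synth.simulate_coverage(truth)
        m = cfg.marks[0]
        np.testing.assert_allclose(tracks[f"{m}_t0"]["chr1"], tracks[f"{m}_t30"]["chr1"])

    def test_gain_integral_matches_planted_induction(self, small_sim):
        """Window integral of (stimulated − resting) equals the planted
        linear induction times the resting integral, within discretization."""
        counts, truth = small_sim
        cfg = truth.config
        tracks, anchors = synth.simulate_coverage(truth)
        mark, mi = cfg.marks[-1], len(cfg.marks) - 1
        rest = tracks[f"{mark}_t0"]["chr1"]
        stim = tracks[f"{mark}_t30"]["chr1"]
        flank = 3000
        for k in (0, 1, 5):
            lo = anchors[k].tss_position - flank
            hi = anchors[k].tss_position + flank + 1
            mult = 2.0 ** truth.mark_log2fc("WT", 30.0)[k, mi]
            gain = stim[lo:hi].sum() - rest[lo:hi].sum()
            assert gain == pytest.approx((mult - 1.0) * rest[lo:hi].sum(), rel=0.01, abs=1e-9)

    def test_minus_strand_skew_mirrored(self, small_sim):
        """The late K4me3-like downstream skew lands on the genomic left
        for minus-strand anchors."""
        _, truth = small_sim
        cfg = truth.config
        tracks, anchors = synth.simulate_coverage(truth)
        mark, mi = cfg.marks[-1], len(cfg.marks) - 1
        rest, stim = tracks[f"{mark}_t0"]["chr1"], tracks[f"{mark}_t30"]["chr1"]
        lfc = truth.mark_log2fc("WT", 30.0)[:, mi]
        for k, anchor in enumerate(anchors):
            if lfc[k] <= 0.3:
                continue
            p = anchor.tss_position
            left = (stim[p - 3000:p] - rest[p - 3000:p]).sum()
            right = (stim[p + 1:p + 3001] - rest[p + 1:p + 3001]).sum()
            if anchor.strand == "+":
                assert right > left
            else:
                assert left > right


class TestRemoteSites:
    def test_all_sites_far_from_tss(self, small_config):
        remote = synth.simulate_remote_sites(small_config)
        regions = synth.make_tss_regions(small_config)
        tss_by_chrom = {}
        for r in regions:
            tss_by_chrom.setdefault(r.chrom, []).append(r.tss_position)
        for s in remote.sites:
            positions = np.asarray(tss_by_chrom.get(s.chrom, [np.inf]))
            assert np.abs(positions - s.summit).min() > 2000

    def test_zero_hic_links_gives_distance_only_targets(self, small_config):
        cfg = dataclasses.replace(small_config, n_hic_links=0)
        remote = synth.simulate_remote_sites(cfg)
        assert remote.links == [] and not remote.hic_linked.any()

    def test_seeded_reproducibility(self, small_config):
        r1 = synth.simulate_remote_sites(small_config)
        r2 = synth.simulate_remote_sites(small_config)
        assert [s.summit for s in r1.sites] == [s.summit for s in r2.sites]
        np.testing.assert_array_equal(r1.site_has_srf, r2.site_has_srf)


def test_analytic_weight_calibration_hits_targets():
    """The population-DI inversion reproduces its own targets."""
    rng = np.random.default_rng(0)
    w = synth.calibrate_attenuation_weights((13.0, 30.0, 34.0, 47.0), n_mc=200_000)
    g = rng.gamma(2.0, 0.30, 400_000)
    f = np.exp2(g)
    for wj, target in zip(w[1:], (13.0, 30.0, 34.0, 47.0)):
        di = 100 * (f.mean() - np.exp2(wj * g).mean())
        assert di == pytest.approx(target, abs=1.0)
    assert all(a > b for a, b in zip(w, w[1:]))
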