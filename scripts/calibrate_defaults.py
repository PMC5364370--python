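"""Calibrate generator defaults against their documented operating points.

Two calibrations, both prescribed properties of the default study
conditions rather than free parameters:

1. attenuation weights — chosen so the Distance-Index ladder measured by
   the full analysis (leading mark first) on the default simulation
   approximates 13/30/34/47 percentage points.  The analytic population
   inverse (``calibrate_attenuation_weights``) seeds a fixed-point
   iteration against the pipeline-measured ladder, which includes
   detection selection and measurement noise.
2. RNA coupling noise SD — chosen so the 5-mark log-log fit on the
   default simulation lands at adjusted R^2 ~ 0.40.

Run from the repository root:  python scripts/calibrate_defaults.py
The printed values are frozen into chromcascade.synthetic defaults.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize

from chromcascade import synthetic as s
from chromcascade import hierarchy as hier
from chromcascade import normalization as norm
from chromcascade import differential as diff
from chromcascade import regression as regr
from chromcascade.pipeline import tss_differential

TARGET_DI = (13.0, 30.0, 34.0, 47.0)
TARGET_R2 = 0.40


def measured_state(cfg: s.SimulationConfig):
    """One pipeline pass: method-1 factors, TSS calling, DI ladder on the
    significant set, plus the pieces the R^2 calibration needs."""
    counts, truth = s.simulate_counts(cfg)
    intr, orf = s.simulate_rna(truth)
    inv = norm.select_invariant_genes(intr, diff.nb_exact_test_many,
                                      dispersion=cfg.nb_dispersion)
    g2r = dict(zip(truth.gene_ids, truth.region_ids))
    invr = pd.Index([g2r[g] for g in inv])
    factors = {m: norm.scaling_method1(counts[m], invr, "WT_FCS0_r1").factors
               for m in cfg.marks}
    res = tss_differential(counts, factors)
    sig_any = pd.DataFrame({m: r["significant"] for m, r in res.items()}).any(axis=1)
    normalized = {m: counts[m].scaled(factors[m]) for m in cfg.marks}
    fc = hier.compute_fold_changes(normalized, background="WT").loc[sig_any]
    di_row, _ = hier.distance_index(fc, cfg.marks[0])
    rna = regr.rna_fold_change(intr.counts, orf.counts,
                               ["WT_FCS0_r1", "WT_FCS0_r2"],
                               ["WT_TPA30_r1", "WT_TPA30_r2"])
    rna_fold = rna["fold_change"].rename(index=g2r)
    common = fc.index.intersection(rna_fold.index)
    model = regr.loglog_fit(rna_fold.loc[common], fc.loc[common])
    return di_row[list(cfg.marks[1:])].to_numpy(), model.adj_r_squared


def analytic_di(w: float, g: np.ndarray) -> float:
    f = np.exp2(g)
    return 100.0 * (f.mean() - np.exp2(w * g).mean())


def calibrate_weights(min_margin: float = 0.04, n_verify_seeds: int = 3):
    """Joint calibration: the weights must reproduce the DI ladder *and*
    the two-subcluster geometry.

    Under single-linkage Euclidean clustering the planted subclusters
    {marks 1,2} and {marks 3,4,5} exist only when the weight gap between
    marks 2 and 3 exceeds both the gap inside the pair and the largest
    chain link inside the triple, with margin to spare against
    measurement noise.  A DI-only inversion can violate this (the ladder's
    last step forces mark 5 far from mark 4), so the search minimizes the
    analytic-DI error subject to the margin constraints, then verifies
    the measured ladder on full pipeline runs.
    """
    rng = np.random.default_rng(2024)
    base_cfg = s.SimulationConfig()
    g = rng.gamma(base_cfg.induction_shape, base_cfg.induction_scale, size=500_000)
    targets = np.asarray(TARGET_DI)

    best, best_key = None, None
    for w2 in np.arange(0.82, 0.91, 0.01):
        for w3 in np.arange(0.52, 0.68, 0.01):
            for w4 in np.arange(w3 - 0.08, w3 - 0.009, 0.01):
                for w5 in np.arange(0.28, 0.46, 0.01):
                    gap23, gap45, gap12 = w2 - w3, w4 - w5, 1.0 - w2
                    margin = min(gap23 - gap45, gap23 - gap12)
                    if margin <= min_margin or w4 <= w5:
                        continue
                    di = np.array([analytic_di(w, g) for w in (w2, w3, w4, w5)])
                    err = float(np.abs(di - targets).max())
                    key = (min(margin, 0.10), -err)
                    if best_key is None or key > best_key:
                        best, best_key = (1.0, round(w2, 3), round(w3, 3),
                                          round(w4, 3), round(w5, 3)), key
    print(f"constrained weights: {best} "
          f"(margin {best_key[0]:.3f}, analytic DI err {-best_key[1]:.1f})")

    cfg = dataclasses.replace(base_cfg, attenuation_weights=best)
    di = np.mean([measured_state(dataclasses.replace(cfg, seed=100 + k))[0]
                  for k in range(n_verify_seeds)], axis=0)
    print(f"measured DI ladder at these weights: {np.round(di, 1)}")
    return best


def calibrate_noise_sd(weights, n_seeds: int = 3):
    def mean_r2(sd: float) -> float:
        vals = []
        for k in range(n_seeds):
            cfg = dataclasses.replace(
                s.SimulationConfig(), attenuation_weights=weights, seed=200 + k,
                rna_coupling=s.RnaCoupling(noise_sd=sd))
            vals.append(measured_state(cfg)[1])
        return float(np.mean(vals))

    lo, hi = 0.05, 1.2
    if mean_r2(lo) < TARGET_R2:
        return lo, mean_r2(lo)
    sd = optimize.brentq(lambda x: mean_r2(x) - TARGET_R2, lo, hi, xtol=0.01)
    return float(np.round(sd, 2)), mean_r2(sd)


if __name__ == "__main__":
    weights = calibrate_weights()
    print("calibrated attenuation weights:", weights)
    sd, r2 = calibrate_noise_sd(weights)
    print(f"calibrated RNA noise SD: {sd} (mean adjusted R^2 {r2:.3f})")
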