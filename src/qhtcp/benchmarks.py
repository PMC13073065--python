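"""Recovery and calibration studies over the synthetic screen generator.

Each study runs the full pipeline on generated data with known truth and
returns summary statistics; they back both the test suite and the
reproduction script. Problem sizes are chosen so a study completes in
seconds to a couple of minutes on one core.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import clustering, enrichment
from .dose import FourPLParams, _HillInc, fit_4pl, window_summary, zip_surface
from .growth import LogisticParams, fit_growth_curve, fit_screen, logistic_eval, qc_arrays
from .interactions import score_screen
from .simulate import (
    ScreenSimConfig,
    interaction_recovery,
    null_adjusted_stats,
    simulate_dose_matrix,
    simulate_screen,
)


def logistic_analytics() -> dict:
    """Closed-form checks of the logistic growth model.

    G(L) must equal K/2 and the maximum slope of a densely sampled
    noiseless curve must match the analytic r*K/4 attained at t = L.
    """
    p = LogisticParams(K=150.0, r=0.2, L=40.0)
    half = float(logistic_eval(p, p.L))
    t = np.linspace(0.0, 120.0, 200001)
    g = logistic_eval(p, t)
    slope = np.diff(g) / np.diff(t)
    i = int(np.argmax(slope))
    return {
        "half_capacity_at_L": half,
        "half_capacity_rel_err": abs(half - p.K / 2) / (p.K / 2),
        "max_slope_rel_err": abs(slope[i] - p.r * p.K / 4) / (p.r * p.K / 4),
        "argmax_time_err_h": abs(t[i] - p.L),
    }


def cpp_recovery_study(seed: int, n_curves: int = 500, noise_cv: float = 0.02) -> dict:
    """Median CPP recovery error over seeded noisy logistic curves.

    Curves span K in [50, 200], r in [0.05, 0.3], L in [20, 80] at the
    3.5 h cadence over 120 h with Gaussian noise of ``noise_cv``*K.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 120.1, 3.5)
    errs_k, errs_l = [], []
    for _ in range(n_curves):
        K = rng.uniform(50, 200)
        r = rng.uniform(0.05, 0.3)
        L = rng.uniform(20, 80)
        y = logistic_eval(LogisticParams(K, r, L), t)
        yn = np.maximum(y + rng.normal(0, noise_cv * K, t.size), 0.0)
        res = fit_growth_curve((t, yn))
        if res.ok:
            errs_k.append(abs(res.params.K - K) / K)
            errs_l.append(abs(res.params.L - L) / L)
    return {
        "n": len(errs_k),
        "median_rel_err_K": float(np.median(errs_k)),
        "median_rel_err_L": float(np.median(errs_l)),
    }


def _run_screen(config: ScreenSimConfig):
    screen = simulate_screen(config)
    fits = fit_screen(screen.series)
    qc = qc_arrays(fits)
    table = score_screen(fits, screen.design, screen.layouts, qc)
    return screen, table


def null_calibration_study(seeds: tuple[int, ...], n_genes: int = 500) -> dict:
    """Null-screen calibration of adjusted z-scores (no planted interactions)."""
    vals = []
    for seed in seeds:
        cfg = ScreenSimConfig(
            n_genes=n_genes, frac_enhancer=0.0, frac_suppressor=0.0, seed=seed
        )
        _, table = _run_screen(cfg)
        cols = [c for c in table.columns if c.startswith(("adjK", "adjL"))]
        v = table[cols].to_numpy(dtype=float).ravel()
        vals.append(v[np.isfinite(v)])
    pooled = np.concatenate(vals)
    return {
        "n": int(pooled.size),
        "median": float(np.median(pooled)),
        "sd": float(np.std(pooled, ddof=1)),
        "frac_abs_below_3": float(np.mean(np.abs(pooled) < 3.0)),
    }


def planted_recovery_study(seeds: tuple[int, ...], n_genes: int = 384) -> dict:
    """Sensitivity / FPR / truth correlation for planted interactions."""
    tp = fn = fp = tn = 0
    rs = []
    for seed in seeds:
        screen, table = _run_screen(ScreenSimConfig(n_genes=n_genes, seed=seed))
        rec = interaction_recovery(table, screen.truth)
        tp += rec["sensitivity"] * rec["n_planted"]
        fn += (1 - rec["sensitivity"]) * rec["n_planted"]
        fp += rec["fpr"] * rec["n_null"]
        tn += (1 - rec["fpr"]) * rec["n_null"]
        rs.append(rec["pearson_r"])
    return {
        "n": int(tp + fn + fp + tn),
        "sensitivity": float(tp / (tp + fn)),
        "fpr": float(fp / (fp + tn)),
        "pearson_r": float(np.mean(rs)),
    }


def planted_cluster_matrix(seed: int, n: int = 400, k: int = 5, sep: float = 6.0):
    """Gaussian planted-partition profile matrix with centroid separation >= sep."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 5, (k, 4))
    while True:
        d = np.linalg.norm(centers[:, None] - centers[None], axis=2)
        bad = np.where((d < sep) & (d > 0))
        if bad[0].size == 0:
            break
        centers[bad[0][0]] += rng.normal(0, 3, 4)
    labels = rng.integers(0, k, n)
    X = centers[labels] + rng.normal(0, 1, (n, 4))
    matrix = clustering.ProfileMatrix(
        pd.DataFrame(X, columns=clustering.FEATURE_COLUMNS), None
    )
    return matrix, labels


def bic_benchmark(seeds: tuple[int, ...]) -> dict:
    """Planted 5-cluster recovery plus the single-Gaussian control."""
    hits = 0
    aris = []
    for seed in seeds:
        matrix, labels = planted_cluster_matrix(seed)
        tree = clustering.hierarchical_cluster(matrix)
        assignment = clustering.bic_cut(tree, matrix)
        hits += assignment.k == 5
        aris.append(adjusted_rand_score(labels, assignment.labels.to_numpy()))
    rng = np.random.default_rng(seeds[0])
    X = rng.normal(0, 1, (300, 4))
    control = clustering.ProfileMatrix(
        pd.DataFrame(X, columns=clustering.FEATURE_COLUMNS), None
    )
    k_control = clustering.bic_cut(
        clustering.hierarchical_cluster(control), control
    ).k
    return {
        "n": len(seeds),
        "frac_k_correct": hits / len(seeds),
        "mean_ari": float(np.mean(aris)),
        "min_ari": float(np.min(aris)),
        "control_k": int(k_control),
    }


def enrichment_null_study(seeds: tuple[int, ...], n_genes: int = 500,
                          n_clusters: int = 10, n_terms: int = 150) -> dict:
    """Type-I calibration: random annotations on random clusters.

    Reports the fraction of (cluster, term) tests reaching q < 0.05; under
    the null this stays at or below the nominal level.
    """
    total = hits = 0
    genes = [f"G{i:04d}" for i in range(n_genes)]
    background = set(genes)
    for seed in seeds:
        rng = np.random.default_rng(seed)
        terms = {
            f"T{j:04d}": set(rng.choice(genes, size=int(rng.integers(5, 61)),
                                        replace=False))
            for j in range(n_terms)
        }
        ann = enrichment.AnnotationSet(terms=terms)
        labels = rng.integers(0, n_clusters, n_genes)
        clusters = {
            int(c) + 1: {genes[i] for i in np.where(labels == c)[0]}
            for c in range(n_clusters)
        }
        res = enrichment.enrich_clusters(clusters, background, ann)
        total += len(res)
        hits += int((res["q"] < 0.05).sum())
    return {"n": total, "frac_q_below_05": hits / total}


ZIP_DOSES_A = 10 * 2.0 ** np.arange(-2, 4)
ZIP_DOSES_B = 1 * 2.0 ** np.arange(-2, 4)


def zip_null_study(hills: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)) -> dict:
    """Max |delta| over noiseless Bliss-consistent matrices across hill slopes."""
    worst = 0.0
    worst_summary = 0.0
    n = 0
    for ha in hills:
        for hb in hills:
            m = simulate_dose_matrix(
                _HillInc(0, 0.9, ha, 10.0), _HillInc(0, 0.8, hb, 1.0),
                ZIP_DOSES_A, ZIP_DOSES_B,
            )
            surface = zip_surface(m)
            worst = max(worst, float(np.abs(surface.delta.to_numpy()).max()))
            worst_summary = max(worst_summary, abs(surface.summary))
            n += 1
    return {"n": n, "max_abs_delta": worst, "max_abs_summary": worst_summary}


def zip_planted_window_study(seed: int, magnitude: float = 15.0,
                             noise_sd: float = 1.0, n_replicates: int = 3) -> dict:
    """Recovery of a planted 3x3 synergy block from replicate-averaged matrices.

    The block sits in the sub-EC50 quadrant of 6-dose two-fold ladders,
    where the zero-interaction expectation is far from its ceiling, and
    the scored matrix is the mean of ``n_replicates`` noisy replicates as
    in a triplicate assay.
    """
    pa = _HillInc(0, 0.9, 2.0, 10.0)
    pb = _HillInc(0, 0.8, 2.0, 1.0)
    doses_a = 10 * 2.0 ** np.arange(-2, 4)
    doses_b = 1 * 2.0 ** np.arange(-2, 4)
    ds = np.zeros((6, 6))
    ds[0:3, 0:3] = magnitude
    reps = [
        simulate_dose_matrix(pa, pb, doses_a, doses_b, delta_surface=ds,
                             noise_sd=noise_sd, seed=seed * 100 + j)
        for j in range(n_replicates)
    ]
    surface = zip_surface(sum(reps) / n_replicates)
    best = window_summary(surface)
    return {
        "n": n_replicates,
        "located": best["row_start"] == 0 and best["col_start"] == 0,
        "window_mean_delta": best["mean_delta"],
        "summary_delta": surface.summary,
        "planted": magnitude,
    }


def ic50_recovery_study(seed: int, noise_sd: float = 0.03,
                        n_replicates: int = 3) -> dict:
    """4PL IC50 recovery for a wild-type-like and a drug-sensitized strain.

    True endpoint dose-responses use IC50s of 6.9 and 2.3 ug/mL over a
    two-fold ladder, read in triplicate with additive absorbance noise.
    """
    rng = np.random.default_rng(seed)
    ladder = np.array([0, 0.3125, 0.625, 1.25, 2.5, 5, 10, 20, 40, 80.0])
    out = {}
    for label, ec50 in (("wildtype", 6.9), ("sensitized", 2.3)):
        # background-subtracted absorbance: bottom 0, so IC50 = EC50
        truth = FourPLParams(bottom=0.0, top=1.0, hill=2.0, ec50=ec50)
        x = np.tile(ladder, n_replicates)
        y = truth(x) + rng.normal(0, noise_sd, x.size)
        fit = fit_4pl(x, y)
        out[label] = {"ic50": fit.ic50, "true_ic50": truth.ic50}
    out["n"] = n_replicates * ladder.size
    return out
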