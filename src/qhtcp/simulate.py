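"""Seeded generators for synthetic screens, annotations, and dose matrices.

The screen generator emulates the statistical structure the analysis
assumes: 384-spot deletion arrays replicated at 0/10/20 ug/mL drug with
matched reference arrays, per-gene baseline fitness effects on K and L,
planted gene-drug interactions expressed in reference-SD units, plate-level
batch effects, and imaging every 3.5 h over 120 h.

Spot noise is split into a *shared* lineage component (the same source
culture is pinned to every condition plate, so inoculum variation travels
with the strain across conditions) and an *independent* per-spot
component. Only the independent part survives the z-score subtraction
``z_drug - z_nodrug``, so the shared:independent ratio sets the null
adjusted-z spread; the default ratio 1.4 yields a null adjusted-z SD of
about 0.82 while the per-condition z-scores keep unit spread.

Everything is deterministic under the mandatory seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .enrichment import AnnotationSet
from .growth import LogisticParams, logistic_eval
from .plate_io import (
    N_COLS,
    N_POSITIONS,
    N_ROWS,
    PlateLayout,
    ScreenDesign,
    SpotTimeSeries,
)

REFERENCE_STRAIN = "REF"
EMPTY = "EMPTY"


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class ScreenSimConfig:
    """Study conditions for a synthetic screen.

    Effect magnitudes for planted interactions are in reference-SD units
    (the unit of the downstream z-scores); baseline defects are relative
    (K) and additive hours (L). Noise defaults make fitted L more precise
    than fitted r at the 3.5 h cadence, as expected of spot-array imaging.
    """

    n_genes: int = 500
    concentrations: tuple[float, ...] = (0.0, 10.0, 20.0)
    # baseline fitness effects: exponential tails, most defects mild
    frac_fitness_defect: float = 0.30
    defect_k_scale: float = 0.06    # mean relative K loss of a defective gene
    defect_k_max: float = 0.35
    defect_l_scale: float = 3.0     # mean L delay (h) of a defective gene
    defect_l_max: float = 12.0
    # planted interactions
    frac_enhancer: float = 0.05
    frac_suppressor: float = 0.05
    interaction_sd_range: tuple[float, float] = (4.0, 10.0)
    frac_duplicate: float = 0.0
    # shared drug response of the reference strain
    drug_k_factor: tuple[float, ...] = (1.0, 0.9, 0.8)
    drug_l_shift: tuple[float, ...] = (0.0, 5.0, 10.0)
    # plate batch effects
    batch_k_cv: float = 0.01
    batch_l_sd: float = 1.0
    # spot-level biological noise: shared across conditions vs independent
    spot_k_cv_shared: float = 0.0260
    spot_k_cv_indep: float = 0.0183
    spot_l_sd_shared: float = 0.715
    spot_l_sd_indep: float = 0.49
    # observation noise
    noise_mult_sd: float = 0.01
    noise_add_sd: float = 1.5
    frac_dropout: float = 0.005
    # sampling
    cadence_h: float = 3.5
    horizon_h: float = 120.0
    cadence_jitter_h: float = 0.0
    # reference strain truth
    K0: float = 150.0
    r0: float = 0.18
    L0: float = 40.0
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_fitness_defect": self.frac_fitness_defect,
            "frac_enhancer": self.frac_enhancer,
            "frac_suppressor": self.frac_suppressor,
            "frac_duplicate": self.frac_duplicate,
            "frac_dropout": self.frac_dropout,
        }
        for key, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{key} must be in [0, 1], got {v}")
        if self.frac_enhancer + self.frac_suppressor > 1.0:
            raise ConfigError("effect-class fractions must sum to <= 1")
        if len(self.drug_k_factor) != len(self.concentrations) or len(
            self.drug_l_shift
        ) != len(self.concentrations):
            raise ConfigError("drug response vectors must match the concentration ladder")
        if self.concentrations[0] != 0.0:
            raise ConfigError("concentration index 1 must be 0 (untreated)")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")

    @property
    def sigma_l_nominal(self) -> float:
        return math.hypot(self.spot_l_sd_shared, self.spot_l_sd_indep)

    def sigma_k_nominal(self, conc_index: int) -> float:
        cv = math.hypot(self.spot_k_cv_shared, self.spot_k_cv_indep)
        return self.K0 * self.drug_k_factor[conc_index - 1] * cv


@dataclass
class GroundTruth:
    """Planted truth tables consistent with the emitted time series."""

    genes: pd.DataFrame         # gene, defect_dk, defect_dl, class, magnitude_sd
    interactions: pd.DataFrame  # gene, conc_index, class, k_effect_sd, l_effect_sd
    entries: pd.DataFrame       # entry, gene, array, row, col, duplicate
    plates: pd.DataFrame        # plate, batch_k, batch_l

    def planted_genes(self, klass: str) -> list[str]:
        return list(self.genes.loc[self.genes["class"] == klass, "gene"])


@dataclass
class SimulatedScreen:
    series: list[SpotTimeSeries]
    layouts: dict[str, PlateLayout]
    design: ScreenDesign
    truth: GroundTruth
    config: ScreenSimConfig


def simulate_growth_curve(
    params: LogisticParams,
    times: np.ndarray,
    rng: np.random.Generator,
    mult_sd: float = 0.0,
    add_sd: float = 0.0,
) -> np.ndarray:
    """Noisy logistic observations: G(t) * exp(eps_mult) + eps_add, >= 0."""
    g = logistic_eval(params, times)
    y = g * np.exp(rng.normal(0.0, mult_sd, times.size)) if mult_sd > 0 else g.copy()
    if add_sd > 0:
        y = y + rng.normal(0.0, add_sd, times.size)
    return np.maximum(y, 0.0)


def _assign_entries(config: ScreenSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    n_dup = int(round(config.frac_duplicate * config.n_genes))
    dup_genes = list(rng.choice(genes, size=n_dup, replace=False)) if n_dup else []
    slots = [(g, False) for g in genes] + [(g, True) for g in dup_genes]
    n_arrays = max(1, math.ceil(len(slots) / N_POSITIONS))
    rows = []
    for i, (gene, is_dup) in enumerate(slots):
        p, within = divmod(i, N_POSITIONS)
        r, c = divmod(within, N_COLS)
        array_id = f"arr{p + 1:02d}"
        rows.append(
            {
                "entry": f"{gene}@{array_id}:{r + 1}.{c + 1}",
                "gene": gene,
                "array": array_id,
                "row": r + 1,
                "col": c + 1,
                "duplicate": is_dup,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_arrays"] = n_arrays
    return df


def _plant_effects(
    config: ScreenSimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    n = len(genes)
    perm = rng.permutation(n)
    n_enh = int(round(config.frac_enhancer * n))
    n_sup = int(round(config.frac_suppressor * n))
    klass = np.array(["none"] * n, dtype=object)
    klass[perm[:n_enh]] = "enhancer"
    klass[perm[n_enh : n_enh + n_sup]] = "suppressor"

    has_defect = rng.random(n) < config.frac_fitness_defect
    dk = np.where(
        has_defect,
        -np.minimum(rng.exponential(config.defect_k_scale, n), config.defect_k_max),
        0.0,
    )
    dl = np.where(
        has_defect,
        np.minimum(rng.exponential(config.defect_l_scale, n), config.defect_l_max),
        0.0,
    )
    mag = np.where(klass != "none", rng.uniform(*config.interaction_sd_range, n), 0.0)

    genes_df = pd.DataFrame(
        {"gene": genes, "defect_dk": dk, "defect_dl": dl, "class": klass, "magnitude_sd": mag}
    )
    c_max = max(config.concentrations)
    rows = []
    for g, kl, m in zip(genes, klass, mag):
        for ci, conc in enumerate(config.concentrations, start=1):
            if ci == 1 or kl == "none":
                k_eff = l_eff = 0.0
            else:
                scale = conc / c_max
                sign = -1.0 if kl == "enhancer" else 1.0
                k_eff = sign * m * scale
                l_eff = -sign * m * scale
            rows.append(
                {"gene": g, "conc_index": ci, "class": kl if k_eff or l_eff else "none",
                 "k_effect_sd": k_eff, "l_effect_sd": l_eff}
            )
    return genes_df, pd.DataFrame(rows)


def simulate_screen(config: ScreenSimConfig) -> SimulatedScreen:
    """Generate a complete synthetic screen with known ground truth.

    Each spot's true logistic parameters are composed as

        K = K0 (1 + dK_g) drugK(c) (1 + batch) (1 + eps_shared + eps_indep)
            + interaction_K(g, c) * sigmaK_nominal(c)
        L = L0 + dL_g + drugL(c) + batch_L + eps_shared + eps_indep
            + interaction_L(g, c) * sigmaL_nominal

    and intensities are logistic evaluations on the cadence grid with
    multiplicative-lognormal plus additive-Gaussian noise. Reference
    arrays use the same machinery with all gene effects zeroed. Identical
    config and seed give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    entries = _assign_entries(config, rng)
    genes_df, inter_df = _plant_effects(config, rng)
    n_arrays = entries.attrs["n_arrays"]
    n_cond = len(config.concentrations)

    gene_defect = genes_df.set_index("gene")[["defect_dk", "defect_dl"]]
    inter_lookup = inter_df.set_index(["gene", "conc_index"])[["k_effect_sd", "l_effect_sd"]]

    # shared lineage noise per entry
    ent_shared_k = rng.normal(0.0, config.spot_k_cv_shared, len(entries))
    ent_shared_l = rng.normal(0.0, config.spot_l_sd_shared, len(entries))

    manifest_rows = []
    plate_rows = []
    layouts: dict[str, PlateLayout] = {}
    series: list[SpotTimeSeries] = []
    base_times = np.arange(0.0, config.horizon_h + 1e-9, config.cadence_h)

    entry_by_array: dict[str, pd.DataFrame] = {
        a: g for a, g in entries.groupby("array", sort=True)
    }

    for p in range(1, n_arrays + 1):
        array_id = f"arr{p:02d}"
        arr_entries = entry_by_array.get(array_id, entries.iloc[0:0])
        occupied = {
            (int(r.row), int(r.col)): (r.gene, "deletion") for r in arr_entries.itertuples()
        }
        del_positions = {
            (r, c): occupied.get((r, c), (EMPTY, "empty"))
            for r in range(1, N_ROWS + 1)
            for c in range(1, N_COLS + 1)
        }
        ref_positions = {
            (r, c): (REFERENCE_STRAIN, "reference")
            for r in range(1, N_ROWS + 1)
            for c in range(1, N_COLS + 1)
        }
        for ci, conc in enumerate(config.concentrations, start=1):
            del_plate = f"{array_id}-c{ci}"
            ref_plate = f"ref{p:02d}-c{ci}"
            layouts[del_plate] = PlateLayout(del_plate, dict(del_positions))
            layouts[ref_plate] = PlateLayout(ref_plate, dict(ref_positions))
            manifest_rows.append(
                {
                    "array_id": array_id,
                    "condition_ugml": conc,
                    "deletion_plate": del_plate,
                    "reference_plate": ref_plate,
                }
            )
            for plate in (del_plate, ref_plate):
                plate_rows.append(
                    {
                        "plate": plate,
                        "batch_k": rng.normal(0.0, config.batch_k_cv),
                        "batch_l": rng.normal(0.0, config.batch_l_sd),
                    }
                )

    plates_df = pd.DataFrame(plate_rows).set_index("plate")
    sigma_l_nom = config.sigma_l_nominal

    def spot_series(
        plate: str, r: int, c: int, strain: str, conc: float, ci: int,
        k_true: float, l_true: float,
    ) -> SpotTimeSeries:
        times = base_times
        if config.cadence_jitter_h > 0:
            times = np.sort(
                np.clip(
                    base_times + rng.uniform(
                        -config.cadence_jitter_h, config.cadence_jitter_h, base_times.size
                    ),
                    0.0,
                    None,
                )
            )
            times = np.maximum.accumulate(times + np.arange(times.size) * 1e-6)
        if rng.random() < config.frac_dropout:
            y = np.maximum(rng.normal(1.0, max(config.noise_add_sd, 0.1), times.size), 0.0)
        else:
            params = LogisticParams(
                K=max(k_true, 1e-3), r=config.r0, L=max(l_true, 0.0)
            )
            y = simulate_growth_curve(
                params, times, rng, config.noise_mult_sd, config.noise_add_sd
            )
        return SpotTimeSeries(
            plate_id=plate, row=r, col=c, strain_id=strain, condition=conc,
            times=times, intensities=y,
        )

    for p in range(1, n_arrays + 1):
        array_id = f"arr{p:02d}"
        arr_entries = entry_by_array.get(array_id, entries.iloc[0:0])
        for ci, conc in enumerate(config.concentrations, start=1):
            del_plate = f"{array_id}-c{ci}"
            ref_plate = f"ref{p:02d}-c{ci}"
            drug_k = config.drug_k_factor[ci - 1]
            drug_l = config.drug_l_shift[ci - 1]
            sig_k_nom = config.sigma_k_nominal(ci)
            bk, bl = plates_df.loc[del_plate]
            for i, rec in enumerate(arr_entries.itertuples()):
                dk, dl = gene_defect.loc[rec.gene]
                k_int, l_int = inter_lookup.loc[(rec.gene, ci)]
                eps_k = ent_shared_k[rec.Index] + rng.normal(0.0, config.spot_k_cv_indep)
                eps_l = ent_shared_l[rec.Index] + rng.normal(0.0, config.spot_l_sd_indep)
                k_true = (
                    config.K0 * (1.0 + dk) * drug_k * (1.0 + bk) * (1.0 + eps_k)
                    + k_int * sig_k_nom
                )
                l_true = config.L0 + dl + drug_l + bl + eps_l + l_int * sigma_l_nom
                series.append(
                    spot_series(del_plate, rec.row, rec.col, rec.gene, conc, ci,
                                k_true, l_true)
                )
            bk, bl = plates_df.loc[ref_plate]
            for r in range(1, N_ROWS + 1):
                for c in range(1, N_COLS + 1):
                    eps_k = rng.normal(0.0, config.spot_k_cv_shared) + rng.normal(
                        0.0, config.spot_k_cv_indep
                    )
                    eps_l = rng.normal(0.0, config.spot_l_sd_shared) + rng.normal(
                        0.0, config.spot_l_sd_indep
                    )
                    k_true = config.K0 * drug_k * (1.0 + bk) * (1.0 + eps_k)
                    l_true = config.L0 + drug_l + bl + eps_l
                    series.append(
                        spot_series(ref_plate, r, c, REFERENCE_STRAIN, conc, ci,
                                    k_true, l_true)
                    )

    design = ScreenDesign(
        concentrations=tuple(config.concentrations),
        manifest=pd.DataFrame(manifest_rows),
    )
    truth = GroundTruth(
        genes=genes_df, interactions=inter_df, entries=entries.drop(columns=[], errors="ignore"),
        plates=plates_df.reset_index(),
    )
    return SimulatedScreen(series=series, layouts=layouts, design=design,
                           truth=truth, config=config)


def simulate_annotations(
    truth: GroundTruth,
    n_terms: int = 100,
    enrichment_strength: float = 0.8,
    background_rate: float = 0.02,
    seed: int = 0,
    term_size_range: tuple[int, int] = (5, 60),
) -> tuple[AnnotationSet, dict[str, str]]:
    """Annotation table with one planted term per interaction class.

    Each planted group (enhancers, suppressors) receives a term covering
    ``enrichment_strength`` of its members plus unrelated genes at
    ``background_rate``; the remaining terms are assigned uniformly at
    random. Returns the annotation set and {group label: planted term id}.
    """
    rng = np.random.default_rng(seed)
    all_genes = list(truth.genes["gene"])
    terms: dict[str, set[str]] = {}
    planted: dict[str, str] = {}
    if n_terms == 0:
        return AnnotationSet(terms={}), planted
    groups = {
        klass: truth.planted_genes(klass)
        for klass in ("enhancer", "suppressor")
        if truth.planted_genes(klass)
    }
    term_counter = 0
    for klass, members in groups.items():
        term_counter += 1
        term_id = f"T{term_counter:04d}"
        n_take = int(round(enrichment_strength * len(members)))
        take = set(rng.choice(members, size=n_take, replace=False)) if n_take else set()
        others = [g for g in all_genes if g not in members]
        extra_mask = rng.random(len(others)) < background_rate
        take |= {g for g, m in zip(others, extra_mask) if m}
        if take:
            terms[term_id] = take
            planted[klass] = term_id
    while term_counter < n_terms:
        term_counter += 1
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        size = min(size, len(all_genes))
        terms[f"T{term_counter:04d}"] = set(rng.choice(all_genes, size=size, replace=False))
    return AnnotationSet(terms=terms), planted


def simulate_dose_matrix(
    params_a,
    params_b,
    doses_a: np.ndarray,
    doses_b: np.ndarray,
    delta_surface: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dose-combination % inhibition matrix from two monotherapy curves.

    ``params_a`` / ``params_b`` are callables returning fractional
    inhibition at a dose (e.g. :class:`qhtcp.dose._HillInc` or any Hill
    curve). Cell inhibition is 100*(yA + yB - yA*yB) plus the planted
    ``delta_surface`` (combination cells only, in percentage points) plus
    Gaussian noise. Margins are noise-free when ``noise_sd`` is 0.
    """
    rng = np.random.default_rng(seed)
    da = np.concatenate(([0.0], np.asarray(doses_a, dtype=float)))
    db = np.concatenate(([0.0], np.asarray(doses_b, dtype=float)))
    ya = np.array([params_a(x) if x > 0 else 0.0 for x in da])
    yb = np.array([params_b(x) if x > 0 else 0.0 for x in db])
    inhib = 100.0 * (np.add.outer(ya, yb) - np.outer(ya, yb))
    if delta_surface is not None:
        ds = np.asarray(delta_surface, dtype=float)
        if ds.shape != (da.size - 1, db.size - 1):
            raise ConfigError("delta_surface must match the combination-cell grid")
        inhib[1:, 1:] += ds
    if noise_sd > 0:
        inhib = inhib + rng.normal(0.0, noise_sd, inhib.shape)
    return pd.DataFrame(inhib, index=pd.Index(da, name="dose_a"),
                        columns=pd.Index(db, name="dose_b"))


# --- recovery metrics ------------------------------------------------------

def interaction_recovery(
    interaction_table: pd.DataFrame,
    truth: GroundTruth,
    threshold: float = 2.0,
    min_effect_sd: float = 4.0,
) -> dict:
    """Sensitivity / false-positive rate of planted interaction recovery.

    One test per (gene entry, CPP, drug concentration): a planted effect
    with |magnitude| >= ``min_effect_sd`` counts as recovered when its
    adjusted z-score passes ``threshold`` with the planted sign; a test on
    a gene with no planted effect counts as a false positive when
    |adjusted z| >= threshold. Also reports the Pearson correlation
    between planted signed effects and measured adjusted z over all
    planted tests.
    """
    inter = truth.interactions.set_index(["gene", "conc_index"])
    tp = fn = fp = tn = 0
    planted_vals: list[tuple[float, float]] = []
    for rec in interaction_table.itertuples():
        gene = rec.strain
        for ci in range(2, 1 + sum(1 for c in interaction_table.columns if c.startswith("adjK")) + 1):
            for cpp, col in (("k", f"adjK{ci}"), ("l", f"adjL{ci}")):
                z = getattr(rec, col, np.nan)
                if z is None or np.isnan(z):
                    continue
                try:
                    eff = float(inter.loc[(gene, ci), f"{cpp}_effect_sd"])
                except KeyError:
                    continue
                if eff != 0.0:
                    planted_vals.append((eff, z))
                    if abs(eff) >= min_effect_sd:
                        if abs(z) >= threshold and np.sign(z) == np.sign(eff):
                            tp += 1
                        else:
                            fn += 1
                else:
                    if abs(z) >= threshold:
                        fp += 1
                    else:
                        tn += 1
    sens = tp / (tp + fn) if tp + fn else np.nan
    fpr = fp / (fp + tn) if fp + tn else np.nan
    if len(planted_vals) >= 3:
        eff, z = np.array(planted_vals).T
        r = float(np.corrcoef(eff, z)[0, 1])
    else:
        r = np.nan
    return {
        "sensitivity": sens,
        "fpr": fpr,
        "pearson_r": r,
        "n_planted": tp + fn,
        "n_null": fp + tn,
    }


def null_adjusted_stats(
    interaction_table: pd.DataFrame, truth: GroundTruth | None = None
) -> dict:
    """Median / SD / |z|<3 fraction of adjusted z-scores over null genes."""
    df = interaction_table
    if truth is not None:
        null_genes = set(truth.genes.loc[truth.genes["class"] == "none", "gene"])
        df = df[df["strain"].isin(null_genes)]
    cols = [c for c in df.columns if c.startswith(("adjK", "adjL"))]
    vals = df[cols].to_numpy(dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    return {
        "median": float(np.median(vals)),
        "sd": float(np.std(vals, ddof=1)),
        "frac_within_3": float(np.mean(np.abs(vals) < 3.0)),
        "n": int(vals.size),
    }


def with_seed(config: ScreenSimConfig, seed: int) -> ScreenSimConfig:
    """Copy of a config with a different seed (convenience for seed sweeps)."""
    return replace(config, seed=seed)
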