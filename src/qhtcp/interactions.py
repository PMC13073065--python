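"""Plate-standardized z-scores and gene-drug interaction calling.

For each deletion array and condition, a strain's CPP is standardized as

    z = (CPP_strain - median CPP over the deletion array) / SD(reference array)

where the denominator is the standard deviation of the same CPP over the
matched 384-spot reference-strain array. Standardization makes plates and
concentrations comparable.

The interaction model expects a strain's fitness in drug to be
proportional to its fitness without drug, i.e. on the z scale
``z_drug = z_nodrug + interaction``. The *adjusted z-score*
``z_drug - z_nodrug`` therefore measures the gene-drug interaction and is
zero for strains whose drug response merely scales with their baseline
fitness.

Sign conventions (growth-inhibitory drug): drug-*suppressing* deletions
have positive adjusted K z-scores, negative adjusted L z-scores, or both;
drug-*enhancing* deletions the opposite.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .growth import ArrayQCReport
from .plate_io import PlateLayout, ScreenDesign

CLASS_ENHANCER = "enhancer"
CLASS_SUPPRESSOR = "suppressor"
CLASS_NEUTRAL = "neutral"

DEFAULT_THRESHOLD = 2.0


class DegenerateReferenceError(ValueError):
    """The reference-array SD is zero or negative; z-scores are undefined."""


def standardize_plate(values: pd.Series, reference_sd: float) -> pd.Series:
    """z = (CPP - deletion-array median) / reference-array SD.

    ``values`` holds one CPP per strain for a single deletion array and
    condition; entries that failed fitting should already be NaN and are
    excluded from the median.
    """
    if not reference_sd > 0:
        raise DegenerateReferenceError(f"reference sd must be > 0, got {reference_sd}")
    med = values.median(skipna=True)
    return (values - med) / reference_sd


def adjust_zscores(profile: pd.DataFrame, n_conditions: int) -> pd.DataFrame:
    """Append adjusted z-scores adj{K,L}[c] = z[c] - z[1] for each c > 1.

    ``profile`` is a wide table with columns ``z_K1..z_K{n}`` and
    ``z_L1..z_L{n}``. Adjusted values are NaN wherever either operand is
    missing.
    """
    out = profile.copy()
    for cpp in ("K", "L"):
        base = out[f"z_{cpp}1"]
        for c in range(2, n_conditions + 1):
            out[f"adj{cpp}{c}"] = out[f"z_{cpp}{c}"] - base
    return out


def classify_interaction(
    adj_k: float, adj_l: float, threshold: float = DEFAULT_THRESHOLD
) -> str:
    """Classify one (strain, concentration) from its adjusted z-scores.

    suppressor: adjK >= threshold or adjL <= -threshold;
    enhancer:   adjK <= -threshold or adjL >= threshold;
    neutral otherwise. If rules for both classes fire, the larger
    |adjusted z| wins; an exact tie is neutral.
    """
    sup = max(
        (adj_k if not np.isnan(adj_k) and adj_k >= threshold else 0.0),
        (-adj_l if not np.isnan(adj_l) and adj_l <= -threshold else 0.0),
    )
    enh = max(
        (-adj_k if not np.isnan(adj_k) and adj_k <= -threshold else 0.0),
        (adj_l if not np.isnan(adj_l) and adj_l >= threshold else 0.0),
    )
    if sup == 0.0 and enh == 0.0:
        return CLASS_NEUTRAL
    if sup > enh:
        return CLASS_SUPPRESSOR
    if enh > sup:
        return CLASS_ENHANCER
    return CLASS_NEUTRAL


def score_screen(
    fit_table: pd.DataFrame,
    design: ScreenDesign,
    layouts: Mapping[str, PlateLayout],
    qc_reports: list[ArrayQCReport] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    min_valid_fraction: float = 0.5,
) -> pd.DataFrame:
    """Turn a fitted screen into the per-strain interaction table.

    One output row per spot lineage (array position); duplicate ORF strains
    are scored independently here and only collapsed where the enrichment
    background requires it. Arrays failing QC, or with fewer than
    ``min_valid_fraction`` valid CPPs, contribute NaN z-scores.

    Columns: array, row, col, strain, z_K1..z_K{n}, z_L1..z_L{n},
    adjK2.., adjL2.., class_{conc}ugml per drug concentration.
    """
    n_cond = len(design.concentrations)
    qc_pass: dict[tuple[str, float], bool] = {}
    if qc_reports is not None:
        qc_pass = {(r.plate_id, r.condition): r.passed for r in qc_reports}

    fit = fit_table.copy()
    fit["valid"] = fit["converged"] & (fit["flags"].fillna("").astype(str) == "")
    by_plate = dict(tuple(fit.groupby("plate", sort=False)))

    # per-physical-plate reference SDs
    records: dict[tuple[str, int, int], dict] = {}
    for rec in design.manifest.itertuples():
        ci = design.concentration_index(rec.condition_ugml)
        del_fit = by_plate.get(rec.deletion_plate)
        ref_fit = by_plate.get(rec.reference_plate)
        if del_fit is None:
            continue
        layout = layouts.get(rec.deletion_plate)
        ok = qc_pass.get((rec.deletion_plate, rec.condition_ugml), True)
        if ref_fit is not None:
            ok &= qc_pass.get((rec.reference_plate, rec.condition_ugml), True)
        z_cols: dict[str, pd.Series] = {}
        if ok and ref_fit is not None:
            for cpp in ("K", "L"):
                vals = del_fit.loc[del_fit["valid"], cpp]
                ref_vals = ref_fit.loc[ref_fit["valid"], cpp]
                if (
                    len(del_fit) == 0
                    or vals.notna().sum() < min_valid_fraction * len(del_fit)
                    or ref_vals.notna().sum() < 2
                ):
                    continue
                ref_sd = float(ref_vals.std(ddof=1))
                if ref_sd <= 0:
                    raise DegenerateReferenceError(
                        f"reference array {rec.reference_plate} has zero {cpp} SD"
                    )
                masked = del_fit[cpp].where(del_fit["valid"])
                z_cols[cpp] = standardize_plate(masked, ref_sd)
        for idx, spot in del_fit.iterrows():
            if layout is not None:
                _, role = layout.positions.get((int(spot["row"]), int(spot["col"])), ("", "empty"))
                if role == "empty":
                    continue
            key = (rec.array_id, int(spot["row"]), int(spot["col"]))
            entry = records.setdefault(
                key,
                {"array": rec.array_id, "row": key[1], "col": key[2], "strain": spot["strain"]},
            )
            for cpp in ("K", "L"):
                entry[f"z_{cpp}{ci}"] = (
                    float(z_cols[cpp].loc[idx]) if cpp in z_cols else np.nan
                )

    if not records:
        return pd.DataFrame()
    profile = pd.DataFrame(sorted(records.values(), key=lambda d: (d["array"], d["row"], d["col"])))
    for cpp in ("K", "L"):
        for c in range(1, n_cond + 1):
            col = f"z_{cpp}{c}"
            if col not in profile.columns:
                profile[col] = np.nan
    profile = adjust_zscores(profile, n_cond)
    for c in range(2, n_cond + 1):
        conc = design.concentrations[c - 1]
        profile[f"class_{conc:g}ugml"] = [
            classify_interaction(k, l, threshold)
            for k, l in zip(profile[f"adjK{c}"], profile[f"adjL{c}"])
        ]
    return profile


def rank_outliers(
    interaction_table: pd.DataFrame,
    parameter: str,
    conc_index: int,
    direction: str = "lowest",
    n: int = 10,
) -> pd.DataFrame:
    """Top-n strains by one adjusted z-score column.

    ``parameter`` is ``"K"`` or ``"L"``; ``conc_index`` the 1-based
    concentration index (> 1). ``direction`` ``"lowest"`` ranks ascending
    (the drug-enhancing tail for K, drug-suppressing for L). Ties are
    broken alphabetically by strain.
    """
    if parameter not in ("K", "L"):
        raise ValueError("parameter must be 'K' or 'L'")
    col = f"adj{parameter}{conc_index}"
    if col not in interaction_table.columns:
        raise KeyError(f"no column {col} in interaction table")
    df = interaction_table.dropna(subset=[col])
    asc = direction == "lowest"
    df = df.sort_values([col, "strain"], ascending=[asc, True], kind="mergesort")
    if n > len(df):
        warnings.warn(
            f"requested {n} outliers but only {len(df)} scored strains available",
            stacklevel=2,
        )
    return df.head(n)[["strain", "array", "row", "col", col]].reset_index(drop=True)
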