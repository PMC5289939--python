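"""Well-level aggregation, hit calling and synergy scoring.

A perturbation is scored by the well-mean residual ``yap_diff`` of the
wild-type shape model: targets whose wells sit far above the control
distribution are candidate YAP *inhibitors* (more nuclear YAP than shape
predicts), far below are candidate *activators*. The threshold is k
standard deviations (default 2) of the control well means, a replicate
rule (2 of 2 or 3 of 4 wells) guards against single-well artifacts, and
directional total-intensity gates drop wells whose YAP protein level is
itself an outlier: wells with very low total YAP cannot be activator
hits, wells with very high total YAP cannot be inhibitor hits.

Density-sensitive shape features can additionally be normalized against a
"standard curve" — the control-well trend of the feature versus (log)
cell count — so that a perturbation's shape effect is read as the
departure from the wild-type density trend rather than its raw value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "summarize_wells",
    "density_standard_curve",
    "StandardCurve",
    "call_hits",
    "synergy_score",
    "score_screen",
]

_SUMMARY_MEANS = {
    "mean_yap_ratio": "yap_ratio",
    "mean_yap_pred": "yap_pred",
    "mean_yap_diff": "yap_diff",
    "mean_yap_total": "yap_total",
    "mean_NF": "NF",
    "mean_LCD": "LCD",
    "mean_cellA": "cellA",
}


def summarize_wells(records: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    """Aggregate QC-passing cells into per-well means.

    ``records`` must carry ``well_id`` plus whichever of the summarized
    columns exist (``yap_pred``/``yap_diff`` from a model's predict step).
    ``layout`` maps wells to plate/treatment/replicate; wells present in
    the data but absent from the layout raise with the orphan list. Wells
    with no (passing) cells keep ``n_cells = 0`` and absent means.
    """
    layout = layout.copy()
    known = set(layout["well"])
    orphans = sorted(set(records["well_id"]) - known)
    if orphans:
        raise ValueError(f"wells present in data but not in layout: {orphans}")
    flags = records.get("qc_flags", pd.Series("", index=records.index)).fillna("")
    passing = records.loc[flags.astype(str).str.len() == 0]
    rows = []
    for _, well_row in layout.iterrows():
        sub = passing.loc[passing["well_id"] == well_row["well"]]
        row = {
            "well_id": well_row["well"],
            "plate_id": well_row.get("plate", ""),
            "treatment": well_row["treatment"],
            "replicate_index": well_row.get("replicate", 0),
            "is_control": bool(well_row.get("is_control", False)),
            "n_cells": int(len(sub)),
        }
        for out_col, in_col in _SUMMARY_MEANS.items():
            if in_col in sub.columns and len(sub):
                row[out_col] = float(sub[in_col].mean())
            else:
                row[out_col] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StandardCurve:
    """Control-well trend of one feature versus cell count."""

    feature: str
    slope: float
    intercept: float
    form: str = "log-linear"  # regressor: log(n_cells) | n_cells

    def __call__(self, n_cells) -> np.ndarray:
        x = np.log(np.asarray(n_cells, dtype=float)) if self.form == "log-linear" \
            else np.asarray(n_cells, dtype=float)
        return self.intercept + self.slope * x

    def normalize(self, summaries: pd.DataFrame) -> pd.Series:
        """Observed well mean minus the control-curve expectation."""
        return summaries[self.feature] - self(summaries["n_cells"])


def density_standard_curve(
    feature_name: str, control_summaries: pd.DataFrame, form: str = "log-linear"
) -> StandardCurve:
    """Least-squares standard curve of a well-mean feature on cell count."""
    ctrl = control_summaries.dropna(subset=[feature_name, "n_cells"])
    if len(ctrl) < 5:
        raise ValueError(f"need >= 5 control wells, got {len(ctrl)}")
    n = ctrl["n_cells"].to_numpy(dtype=float)
    if n.max() / max(n.min(), 1e-12) < 2:
        warnings.warn(
            f"control wells span under a 2-fold cell-count range "
            f"({n.min():.0f}-{n.max():.0f}); standard curve may be unstable"
        )
    x = np.log(n) if form == "log-linear" else n
    y = ctrl[feature_name].to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return StandardCurve(feature_name, float(slope), float(intercept), form)


def call_hits(
    summaries: pd.DataFrame,
    control_summaries: pd.DataFrame | None = None,
    replicate_rule: str = "2of2",
    k_sd: float = 2.0,
    apply_intensity_gates: bool = True,
) -> pd.DataFrame:
    """Call activator/inhibitor candidates from well summaries.

    The threshold is ``k_sd`` times the SD of the *control well means* of
    ``yap_diff`` (not pooled single cells). A target is called in a
    direction only if the replicate rule's required number of wells exceeds
    the threshold strictly in that direction and those wells pass the
    corresponding total-intensity gate.
    """
    if replicate_rule not in ("2of2", "3of4"):
        raise ValueError(f"unknown replicate_rule {replicate_rule!r}")
    need = {"2of2": 2, "3of4": 3}[replicate_rule]
    if control_summaries is None:
        control_summaries = summaries.loc[summaries["is_control"]]
    ctrl = control_summaries.dropna(subset=["mean_yap_diff"])
    if len(ctrl) < 2:
        raise ValueError("need at least 2 control wells with yap_diff")
    sd = float(ctrl["mean_yap_diff"].std(ddof=1))
    threshold = k_sd * sd
    tot = ctrl["mean_yap_total"].dropna()
    low_gate = float(tot.mean() - k_sd * tot.std(ddof=1)) if len(tot) > 1 else -np.inf
    high_gate = float(tot.mean() + k_sd * tot.std(ddof=1)) if len(tot) > 1 else np.inf

    rows = []
    targets = summaries.loc[~summaries["is_control"], "treatment"].unique()
    for target in targets:
        wells = summaries.loc[summaries["treatment"] == target]
        d = wells["mean_yap_diff"]
        t = wells["mean_yap_total"]
        hi_raw = d > threshold
        lo_raw = d < -threshold
        if apply_intensity_gates:
            hi_ok = hi_raw & (t.fillna(np.inf) < high_gate)
            lo_ok = lo_raw & (t.fillna(-np.inf) > low_gate)
        else:
            hi_ok, lo_ok = hi_raw, lo_raw
        n_hi, n_lo = int(hi_ok.sum()), int(lo_ok.sum())
        direction, passing, gate = "none", 0, "pass"
        if n_lo >= need:
            direction, passing = "activator_candidate", n_lo
        elif n_hi >= need:
            direction, passing = "inhibitor_candidate", n_hi
        else:
            # report when the gate (not the threshold) blocked the call
            if int(lo_raw.sum()) >= need:
                gate = "low_total_excluded"
            elif int(hi_raw.sum()) >= need:
                gate = "high_total_excluded"
            passing = max(int(lo_raw.sum()), int(hi_raw.sum()))
        rows.append(
            dict(
                target=target,
                direction=direction,
                wells_passing=passing,
                replicate_rule_met=direction != "none",
                intensity_gate=gate,
                threshold_used=threshold,
                n_wells=int(len(wells)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "target", "direction", "wells_passing", "replicate_rule_met",
            "intensity_gate", "threshold_used", "n_wells",
        ],
    )


def score_screen(
    cells: pd.DataFrame,
    layout: pd.DataFrame,
    replicate_rule: str = "2of2",
    k_sd: float = 2.0,
    feature_set: str = "MLR6",
):
    """Full screen scoring: fit on controls, predict all, aggregate, call.

    Fits the shape model on QC-passing cells of the layout's control
    wells, applies it to every cell, aggregates wells and calls hits.
    Returns ``(model_results, summaries, hit_calls)``.
    """
    from .model import ShapeNormalizationModel

    control_wells = set(layout.loc[layout["is_control"], "well"])
    ctrl_cells = cells.loc[cells["well_id"].isin(control_wells)]
    results = ShapeNormalizationModel.from_records(ctrl_cells, feature_set=feature_set).fit()
    pred = results.predict(cells)
    scored = cells.copy()
    scored["yap_pred"] = pred["yap_pred"]
    scored["yap_diff"] = pred["yap_diff"]
    summaries = summarize_wells(scored, layout)
    calls = call_hits(summaries, replicate_rule=replicate_rule, k_sd=k_sd)
    return results, summaries, calls


def synergy_score(
    dmso_summaries: pd.DataFrame,
    drug_summaries: pd.DataFrame,
    wildtype_targets: list[str],
) -> pd.DataFrame:
    """Drug-by-knockdown synergy as distance from the wild-type trend.

    For each target, the drug effect is the change in shape-normalized YAP
    (mean ``yap_diff`` under drug minus under vehicle). Because the drug
    effect itself varies with cell number, the wild-type pairs define a
    least-squares reference line of effect versus cell count; a target's
    synergy is its signed vertical residual from that line (negative =
    drug lowers YAP beyond what shape and density predict).
    """
    def per_target(summaries):
        g = summaries.groupby("treatment")
        return pd.DataFrame(
            {"yap_diff": g["mean_yap_diff"].mean(), "n_cells": g["n_cells"].mean()}
        )

    dmso = per_target(dmso_summaries)
    drug = per_target(drug_summaries)
    rows = []
    for target in drug.index:
        if target not in dmso.index:
            warnings.warn(f"target {target!r} has no vehicle partner; skipped")
            continue
        rows.append(
            dict(
                target=target,
                delta_yap_diff=float(drug.loc[target, "yap_diff"] - dmso.loc[target, "yap_diff"]),
                n_cells=float(
                    0.5 * (drug.loc[target, "n_cells"] + dmso.loc[target, "n_cells"])
                ),
                is_wildtype=target in wildtype_targets,
            )
        )
    table = pd.DataFrame(rows)
    wt = table.loc[table["is_wildtype"]]
    if len(wt) < 3:
        raise ValueError(f"need >= 3 wild-type pairs for the reference line, got {len(wt)}")
    slope, intercept = np.polyfit(wt["n_cells"], wt["delta_yap_diff"], 1)
    table["synergy"] = table["delta_yap_diff"] - (intercept + slope * table["n_cells"])
    table.attrs["reference_line"] = {"slope": float(slope), "intercept": float(intercept)}
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(wt["n_cells"], wt["delta_yap_diff"])[0, 1]
    table.attrs["reference_r_squared"] = float(r**2)
    return table
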