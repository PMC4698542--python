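"""Two-stage blot normalization, loading-control QC, and group summaries.

Every band of protein *p* is first divided by the average of all *p* bands
in its blot set (the membranes processed together), then by the pooled
control-sample band for *p* on its own blot.  Because both stages are
ratios, any multiplicative factor shared by a whole blot — batch effects
from transfer efficiency, antibody incubation, or scanning — cancels.
Finally, values are rescaled so the reference group's mean is exactly 1
per protein (fold-of-reference), the scale on which results are reported.

The loading control (GAPDH) is used for quality control only: each group
is compared to the reference group with the study's Monte-Carlo procedure,
and the QC passes when no comparison is significant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .mc import MCConfig

__all__ = [
    "NormalizedTable",
    "GroupSummary",
    "QCReport",
    "normalize",
    "summarize",
    "to_summaries",
    "loading_control_qc",
]

BAND_COLUMNS = ("blot_id", "lane_id", "animal_id", "group", "protein", "raw_density")


@dataclass(frozen=True)
class GroupSummary:
    """Per group x measure sample statistics feeding the Monte-Carlo null."""

    group: str
    measure: str
    n: int
    mean: float
    sd: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"{self.group}/{self.measure}: n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if abs(self.sem - self.sd / np.sqrt(self.n)) > 1e-12 * max(1.0, self.sd):
            raise ValueError("sem must equal sd/sqrt(n)")


@dataclass(frozen=True)
class NormalizedTable:
    """Per animal x protein normalized expression, fold-of-reference scale."""

    rows: pd.DataFrame  # columns: animal_id, group, protein, value
    reference_group: str
    provenance: dict

    def pivot(self) -> pd.DataFrame:
        """Animals x proteins wide view."""
        return self.rows.pivot_table(
            index=["animal_id", "group"], columns="protein", values="value", aggfunc="mean"
        )


@dataclass(frozen=True)
class QCReport:
    """Loading-control check: passes iff no group differs from reference."""

    passed: bool
    control_protein: str
    alpha: float
    comparisons: pd.DataFrame


def _validate_band_table(table: pd.DataFrame) -> None:
    missing = [c for c in BAND_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"band table missing columns: {', '.join(missing)}")
    if len(table) and not (table["raw_density"] > 0).all():
        bad = table.loc[~(table["raw_density"] > 0)]
        raise ValueError(
            f"raw densities must be strictly positive; offending rows: {bad.index.tolist()[:10]}"
        )


def normalize(
    table: pd.DataFrame,
    blot_set_map: Mapping[str, str],
    control_lanes: Mapping[str, str],
    reference_group: str,
) -> NormalizedTable:
    """Apply the two-stage normalization and fold-of-reference rescaling.

    Parameters
    ----------
    table
        Band table (one row per blot x lane x protein) with the canonical
        columns.  Control-sample bands are identified by *control_lanes*.
    blot_set_map
        blot_id -> blot-set label (membranes processed together).
    control_lanes
        blot_id -> lane_id holding the pooled control sample.
    reference_group
        Group whose mean becomes 1 per protein.
    """
    _validate_band_table(table)
    df = table.copy()

    unassigned = sorted(set(df["blot_id"].unique()) - set(blot_set_map))
    if unassigned:
        raise ValueError(f"blots missing from blot_set_map: {', '.join(map(str, unassigned))}")
    no_control = sorted(set(df["blot_id"].unique()) - set(control_lanes))
    if no_control:
        raise ValueError(f"blots missing a control-sample lane: {', '.join(map(str, no_control))}")

    df["blot_set"] = df["blot_id"].map(blot_set_map)
    is_control = pd.Series(
        [control_lanes.get(b) == l for b, l in zip(df["blot_id"], df["lane_id"])], index=df.index
    )
    samples = df.loc[~is_control].copy()
    controls = df.loc[is_control].copy()

    # stage 1: divide by the per-protein average over the blot set (sample bands)
    set_mean = samples.groupby(["blot_set", "protein"])["raw_density"].transform("mean")
    samples["v1"] = samples["raw_density"] / set_mean
    ctrl_set_mean = (
        samples.groupby(["blot_set", "protein"])["raw_density"].mean().rename("set_mean")
    )
    controls = controls.join(ctrl_set_mean, on=["blot_set", "protein"])
    if controls["set_mean"].isna().any() or (controls["set_mean"] <= 0).any():
        bad = controls.loc[controls["set_mean"].isna() | (controls["set_mean"] <= 0)]
        pairs = sorted({(r.protein, r.blot_id) for r in bad.itertuples()})
        raise ValueError(f"zero or absent blot-set mean for (protein, blot): {pairs}")
    controls["v1"] = controls["raw_density"] / controls["set_mean"]

    # stage 2: divide by the control-sample band for the protein on the same blot
    ctrl_v1 = controls.set_index(["blot_id", "protein"])["v1"]
    if ctrl_v1.index.has_duplicates:
        raise ValueError("multiple control-sample bands for the same (blot, protein)")
    expected = pd.MultiIndex.from_product(
        [samples["blot_id"].unique(), samples["protein"].unique()], names=["blot_id", "protein"]
    )
    absent = sorted(set(expected) - set(ctrl_v1.index))
    if absent:
        raise ValueError(f"control-sample band missing for (blot, protein): {absent[:10]}")
    samples["v2"] = samples["v1"] / ctrl_v1.loc[
        pd.MultiIndex.from_arrays([samples["blot_id"], samples["protein"]])
    ].to_numpy()

    # replicate bands collapse to one value per animal x protein
    per_animal = (
        samples.groupby(["animal_id", "group", "protein"], as_index=False)["v2"]
        .mean()
        .rename(columns={"v2": "value"})
    )

    # fold-of-reference: reference-group mean becomes exactly 1 per protein
    if reference_group not in set(per_animal["group"]):
        raise ValueError(f"reference group {reference_group!r} absent from the table")
    ref_mean = (
        per_animal.loc[per_animal["group"] == reference_group]
        .groupby("protein")["value"]
        .mean()
    )
    missing_ref = sorted(set(per_animal["protein"].unique()) - set(ref_mean.index))
    if missing_ref:
        raise ValueError(f"reference group lacks proteins: {', '.join(missing_ref)}")
    per_animal["value"] = per_animal["value"] / ref_mean.loc[per_animal["protein"]].to_numpy()

    if not (per_animal["value"] > 0).all():
        raise ValueError("normalization produced non-positive values")

    provenance = {
        "steps": [
            "blot_set_average_per_protein",
            "control_sample_ratio_per_blot",
            "fold_of_reference_group",
        ],
        "reference_group": reference_group,
        "blot_set_map": dict(sorted(blot_set_map.items())),
        "control_lanes": dict(sorted(control_lanes.items())),
        "input_sha256": hashlib.sha256(
            table.to_csv(index=False).encode()
        ).hexdigest(),
    }
    return NormalizedTable(
        rows=per_animal.sort_values(["protein", "group", "animal_id"], ignore_index=True),
        reference_group=reference_group,
        provenance=provenance,
    )


def summarize(table: NormalizedTable | pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Per group x measure: n, mean, sample SD (n-1), SEM = SD/sqrt(n).

    Accepts a :class:`NormalizedTable` or any long frame with ``group``,
    a measure column (``protein`` or ``measure``/``index``) and a value column.
    """
    df = table.rows if isinstance(table, NormalizedTable) else table
    measure_col = next((c for c in ("protein", "measure", "index") if c in df.columns), None)
    if measure_col is None:
        raise ValueError("no measure column (protein/measure/index) found")
    g = df.groupby(["group", measure_col])[value_col]
    out = g.agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1)).reset_index()
    out = out.rename(columns={measure_col: "measure"})
    small = out.loc[out["n"] < 2]
    if len(small):
        pairs = [(r.group, r.measure) for r in small.itertuples()]
        raise ValueError(f"groups with < 2 animals: {pairs}")
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.sort_values(["measure", "group"], ignore_index=True)


def to_summaries(summary: pd.DataFrame) -> list[GroupSummary]:
    return [
        GroupSummary(
            group=r.group, measure=r.measure, n=int(r.n), mean=float(r.mean),
            sd=float(r.sd), sem=float(r.sem),
        )
        for r in summary.itertuples()
    ]


def loading_control_qc(
    normalized: NormalizedTable,
    control_protein: str,
    config: "MCConfig",
    alpha: float | None = None,
) -> QCReport:
    """Compare every group to the reference on the loading control.

    Runs the study's Monte-Carlo comparison of each non-reference group
    against the reference group on *control_protein*; the QC passes iff
    no comparison is significant at *alpha* (default: ``config.alpha``).
    """
    from .mc import comparison_matrix  # deferred to avoid a module cycle

    df = normalized.rows
    present = df.loc[df["protein"] == control_protein, "animal_id"]
    all_animals = df["animal_id"].unique()
    missing = sorted(set(all_animals) - set(present))
    if missing:
        raise ValueError(
            f"loading control {control_protein!r} missing for animals: {', '.join(missing)}"
        )
    alpha = config.alpha if alpha is None else alpha
    sub = df.loc[df["protein"] == control_protein]
    groups = list(pd.unique(sub["group"]))
    if len(groups) < 2:
        return QCReport(
            passed=True, control_protein=control_protein, alpha=alpha,
            comparisons=pd.DataFrame(),
        )
    cfg = config.replace(alpha=alpha)
    summary = summarize(sub.rename(columns={"protein": "measure"}))
    comps = comparison_matrix(
        summary,
        cfg,
        references=[normalized.reference_group],
        include_self=False,
    )
    return QCReport(
        passed=not bool(comps["significant"].any()),
        control_protein=control_protein,
        alpha=alpha,
        comparisons=comps,
    )


def provenance_json(normalized: NormalizedTable) -> str:
    return json.dumps(normalized.provenance, indent=2, sort_keys=True)
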