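"""Synthetic Western-blot data with the statistical structure the analysis assumes.

The generator forward-models the measurement process: a band's raw density is

    raw(a, p) = mu(group(a), p) * animal_effect * batch_factor(blot) * loading_factor(lane)

where ``mu`` is the true group mean expression on a fold-of-normal scale,
``animal_effect`` is normal with mean 1 (truncated positive) capturing
between-animal biological variation, and the batch and loading factors are
log-normal with median 1 modelling blot-to-blot processing differences and
per-lane pipetting jitter.  A pooled control sample — an aliquot combining
every animal's sample — is placed in a dedicated lane on every blot; its
expected composition is the animal-weighted average of the group means.

The default design emulates a four-group visual-cortex study (normal n=6,
fluoxetine n=8, monocular deprivation n=6, fluoxetine+MD n=8) over 12
synaptic proteins plus a GAPDH loading control, with true effect sizes and
between-animal SDs reconstructed from reported percent changes and SEMs
(SD = SEM * sqrt(n)).  Groups without a reported change default to no
effect (1.0) with a conservative SD of 0.10.

``render_gel_image`` draws a blot's bands as 2-D Gaussian bumps on a
constant background in a 16-bit image, scaled so the background-corrected,
width-normalized integral of each band reproduces the tabulated raw
density — giving the densitometry module a closed-loop fixture.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .densitometry import BandROI

__all__ = [
    "SyntheticDesign",
    "SyntheticBandTable",
    "GelGeometry",
    "default_design",
    "generate_table",
    "render_gel_image",
    "write_band_table",
    "CONTROL_ANIMAL",
    "CONTROL_GROUP",
    "DEFAULT_GROUPS",
    "DEFAULT_PROTEINS",
    "LOADING_CONTROL",
]

CONTROL_ANIMAL = "pooled_control"
CONTROL_GROUP = "control_sample"

DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (
    ("normal", 6),
    ("fluoxetine", 8),
    ("MD", 6),
    ("fluoxetine+MD", 8),
)

DEFAULT_PROTEINS: tuple[str, ...] = (
    "synapsin",
    "synaptophysin",
    "VGLUT1",
    "VGAT",
    "PSD-95",
    "gephyrin",
    "GluN1",
    "GluA2",
    "GluN2A",
    "GluN2B",
    "GABAAa1",
    "GABAAa3",
)

LOADING_CONTROL = "GAPDH"

# Reported group changes: (group, protein) -> (percent change, SEM percent).
# Groups/proteins without a reported change are left at effect 1.0.
_REPORTED_CHANGES: dict[tuple[str, str], tuple[float, float]] = {
    ("MD", "synaptophysin"): (-13.0, 4.1),
    ("fluoxetine", "VGLUT1"): (-29.0, 3.0),
    ("MD", "VGLUT1"): (25.0, 8.4),
    ("fluoxetine+MD", "VGLUT1"): (-13.0, 4.9),
    ("MD", "PSD-95"): (-37.0, 5.6),
    ("fluoxetine+MD", "PSD-95"): (46.0, 15.0),
    ("MD", "gephyrin"): (-45.0, 4.0),
    ("fluoxetine+MD", "gephyrin"): (34.0, 11.0),
    ("fluoxetine", "GluN1"): (-15.0, 4.8),
    ("MD", "GluN1"): (25.0, 8.8),
    ("fluoxetine+MD", "GluN1"): (-18.0, 4.5),
    ("MD", "GluA2"): (18.0, 5.9),
    ("fluoxetine+MD", "GluA2"): (-15.0, 4.2),
    ("fluoxetine", "GluN2B"): (-28.0, 4.5),
    ("fluoxetine+MD", "GluN2B"): (-21.0, 4.0),
    ("MD", "GABAAa3"): (18.0, 6.6),
    ("fluoxetine", "GABAAa1"): (24.0, 11.0),
    ("fluoxetine+MD", "GABAAa1"): (24.0, 20.0),
}

#: between-animal SD used where no SEM is reported (conservative null filler)
DEFAULT_NOISE_SD = 0.10


@dataclass(frozen=True)
class SyntheticDesign:
    """Truth underlying a synthetic study: groups, effects, and noise structure."""

    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    proteins: tuple[str, ...] = DEFAULT_PROTEINS
    loading_control: str = LOADING_CONTROL
    effect: Mapping[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: Mapping[tuple[str, str], float] = field(default_factory=dict)
    n_blots: int = 2
    batch_sd: float = 0.10
    loading_sd: float = 0.05
    replicates: int = 1
    seed: int = 0

    @property
    def reference_group(self) -> str:
        return self.groups[0][0]

    @property
    def all_proteins(self) -> tuple[str, ...]:
        return self.proteins + (self.loading_control,)

    @property
    def group_sizes(self) -> dict[str, int]:
        return dict(self.groups)

    def get_effect(self, group: str, protein: str) -> float:
        return float(self.effect.get((group, protein), 1.0))

    def get_noise_sd(self, group: str, protein: str) -> float:
        return float(self.noise_sd.get((group, protein), DEFAULT_NOISE_SD))

    def animals(self) -> list[tuple[str, str]]:
        """(animal_id, group) pairs in a stable order."""
        out = []
        for group, n in self.groups:
            for i in range(n):
                out.append((f"{group}_{i + 1:02d}", group))
        return out

    def blot_of(self) -> dict[str, str]:
        """Round-robin animal→blot assignment, balancing groups across blots."""
        assignment = {}
        for j, (animal, _) in enumerate(self.animals()):
            assignment[animal] = f"B{j % self.n_blots + 1}"
        return assignment

    def validate(self) -> None:
        if self.n_blots < 1:
            raise ValueError("n_blots must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.batch_sd < 0 or self.loading_sd < 0:
            raise ValueError("batch_sd and loading_sd must be >= 0")
        for group, n in self.groups:
            if n < 2:
                raise ValueError(f"group {group!r}: animal count must be >= 2, got {n}")
        for (group, protein), mu in self.effect.items():
            if mu <= 0:
                raise ValueError(f"effect[{group}, {protein}] must be > 0, got {mu}")
        for (group, protein), sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{group}, {protein}] must be >= 0, got {sd}")
        ref = self.reference_group
        for p in self.all_proteins:
            if self.get_effect(ref, p) != 1.0:
                raise ValueError(f"reference group must have effect 1.0 for {p!r}")
        for g, _ in self.groups:
            if self.get_effect(g, self.loading_control) != 1.0:
                raise ValueError(
                    f"loading control {self.loading_control!r} must have effect 1.0 "
                    f"in every group (violated by {g!r})"
                )


@dataclass(frozen=True)
class SyntheticBandTable:
    """Generated band table plus the design truth and layout maps that produced it."""

    table: pd.DataFrame
    design: SyntheticDesign
    blot_set_map: dict[str, str]
    control_lanes: dict[str, str]

    def truth(self, group: str, protein: str) -> float:
        return self.design.get_effect(group, protein)


def default_design(**overrides) -> SyntheticDesign:
    """Design matching the emulated four-group study.

    Effects are fold-of-normal reconstructed from reported percent changes;
    between-animal SDs are SEM(%) * sqrt(n) on the same scale.  The loading
    control and all unreported group effects are 1.0 (SD 0.10).
    """
    sizes = dict(overrides.get("groups", DEFAULT_GROUPS))
    effect: dict[tuple[str, str], float] = {}
    noise: dict[tuple[str, str], float] = {}
    for (group, protein), (pct, sem_pct) in _REPORTED_CHANGES.items():
        if group not in sizes:
            continue
        effect[(group, protein)] = 1.0 + pct / 100.0
        noise[(group, protein)] = (sem_pct / 100.0) * np.sqrt(sizes[group])
    overrides.setdefault("effect", effect)
    overrides.setdefault("noise_sd", noise)
    design = SyntheticDesign(**overrides)
    design.validate()
    return design


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated positive by resampling non-positive values."""
    x = rng.normal(mean, sd, size)
    while True:
        bad = x <= 0
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, int(bad.sum()))


def generate_table(design: SyntheticDesign, seed: int | None = None) -> SyntheticBandTable:
    """Generate one synthetic band table from *design*; reproducible for a fixed seed."""
    design.validate()
    rng = np.random.default_rng(design.seed if seed is None else seed)

    animals = design.animals()
    blot_of = design.blot_of()
    blots = sorted(set(blot_of.values()), key=lambda b: int(b[1:]))
    sizes = design.group_sizes
    n_total = sum(sizes.values())

    # lane layout per blot: samples in assignment order, control sample last
    lanes: dict[str, dict[str, str]] = {b: {} for b in blots}  # blot -> animal -> lane
    for b in blots:
        members = [a for a, _ in animals if blot_of[a] == b]
        for k, a in enumerate(members):
            lanes[b][a] = f"L{k + 1:02d}"
    control_lanes = {b: f"L{len(lanes[b]) + 1:02d}" for b in blots}

    batch = {b: float(np.exp(rng.normal(0.0, design.batch_sd))) for b in blots}
    loading: dict[tuple[str, str], float] = {}
    for b in blots:
        for lane in list(lanes[b].values()) + [control_lanes[b]]:
            loading[(b, lane)] = float(np.exp(rng.normal(0.0, design.loading_sd)))

    # pooled control sample: animal-weighted average of group means per protein
    control_truth = {
        p: sum(sizes[g] * design.get_effect(g, p) for g, _ in design.groups) / n_total
        for p in design.all_proteins
    }

    records = []
    for protein in design.all_proteins:
        for animal, group in animals:
            mu = design.get_effect(group, protein)
            sd = design.get_noise_sd(group, protein)
            cv = sd / mu
            eff = _positive_normal(rng, 1.0, cv, design.replicates) if cv > 0 else np.ones(design.replicates)
            b = blot_of[animal]
            lane = lanes[b][animal]
            for r in range(design.replicates):
                records.append(
                    {
                        "blot_id": b,
                        "lane_id": lane,
                        "animal_id": animal,
                        "group": group,
                        "protein": protein,
                        "raw_density": mu * eff[r] * batch[b] * loading[(b, lane)],
                    }
                )
        for b in blots:
            lane = control_lanes[b]
            records.append(
                {
                    "blot_id": b,
                    "lane_id": lane,
                    "animal_id": CONTROL_ANIMAL,
                    "group": CONTROL_GROUP,
                    "protein": protein,
                    "raw_density": control_truth[protein] * batch[b] * loading[(b, lane)],
                }
            )

    table = pd.DataFrame.from_records(records)
    assert (table["raw_density"] > 0).all()
    blot_set_map = {b: "set1" for b in blots}
    return SyntheticBandTable(
        table=table, design=design, blot_set_map=blot_set_map, control_lanes=control_lanes
    )


@dataclass(frozen=True)
class GelGeometry:
    """Band layout for rendered gel images (pixel units)."""

    lane_width: int = 24
    lane_gap: int = 10
    band_height: int = 12
    row_gap: int = 12
    margin: int = 16
    background: float = 100.0
    sigma_divisor: float = 8.0  # band sigma = extent / sigma_divisor

    def __post_init__(self) -> None:
        if min(self.lane_width, self.band_height) < 4:
            raise ValueError("lane_width and band_height must be >= 4 px")
        if min(self.lane_gap, self.row_gap) < 2:
            raise ValueError("lane_gap and row_gap must be >= 2 px so ROIs cannot overlap")
        if self.margin < 4:
            raise ValueError("margin must be >= 4 px to leave a background frame")
        if self.background < 0:
            raise ValueError("background must be >= 0")


def render_gel_image(
    table: SyntheticBandTable | pd.DataFrame,
    blot_id: str,
    geometry: GelGeometry = GelGeometry(),
) -> tuple[np.ndarray, list[BandROI]]:
    """Render one blot's bands as a 16-bit grayscale image plus its ROI list.

    Each band is a 2-D Gaussian bump scaled so the pixel sum over its ROI is
    exactly ``raw_density * roi.width`` before quantization, i.e. the
    densitometry contract recovers the tabulated density up to 16-bit
    rounding.  The constant geometry background is added everywhere.
    """
    df = table.table if isinstance(table, SyntheticBandTable) else table
    sub = df[df["blot_id"] == blot_id]
    if sub.empty:
        raise ValueError(f"no rows for blot {blot_id!r}")
    lanes = sorted(sub["lane_id"].unique())
    proteins = sorted(sub["protein"].unique())
    g = geometry

    width = 2 * g.margin + len(lanes) * g.lane_width + (len(lanes) - 1) * g.lane_gap
    height = 2 * g.margin + len(proteins) * g.band_height + (len(proteins) - 1) * g.row_gap
    # integer background keeps quantization confined to the band signal
    background = int(round(g.background))
    img = np.full((height, width), background, dtype=np.int64)

    rois: list[BandROI] = []
    sigx = g.lane_width / g.sigma_divisor
    sigy = g.band_height / g.sigma_divisor
    yy, xx = np.mgrid[0 : g.band_height, 0 : g.lane_width]
    cx, cy = (g.lane_width - 1) / 2.0, (g.band_height - 1) / 2.0
    bump = np.exp(-0.5 * (((xx - cx) / sigx) ** 2 + ((yy - cy) / sigy) ** 2))
    bump_sum = bump.sum()

    for row in sub.itertuples():
        li = lanes.index(row.lane_id)
        pi = proteins.index(row.protein)
        x0 = g.margin + li * (g.lane_width + g.lane_gap)
        y0 = g.margin + pi * (g.band_height + g.row_gap)
        roi = BandROI(
            blot_id=blot_id,
            protein=row.protein,
            lane_id=row.lane_id,
            x0=x0,
            y0=y0,
            width=g.lane_width,
            height=g.band_height,
        )
        for prev in rois:
            if prev.overlaps(roi):
                raise ValueError(
                    f"duplicate/overlapping band placement at {row.protein}/{row.lane_id}"
                )
        target = float(row.raw_density) * roi.width
        if target > 0:
            scale = target / bump_sum
            if scale + background > 65535:
                raise ValueError(
                    f"band {row.protein}/{row.lane_id} (density {row.raw_density:g}) "
                    "saturates 16-bit depth; enlarge the geometry"
                )
            signal = scale * bump
            quantized = np.round(signal).astype(np.int64)
            # redistribute the rounding deficit so the ROI sum stays exact to
            # +/-0.5 counts even for faint bands with large sub-count tails
            deficit = int(round(target)) - int(quantized.sum())
            if deficit != 0:
                residual = (signal - quantized).ravel()
                order = np.argsort(-residual if deficit > 0 else residual, kind="stable")
                step = 1 if deficit > 0 else -1
                bumped = 0
                flat = quantized.ravel()
                for idx in order:
                    if bumped == abs(deficit):
                        break
                    if step < 0 and flat[idx] <= 0:
                        continue
                    flat[idx] += step
                    bumped += 1
                quantized = flat.reshape(quantized.shape)
            img[y0 : y0 + g.band_height, x0 : x0 + g.lane_width] += quantized
        rois.append(roi)

    return np.clip(img, 0, 65535).astype(np.uint16), rois


def write_band_table(table: SyntheticBandTable | pd.DataFrame, path: str | Path) -> None:
    df = table.table if isinstance(table, SyntheticBandTable) else table
    df.to_csv(path, index=False)


def design_to_dict(design: SyntheticDesign) -> dict:
    """JSON/YAML-ready representation (tuple keys flattened to 'group|protein')."""
    d = dataclasses.asdict(design)
    d["effect"] = {f"{g}|{p}": v for (g, p), v in design.effect.items()}
    d["noise_sd"] = {f"{g}|{p}": v for (g, p), v in design.noise_sd.items()}
    d["groups"] = [list(gp) for gp in design.groups]
    d["proteins"] = list(design.proteins)
    return d
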