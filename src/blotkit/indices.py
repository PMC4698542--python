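"""Contrast indices quantifying receptor-subunit and E/I balances.

A contrast index between two non-negative quantities A and B is
``(A - B) / (A + B)``: a bounded, scale-free balance statistic in [-1, 1]
that is 0 at perfect balance, antisymmetric under swapping A and B, and
invariant to rescaling both inputs.  Five standard definitions pair the
excitatory/inhibitory and mature/immature synaptic markers:

==================  ==========  ==========
index               A           B
==================  ==========  ==========
AMPAR-NMDAR         GluA2       GluN1
NMDAR (2A-2B)       GluN2A      GluN2B
GABAAR (a1-a3)      GABAAa1     GABAAa3
Presynaptic E/I     VGLUT1      VGAT
Postsynaptic E/I    PSD-95      gephyrin
==================  ==========  ==========

Indices are computed per animal (pairing A and B within the same animal),
so group dispersion and the Monte-Carlo comparisons apply to them exactly
as to single proteins; computing on group means is available as an option.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .normalization import NormalizedTable

__all__ = ["DEFAULT_INDEX_DEFINITIONS", "contrast_index", "compute_indices"]

DEFAULT_INDEX_DEFINITIONS: dict[str, tuple[str, str]] = {
    "AMPAR-NMDAR": ("GluA2", "GluN1"),
    "NMDAR (2A-2B)": ("GluN2A", "GluN2B"),
    "GABAAR (a1-a3)": ("GABAAa1", "GABAAa3"),
    "Presynaptic E/I": ("VGLUT1", "VGAT"),
    "Postsynaptic E/I": ("PSD-95", "gephyrin"),
}


def contrast_index(a, b):
    """(a - b) / (a + b) for non-negative a, b with a + b > 0.

    Accepts scalars or arrays (element-wise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("contrast_index inputs must be non-negative")
    total = a + b
    if (total <= 0).any():
        raise ValueError("contrast_index undefined when a + b = 0")
    out = (a - b) / total
    return float(out) if out.ndim == 0 else out


def compute_indices(
    table: NormalizedTable | pd.DataFrame,
    definitions: Mapping[str, tuple[str, str]] | None = None,
    per_animal: bool = True,
) -> pd.DataFrame:
    """Contrast-index values for every animal (or group) and definition.

    Returns a long frame with columns ``measure``, ``animal_id``, ``group``,
    ``value`` (``animal_id`` omitted when ``per_animal=False``, in which case
    the index is computed on group mean expression).
    """
    definitions = DEFAULT_INDEX_DEFINITIONS if definitions is None else dict(definitions)
    df = table.rows if isinstance(table, NormalizedTable) else table
    wide = df.pivot_table(
        index=["animal_id", "group"], columns="protein", values="value", aggfunc="mean"
    )

    records = []
    if per_animal:
        for name, (prot_a, prot_b) in definitions.items():
            for col in (prot_a, prot_b):
                if col not in wide.columns:
                    raise ValueError(f"index {name!r}: protein {col!r} not measured")
                missing = wide.index[wide[col].isna()].get_level_values("animal_id").tolist()
                if missing:
                    raise ValueError(
                        f"index {name!r}: protein {col!r} missing for animals {missing}"
                    )
            values = contrast_index(wide[prot_a].to_numpy(), wide[prot_b].to_numpy())
            for (animal, group), v in zip(wide.index, values):
                records.append(
                    {"measure": name, "animal_id": animal, "group": group, "value": float(v)}
                )
        return pd.DataFrame.from_records(
            records, columns=["measure", "animal_id", "group", "value"]
        )

    group_means = df.groupby(["group", "protein"])["value"].mean().unstack("protein")
    for name, (prot_a, prot_b) in definitions.items():
        for col in (prot_a, prot_b):
            if col not in group_means.columns or group_means[col].isna().any():
                raise ValueError(f"index {name!r}: protein {col!r} not measured in every group")
        values = contrast_index(group_means[prot_a].to_numpy(), group_means[prot_b].to_numpy())
        for group, v in zip(group_means.index, values):
            records.append({"measure": name, "group": group, "value": float(v)})
    return pd.DataFrame.from_records(records, columns=["measure", "group", "value"])
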