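"""Connector-hub registries: printed per-condition hub tables as data.

Each registry row records one connector hub: its subunit id in the
278-parcel whole-brain atlas (the authoritative key; per-table node
numbers differ between conditions), optional Brodmann and AAL labels,
and Talairach coordinates.  The packaged tables list the hubs reported
for the positive (31), negative (42) and neutral (23) picture
conditions; set algebra over the three gives 65 distinct hubs of which
11 are shared by all conditions, all in the left hemisphere
(Talairach x < 0).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "HubRegistry",
    "load_hub_registry",
    "packaged_table_paths",
    "CONDITIONS",
]

CONDITIONS = ("positive", "negative", "neutral")
_COLUMNS = ["node", "subunit", "ba", "aal", "tal_x", "tal_y", "tal_z", "condition"]


class HubRegistry:
    """Per-condition connector-hub tables with set-algebra helpers."""

    def __init__(self, table: pd.DataFrame):
        missing = set(_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"registry table missing columns: {sorted(missing)}")
        for cond, sub in table.groupby("condition"):
            dup = sub[sub.subunit.duplicated()]
            if len(dup):
                raise ValueError(
                    f"duplicate subunit id(s) {sorted(dup.subunit)} in "
                    f"condition {cond!r}"
                )
        coords = table[["tal_x", "tal_y", "tal_z"]]
        if coords.isna().any().any():
            bad = table.loc[coords.isna().any(axis=1), "subunit"].tolist()
            raise ValueError(f"malformed Talairach coordinates for subunits {bad}")
        self.table = table.reset_index(drop=True)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table.condition.unique())

    def subunits(self, condition: str) -> frozenset[int]:
        return frozenset(self.table.loc[self.table.condition == condition, "subunit"])

    def counts(self) -> dict[str, int]:
        return {c: len(self.subunits(c)) for c in self.conditions}

    def union(self) -> frozenset[int]:
        sets = [self.subunits(c) for c in self.conditions]
        return frozenset().union(*sets) if sets else frozenset()

    def shared(self) -> frozenset[int]:
        """Subunits present in every condition's table."""
        sets = [self.subunits(c) for c in self.conditions]
        return frozenset.intersection(*sets) if sets else frozenset()

    def hemisphere_split(self, subunits) -> dict[str, int]:
        """Left/right counts by the sign of Talairach x."""
        rows = self.table.drop_duplicates("subunit")
        rows = rows[rows.subunit.isin(set(subunits))]
        return {"left": int((rows.tal_x < 0).sum()),
                "right": int((rows.tal_x > 0).sum())}


def load_hub_registry(csv_paths: dict[str, str | Path]) -> HubRegistry:
    """Load per-condition hub-table CSVs into one validated registry.

    Parameters
    ----------
    csv_paths : mapping condition -> CSV path
        Each file needs the header
        ``node,subunit,ba,aal,tal_x,tal_y,tal_z,condition``.
    """
    frames = []
    for cond, path in csv_paths.items():
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path, dtype={"ba": "string", "aal": "string"})
        df["condition"] = df["condition"].fillna(cond)
        if not (df["condition"] == cond).all():
            raise ValueError(
                f"{path} declares conditions {sorted(df.condition.unique())}, "
                f"expected {cond!r}"
            )
        for col in ("tal_x", "tal_y", "tal_z"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return HubRegistry(table)


def packaged_table_paths() -> dict[str, Path]:
    """Paths of the hub tables shipped with the package."""
    base = resources.files("chronnect") / "data" / "hub_tables"
    return {c: Path(str(base / f"{c}.csv")) for c in CONDITIONS}
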