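"""Sample design table: condition / time / replicate annotation per sample."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

VALID_CONDITIONS = ("M0", "M1", "M2")
POLARIZED = ("M1", "M2")


@dataclass(frozen=True)
class SampleDesign:
    """Ordered sample annotation for a polarization time course.

    Wraps a DataFrame with columns ``sample_id``, ``condition`` (M0/M1/M2),
    ``time_h`` (positive real) and ``replicate`` (small integer).  M1 and M2
    must share the same set of time points so that time-paired contrasts are
    well defined; M0 samples are unstimulated controls and may sit at a
    single time point.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "condition", "time_h", "replicate"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        t = self.table
        dup = t["sample_id"][t["sample_id"].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate sample ids in design: {dup}")
        bad = sorted(set(t["condition"]) - set(VALID_CONDITIONS))
        if bad:
            raise ValueError(f"unknown conditions {bad}; expected one of {VALID_CONDITIONS}")
        if (t["time_h"] <= 0).any():
            raise ValueError("time_h must be positive")
        tp_m1 = set(t.loc[t.condition == "M1", "time_h"])
        tp_m2 = set(t.loc[t.condition == "M2", "time_h"])
        if tp_m1 != tp_m2:
            raise ValueError(
                f"M1 and M2 must share time points; M1 has {sorted(tp_m1)}, M2 has {sorted(tp_m2)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def timepoints(self) -> list[float]:
        """Sorted polarized time points shared by M1 and M2."""
        return sorted(set(self.table.loc[self.table.condition == "M1", "time_h"]))

    def polarized(self) -> "SampleDesign":
        """Sub-design restricted to M1/M2 samples (M0 controls dropped)."""
        sub = self.table[self.table.condition.isin(POLARIZED)].reset_index(drop=True)
        return SampleDesign(sub)

    def samples(self, condition: str, time_h: float | None = None) -> list[str]:
        t = self.table
        mask = t.condition == condition
        if time_h is not None:
            mask &= t.time_h == time_h
        return list(t.loc[mask, "sample_id"])

    def reorder(self, sample_ids: list[str]) -> "SampleDesign":
        sub = self.table.set_index("sample_id").loc[sample_ids].reset_index()
        return SampleDesign(sub)

    def __len__(self) -> int:
        return len(self.table)
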