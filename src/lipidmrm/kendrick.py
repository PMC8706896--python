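"""Kendrick mass defect (CH2 base) annotation checks.

Rescaling m/z so that CH2 has integer mass 14 makes acyl-chain homologs
share a mass defect: within one class, species with the same double-bond
count line up at the same KMD (a horizontal line in a KMD-vs-RT plot)
while species with the same carbon number fall on a common diagonal.  In
reversed-phase separation the retention time grows with carbon number
and shrinks with unsaturation, so mis-annotated transitions betray
themselves either by an off-grid KMD (e.g. a 13C isotope mis-pick,
+1.00335 Da, shifts the CH2-based KMD by 0.0022) or by breaking the
retention-time ordering of their homolog series.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

KENDRICK_FACTOR = 14.0 / 14.01565

PASS = "pass"
DIAGONAL = "diagonal_violation"
HORIZONTAL = "horizontal_violation"

__all__ = ["kendrick", "KendrickPoint", "grid_check", "PASS", "DIAGONAL", "HORIZONTAL"]


def kendrick(mz: float) -> tuple[float, float]:
    """Kendrick mass and mass defect of an m/z value (CH2 base).

    KM = mz * 14 / 14.01565; KMD = nearest_integer(KM) - KM.
    """
    if mz <= 0:
        raise ValueError(f"non-positive m/z: {mz}")
    km = mz * KENDRICK_FACTOR
    kmd = round(km) - km
    return km, kmd


@dataclass(frozen=True)
class KendrickPoint:
    transition_id: str
    mz: float
    rt: float  # minutes
    lipid_class: str
    total_carbons: int
    total_double_bonds: int


def grid_check(
    points: list[KendrickPoint] | pd.DataFrame,
    rt_tolerance: float = 0.05,
    kmd_tolerance: float = 0.002,
) -> pd.DataFrame:
    """Flag annotation outliers from the KMD/RT grid structure.

    Within each (class, total double bonds) series the KMD must be
    constant to ``kmd_tolerance`` (deviation from the series median flags
    a ``horizontal_violation``) and the retention time must increase with
    carbon number; within each (class, total carbons) series the
    retention time must decrease with double-bond count.  Retention-time
    inversions larger than ``rt_tolerance`` minutes flag both members of
    the offending adjacent pair as ``diagonal_violation``.  Series with
    fewer than three members pass by default and carry a note.

    Returns a DataFrame with km/kmd columns, a ``flag`` per point and a
    ``note`` column.  Duplicate (class, C, DB) entries raise (the grid
    position would be ambiguous).
    """
    if isinstance(points, pd.DataFrame):
        df = points.copy()
    else:
        df = pd.DataFrame([vars(p) for p in points])
    required = {"transition_id", "mz", "rt", "lipid_class",
                "total_carbons", "total_double_bonds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    dup = df.duplicated(["lipid_class", "total_carbons", "total_double_bonds"])
    if dup.any():
        bad = df.loc[dup, ["lipid_class", "total_carbons", "total_double_bonds"]]
        raise ValueError(f"duplicate grid entries (ambiguous):\n{bad}")

    km_kmd = df["mz"].map(kendrick)
    df["km"] = [v[0] for v in km_kmd]
    df["kmd"] = [v[1] for v in km_kmd]
    df["flag"] = PASS
    df["note"] = ""

    def _mark(idx, flag):
        # first violation wins; never downgrade an existing flag
        idx = [i for i in idx if df.at[i, "flag"] == PASS]
        df.loc[idx, "flag"] = flag

    def _rt_inversions(sub: pd.DataFrame, sign: int) -> list:
        """Indices breaking monotone RT order (+1 increasing, -1 decreasing)."""
        bad = []
        rts = sub["rt"].to_numpy()
        for i in range(len(rts) - 1):
            if sign * (rts[i + 1] - rts[i]) < -rt_tolerance:
                bad.extend(sub.index[[i, i + 1]])
        return bad

    # horizontal lines: same class, same DB; KMD constant, RT up with C
    for _, sub in df.groupby(["lipid_class", "total_double_bonds"]):
        if len(sub) < 3:
            idx = sub.index[df.loc[sub.index, "note"] == ""]
            df.loc[idx, "note"] = "short-series"
            continue
        sub = sub.sort_values("total_carbons")
        dev = (sub["kmd"] - sub["kmd"].median()).abs()
        _mark(dev.index[dev > kmd_tolerance], HORIZONTAL)
        _mark(_rt_inversions(sub, +1), DIAGONAL)

    # diagonals: same class, same C; RT down with DB
    for _, sub in df.groupby(["lipid_class", "total_carbons"]):
        if len(sub) < 3:
            if (df.loc[sub.index, "note"] == "").all():
                df.loc[sub.index, "note"] = "short-series"
            continue
        sub = sub.sort_values("total_double_bonds")
        _mark(_rt_inversions(sub, -1), DIAGONAL)

    return df
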