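"""Conduit-level derived metrics.

Thickness-to-span ratio (t/b)^2 — the squared ratio of the double wall
thickness to the lumen span, quantifying the wall's resistance to bending
collapse; Mork's index and the earlywood/latewood classification it defines;
the conductivity-weighted hydraulic diameter; and per-organ summary tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import ORGANS

__all__ = [
    "thickness_to_span",
    "mork_index",
    "classify_wood",
    "hydraulic_diameter",
    "conduit_metrics",
    "organ_summary",
]

_WALL_COLS = ["wall_rad1_um", "wall_rad2_um", "wall_tan1_um", "wall_tan2_um"]


def thickness_to_span(wall_rad1, wall_rad2, wall_tan1, wall_tan2, span):
    """(t/b)^2 from four single-wall thicknesses and the lumen span (all um).

    The double wall thickness t is twice the smallest single wall (the wall
    most susceptible to collapse); the span b paired with it is taken as the
    circular-equivalent lumen diameter. Accepts scalars or aligned arrays.
    """
    walls = np.stack(np.broadcast_arrays(
        np.asarray(wall_rad1, float), np.asarray(wall_rad2, float),
        np.asarray(wall_tan1, float), np.asarray(wall_tan2, float)))
    span = np.asarray(span, float)
    if np.any(walls <= 0) or np.any(span <= 0):
        raise ValueError("wall thicknesses and span must be strictly positive")
    t = 2.0 * walls.min(axis=0)
    out = (t / span) ** 2
    return out if out.ndim else float(out)


def mork_index(x_tan, d_rad):
    """Mork's index M = 4 * x_tan / d_rad.

    ``x_tan`` is the mean tangential single-wall thickness and ``d_rad`` the
    radial lumen diameter (both um). The factor of 4 accounts for the two
    double walls a radial file of tracheids shares across the lumen.
    """
    x_tan = np.asarray(x_tan, float)
    d_rad = np.asarray(d_rad, float)
    if np.any(x_tan <= 0) or np.any(d_rad <= 0):
        raise ValueError("x_tan and d_rad must be strictly positive")
    out = 4.0 * x_tan / d_rad
    return out if out.ndim else float(out)


def classify_wood(M):
    """Latewood iff M > 1; the tie M == 1 counts as earlywood."""
    M = np.asarray(M, float)
    out = np.where(M > 1.0, "latewood", "earlywood")
    return out if out.ndim else str(out)


def hydraulic_diameter(diameters) -> float:
    """Hydraulic diameter d_h = sum(d^5) / sum(d^4) of a conduit population.

    A conductivity-weighted mean: always between min and max and never below
    the arithmetic mean, because wider (earlywood) conduits dominate flow.
    """
    d = np.asarray(diameters, float)
    if d.size == 0:
        raise ValueError("empty diameter collection")
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("diameters must be finite and strictly positive")
    # rescale for numerical stability at high powers
    s = d / d.max()
    return float(d.max() * (s**5).sum() / (s**4).sum())


def conduit_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Append derived per-conduit columns: tb2, mork_M, wood_type, L_rel.

    ``wood_type`` is recomputed from Mork's index when the input column is
    absent; when present it is kept as measured.
    """
    df = records.copy()
    df["tb2"] = thickness_to_span(
        df["wall_rad1_um"].to_numpy(), df["wall_rad2_um"].to_numpy(),
        df["wall_tan1_um"].to_numpy(), df["wall_tan2_um"].to_numpy(),
        df["d_um"].to_numpy())
    x_tan = 0.5 * (df["wall_tan1_um"].to_numpy() + df["wall_tan2_um"].to_numpy())
    df["mork_M"] = mork_index(x_tan, df["d_rad_um"].to_numpy())
    if "wood_type" not in df.columns or df["wood_type"].isna().all():
        df["wood_type"] = classify_wood(df["mork_M"].to_numpy())
    df["L_rel"] = df["L_m"] / df["H_m"]
    bad = ~((df["L_rel"] > 0) & (df["L_rel"] <= 1))
    if bad.any():
        raise ValueError(f"L_rel outside (0, 1] for rows {list(df.index[bad][:10])}")
    return df


def organ_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-organ table of n, mean/median d and (t/b)^2, and wood-type counts.

    Organs are emitted in axial order (leaf first, very fine root last);
    organ classes absent from the input are omitted rather than zero-filled.
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    df = records if "tb2" in records.columns else conduit_metrics(records)
    rows = []
    for organ in ORGANS:
        sub = df[df["organ"] == organ]
        if len(sub) == 0:
            continue
        wt = sub["wood_type"].astype(str)
        rows.append({
            "organ": organ,
            "n": int(len(sub)),
            "mean_d_um": float(sub["d_um"].mean()),
            "median_d_um": float(sub["d_um"].median()),
            "mean_tb2": float(sub["tb2"].mean()),
            "median_tb2": float(sub["tb2"].median()),
            "n_earlywood": int((wt == "earlywood").sum()),
            "n_latewood": int((wt == "latewood").sum()),
        })
    return pd.DataFrame(rows)
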