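"""Combined ¹H/¹⁵N chemical-shift-difference profiles.

Localises binding/release along a protein sequence from two peak lists
(e.g. free vs complex-bound) using the standard weighted combination

    Δδ = [(Δδ¹H_N)² + 0.0289·(Δδ¹⁵N_H)²]^(1/2),

where 0.0289 ≈ (0.17)² rescales the nitrogen dimension to the proton
chemical-shift range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["load_peak_table", "combined_shift_profile", "NITROGEN_WEIGHT"]

NITROGEN_WEIGHT = 0.0289

_REQUIRED = ("residue", "dH_ppm", "dN_ppm")


def load_peak_table(path_or_df, condition: str | None = None) -> pd.DataFrame:
    """Load a peak list (CSV with residue, dH_ppm, dN_ppm [, condition])."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"peak table missing columns {missing}")
    if df["residue"].duplicated().any():
        raise ValueError("duplicate residues in peak table")
    if condition is not None:
        df = df.assign(condition=condition)
    return df


def combined_shift_profile(free, bound) -> pd.DataFrame:
    """Per-residue combined chemical-shift difference between two states.

    Only residues assigned in both tables get a Δδ; residues present in
    one table only are reported with Δδ = NaN (missing, never
    zero-filled).  Raises when the tables share no residues.
    """
    free = load_peak_table(free)
    bound = load_peak_table(bound)
    merged = free.merge(bound, on="residue", how="outer",
                        suffixes=("_free", "_bound"), sort=True)
    both = merged["dH_ppm_free"].notna() & merged["dH_ppm_bound"].notna()
    if not both.any():
        raise ValueError("peak tables share no residues")
    ddH = merged["dH_ppm_bound"] - merged["dH_ppm_free"]
    ddN = merged["dN_ppm_bound"] - merged["dN_ppm_free"]
    dd = np.sqrt(ddH ** 2 + NITROGEN_WEIGHT * ddN ** 2)
    out = pd.DataFrame({
        "residue": merged["residue"],
        "delta_delta": dd.where(both),
        "ddH_ppm": ddH.where(both),
        "ddN_ppm": ddN.where(both),
        "missing": ~both,
    })
    return out.reset_index(drop=True)
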