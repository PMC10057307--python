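"""Binding-kinetics arithmetic for selected clones.

The equilibrium dissociation constant of a 1:1 interaction is
``K_D = k_d / k_a`` (molar), with ``k_a`` the association rate constant
(1/(M*s)) and ``k_d`` the dissociation rate constant (1/s).  Values are
reported to 3 significant figures; when an expected K_D column is supplied,
computed values deviating by more than 0.2% (beyond printed-value rounding)
are flagged.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = ["equilibrium_kd", "process_kinetics_table", "DISCREPANCY_THRESHOLD"]

DISCREPANCY_THRESHOLD = 0.002  # relative


def round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def equilibrium_kd(ka: float, kd: float) -> float:
    """K_D = kd / ka in molar units, rounded to 3 significant figures."""
    if ka <= 0:
        raise ValueError(f"ka must be positive, got {ka}")
    if kd < 0:
        raise ValueError(f"kd must be non-negative, got {kd}")
    return round_sig(kd / ka, 3)


def process_kinetics_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a computed ``KD`` column to a (clone_id, ka, kd) table.

    An optional ``KD_expected`` column triggers a relative-difference check;
    rows deviating by more than 0.2% are flagged in ``discrepant``.
    """
    required = {"clone_id", "ka", "kd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"kinetics table lacks columns {sorted(missing)}")
    out = df.copy()
    out["KD"] = [equilibrium_kd(ka, kd) for ka, kd in zip(out["ka"], out["kd"])]
    if "KD_expected" in out.columns:
        rel = (out["KD"] - out["KD_expected"]).abs() / out["KD_expected"]
        out["rel_difference"] = rel
        out["discrepant"] = rel > DISCREPANCY_THRESHOLD
    return out
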