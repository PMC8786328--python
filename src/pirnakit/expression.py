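"""Expression screening: CPM normalization, per-sample z-score screening,
abundance ranking, and anticorrelation pairing for target prediction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionProfile",
    "cpm_normalize",
    "zscore_screen",
    "top_abundant",
    "anticorrelated_pairs",
    "profile_expression",
    "read_counts",
    "read_de_table",
]

DE_COLUMNS = ("id", "log2fc", "direction", "kind")


def read_counts(path) -> pd.DataFrame:
    """Read a TSV count matrix (rows = piRNA ids, columns = samples)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts.values < 0).any():
        raise ValueError("count matrix contains negative entries")
    return counts


def read_de_table(path) -> pd.DataFrame:
    """Read a differential-expression summary table and validate that
    each direction matches the sign of its log2 fold change."""
    de = pd.read_csv(path, sep="\t")
    missing = set(DE_COLUMNS) - set(de.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    bad = de[
        ((de["direction"] == "up") & (de["log2fc"] < 0))
        | ((de["direction"] == "down") & (de["log2fc"] > 0))
    ]
    if len(bad):
        raise ValueError(
            f"direction inconsistent with log2fc sign for ids: "
            f"{bad['id'].tolist()[:5]}"
        )
    return de


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: each column scaled to sum to 1e6."""
    if (counts.values < 0).any():
        raise ValueError("count matrix contains negative entries")
    colsums = counts.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(
            f"zero library size for sample(s): {list(zero.index)}"
        )
    return counts / colsums * 1e6


def zscore_screen(
    values: pd.Series | np.ndarray,
    z_min: float = -3.0,
    z_max: float = 3.0,
    expressed_only: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each value within a sample and retain those in [z_min, z_max].

    Z-scores are computed over the expressed entries (value > 0) by
    default; unexpressed entries get z = NaN and are not retained. With a
    zero-variance column every expressed entry is retained (z = 0) with a
    warning. Returns ``(z, retained)`` aligned with the input.
    """
    x = np.asarray(values, dtype=float)
    mask = x > 0 if expressed_only else np.ones_like(x, dtype=bool)
    z = np.full(x.shape, np.nan)
    retained = np.zeros(x.shape, dtype=bool)
    expressed = x[mask]
    if expressed.size < 2:
        raise ValueError("need >= 2 expressed values to z-score")
    sd = expressed.std(ddof=0)
    if sd == 0:
        warnings.warn("zero variance; all expressed values retained with z=0",
                      stacklevel=2)
        z[mask] = 0.0
        retained[mask] = True
        return z, retained
    z[mask] = (expressed - expressed.mean()) / sd
    retained[mask] = (z[mask] >= z_min) & (z[mask] <= z_max)
    return z, retained


def top_abundant(cpm: pd.Series, n: int = 200) -> pd.Series:
    """Top-n expressed piRNAs by CPM, descending; ties broken by id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    expressed = cpm[cpm > 0]
    order = sorted(expressed.index, key=lambda i: (-expressed[i], i))
    return expressed.loc[order[:n]]


@dataclass
class ExpressionProfile:
    """CPM values with per-sample z-scores and the retained mask."""

    cpm: pd.DataFrame
    zscore: pd.DataFrame
    retained: pd.DataFrame


def profile_expression(
    counts: pd.DataFrame, z_min: float = -3.0, z_max: float = 3.0
) -> ExpressionProfile:
    """CPM-normalize then z-screen every sample column."""
    cpm = cpm_normalize(counts)
    z = pd.DataFrame(index=cpm.index, columns=cpm.columns, dtype=float)
    retained = pd.DataFrame(False, index=cpm.index, columns=cpm.columns)
    for col in cpm.columns:
        zc, rc = zscore_screen(cpm[col], z_min, z_max)
        z[col] = zc
        retained[col] = rc
    return ExpressionProfile(cpm, z, retained)


def anticorrelated_pairs(
    pirna_de: pd.DataFrame, target_de: pd.DataFrame
) -> pd.DataFrame:
    """Candidate (piRNA, target) pairs with opposite regulation:
    up piRNAs x down targets, plus down piRNAs x up targets."""
    rows = []
    for p_dir, t_dir in (("up", "down"), ("down", "up")):
        pirnas = pirna_de.loc[pirna_de["direction"] == p_dir, "id"]
        targets = target_de[target_de["direction"] == t_dir]
        for pid in pirnas:
            for _, trow in targets.iterrows():
                rows.append(
                    {
                        "pirna_id": pid,
                        "target_id": trow["id"],
                        "pirna_direction": p_dir,
                        "target_direction": t_dir,
                        "target_kind": trow.get("kind", "mRNA"),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "pirna_id",
            "target_id",
            "pirna_direction",
            "target_direction",
            "target_kind",
        ],
    )
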