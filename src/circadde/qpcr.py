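"""RT-qPCR crossing-point processing and reference-gene normalization.

Cp values are converted to relative quantities with per-primer
amplification efficiencies (quantity proportional to E^(-Cp), E close
to 2 for a perfect doubling per cycle), then each sample's target
quantities are divided by the geometric mean of the three constant
reference genes (Hmbs, Eif2A, Ppib).  Quantities are relative within a
gene; cross-gene absolute comparisons are deliberately unsupported.
Technical replicates are assumed pre-averaged upstream; the table
models biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cosinor import TimeSeries

__all__ = ["QpcrTable", "cp_to_quantity", "reference_normalize",
           "aggregate_replicates", "DEFAULT_REFERENCE_GENES"]

DEFAULT_REFERENCE_GENES = ("Hmbs", "Eif2A", "Ppib")


def cp_to_quantity(cp, efficiency: float):
    """Relative quantity from a crossing point: efficiency**(-cp).

    ``efficiency`` is the fold amplification per cycle, in (1, 2];
    only ratios within one gene are meaningful (one cycle difference at
    E = 2 means a two-fold quantity ratio)."""
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("primer efficiency must lie in (1, 2]")
    return np.asarray(efficiency, float) ** (-np.asarray(cp, float))


@dataclass
class QpcrTable:
    """Cp-level records with primer efficiencies and reference flags.

    ``data`` columns: gene, time_h, replicate, cp.
    """

    data: pd.DataFrame
    efficiencies: dict[str, float]
    reference_genes: tuple = DEFAULT_REFERENCE_GENES

    def __post_init__(self):
        need = {"gene", "time_h", "replicate", "cp"}
        if not need <= set(self.data.columns):
            raise ValueError(f"table must have columns {sorted(need)}")
        if (self.data["cp"] <= 0).any():
            raise ValueError("Cp values must be positive")
        for g in self.data["gene"].unique():
            if g not in self.efficiencies:
                raise ValueError(f"missing primer efficiency for {g}")
            e = self.efficiencies[g]
            if not 1.0 < e <= 2.0:
                raise ValueError(f"efficiency of {g} out of (1, 2]: {e}")

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.data["gene"].unique()
                if g not in self.reference_genes]

    def to_csv(self, path):
        self.data.to_csv(path, index=False)


def reference_normalize(table: QpcrTable) -> pd.DataFrame:
    """Per-sample normalization by the reference-gene geometric mean.

    Every (time, replicate) sample must contain all reference genes;
    the result has columns gene, time_h, replicate, value where value
    is the target quantity divided by that sample's normalization
    factor.  Multiplying all of a sample's quantities by a constant
    leaves the output unchanged (scale invariance).
    """
    df = table.data.copy()
    df["quantity"] = [
        float(cp_to_quantity(cp, table.efficiencies[g]))
        for g, cp in zip(df["gene"], df["cp"])]
    refs = df[df["gene"].isin(table.reference_genes)]
    norm = (refs.groupby(["time_h", "replicate"])["quantity"]
            .apply(lambda q: float(np.exp(np.mean(np.log(q)))))
            .rename("norm_factor"))
    counts = refs.groupby(["time_h", "replicate"])["gene"].nunique()
    bad = counts[counts < len(table.reference_genes)]
    targets = df[~df["gene"].isin(table.reference_genes)]
    missing = (set(map(tuple, targets[["time_h", "replicate"]]
                       .drop_duplicates().to_numpy()))
               - set(norm.index))
    if len(bad) or missing:
        samples = sorted(set(bad.index) | missing)
        raise ValueError(
            f"samples missing reference genes: {samples[:10]}")
    out = targets.merge(norm, on=["time_h", "replicate"])
    out["value"] = out["quantity"] / out["norm_factor"]
    return out[["gene", "time_h", "replicate", "value"]].reset_index(drop=True)


def aggregate_replicates(records: pd.DataFrame, gene: str | None = None):
    """Per-time mean, SD and n of normalized records.

    Returns (summary DataFrame, TimeSeries of raw records) so the raw
    replicate-level data stay available for the regression stage.  SD
    is NaN for a single replicate.
    """
    df = records if gene is None else records[records["gene"] == gene]
    if df.empty:
        raise ValueError("no records to aggregate")
    summary = (df.groupby(["gene", "time_h"])["value"]
               .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
               .reset_index())
    series = None
    if gene is not None:
        series = TimeSeries(gene, df["time_h"].to_numpy(),
                            df["value"].to_numpy(),
                            df["replicate"].to_numpy())
    return summary, series
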