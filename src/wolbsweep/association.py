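"""Survey statistics: infection x haplotype association in individual-level data.

Under strict maternal co-inheritance every doubly infected fly should carry
the haplotype that hitchhiked with the invading strain (HT2), and every
singly infected fly the resident HT1.  The interesting quantities are the
*mismatch* proportions -- doubly infected flies on HT1, singly infected on
HT2 -- stratified by zone, collection period or host plant, with Fisher's
exact test for contrasts between strata.

Records are plain pandas rows with categorical columns; individuals with an
untyped haplotype enter infection-frequency denominators but are excluded
(and counted) from haplotype denominators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COLUMNS",
    "PERIODS",
    "ZONES",
    "HOST_PLANTS",
    "INFECTIONS",
    "HAPLOTYPES",
    "AssociationSummary",
    "validate_records",
    "summarize",
    "fisher_exact",
    "host_plant_contrast",
    "round_half_up",
]

logger = logging.getLogger(__name__)

COLUMNS = ("population", "period", "zone", "host_plant", "infection", "haplotype")
PERIODS = ("1998/1999", "2000/2001", "2008", "2014")
ZONES = ("fixed", "transition")
HOST_PLANTS = ("Prunus", "Lonicera", "unknown")
INFECTIONS = ("single", "double")
HAPLOTYPES = ("HT1", "HT2", "untyped")

_LEVELS = {
    "period": PERIODS,
    "zone": ZONES,
    "host_plant": HOST_PLANTS,
    "infection": INFECTIONS,
    "haplotype": HAPLOTYPES,
}


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (21.875 -> 21.9 at one decimal)."""
    if math.isnan(value):
        return value
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check columns and categorical levels; returns the frame unchanged."""
    missing = [c for c in COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing columns: {missing}")
    for col, levels in _LEVELS.items():
        bad = set(records[col].unique()) - set(levels)
        if bad:
            raise ValueError(f"column {col!r} has unknown levels: {sorted(bad)}")
    return records


@dataclass(frozen=True)
class AssociationSummary:
    """Counts and mismatch percentages for one stratum.

    ``n_double_typed``/``n_single_typed`` are the haplotype denominators
    (untyped individuals excluded); percentages are NaN when the
    denominator is empty.
    """

    stratum: tuple
    n: int
    n_double: int
    n_single: int
    n_double_typed: int
    n_single_typed: int
    n_double_ht1: int
    n_single_ht2: int

    @property
    def pct_double_ht1(self) -> float:
        if self.n_double_typed == 0:
            return math.nan
        return 100.0 * self.n_double_ht1 / self.n_double_typed

    @property
    def pct_single_ht2(self) -> float:
        if self.n_single_typed == 0:
            return math.nan
        return 100.0 * self.n_single_ht2 / self.n_single_typed

    def as_row(self) -> dict:
        return {
            "n": self.n,
            "n_double": self.n_double,
            "n_single": self.n_single,
            "n_double_typed": self.n_double_typed,
            "n_single_typed": self.n_single_typed,
            "n_double_HT1": self.n_double_ht1,
            "n_single_HT2": self.n_single_ht2,
            "pct_double_HT1": round_half_up(self.pct_double_ht1),
            "pct_single_HT2": round_half_up(self.pct_single_ht2),
        }


def _summarize_group(stratum: tuple, g: pd.DataFrame) -> AssociationSummary:
    double = g["infection"] == "double"
    typed = g["haplotype"] != "untyped"
    n_untyped = int((~typed).sum())
    if n_untyped:
        logger.info("stratum %s: %d untyped individuals excluded from haplotype denominators",
                    stratum, n_untyped)
    return AssociationSummary(
        stratum=stratum,
        n=len(g),
        n_double=int(double.sum()),
        n_single=int((~double).sum()),
        n_double_typed=int((double & typed).sum()),
        n_single_typed=int((~double & typed).sum()),
        n_double_ht1=int((double & (g["haplotype"] == "HT1")).sum()),
        n_single_ht2=int((~double & (g["haplotype"] == "HT2")).sum()),
    )


def summarize(records: pd.DataFrame, strata: list[str] | None = None) -> pd.DataFrame:
    """Association summary per stratum, in deterministic stratum order.

    ``strata`` is a list of record columns (e.g. ``["zone", "period"]``);
    ``None`` or ``[]`` pools everything into a single stratum.  Output is a
    tidy frame indexed by the stratum columns.
    """
    validate_records(records)
    if not strata:
        summ = _summarize_group(("all",), records)
        return pd.DataFrame([summ.as_row()], index=pd.Index(["all"], name="stratum"))
    unknown = [s for s in strata if s not in COLUMNS]
    if unknown:
        raise KeyError(f"unknown stratum fields: {unknown}")
    rows, keys = [], []
    for key, g in records.groupby(list(strata), sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        rows.append(_summarize_group(key, g).as_row())
        keys.append(key)
    index = pd.MultiIndex.from_tuples(keys, names=strata)
    if len(strata) == 1:
        index = index.get_level_values(0)
    return pd.DataFrame(rows, index=index)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table of counts.

    Returns ``(odds_ratio, p)``.  The p-value is the exact hypergeometric
    two-sided probability (sum over tables whose probability does not
    exceed the observed one).  The odds ratio is the sample odds ratio
    with Haldane's 0.5 continuity value added to every cell; it is purely
    descriptive and plays no role in the p-value.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("a margin of the table is zero")
    p = float(stats.fisher_exact(t, alternative="two-sided").pvalue)
    a, b, c, d = (float(v) + 0.5 for v in t.ravel())
    return (a * d) / (b * c), p


def host_plant_contrast(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Mismatch among doubly infected flies per host plant, plus Fisher p.

    Only doubly infected, haplotyped individuals with a known host plant
    enter; both host-plant classes must be present.
    """
    validate_records(records)
    sel = records[
        (records["infection"] == "double")
        & (records["haplotype"] != "untyped")
        & (records["host_plant"] != "unknown")
    ]
    present = set(sel["host_plant"].unique())
    absent = {"Prunus", "Lonicera"} - present
    if absent:
        raise ValueError(f"host-plant class absent from records: {sorted(absent)}")
    summary = summarize(sel, ["host_plant"])
    table = [
        [
            int(summary.loc[plant, "n_double_HT1"]),
            int(summary.loc[plant, "n_double_typed"] - summary.loc[plant, "n_double_HT1"]),
        ]
        for plant in ("Lonicera", "Prunus")
    ]
    _, p = fisher_exact(table)
    return summary, p
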