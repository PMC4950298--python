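"""Synthetic survey data and sequence fixtures.

Everything the analysis consumes can be generated here, with the
statistical structure the field data are assumed to have: a logistic
double-infection cline along a north-south transect (the travelling-wave
profile), elevated infection-haplotype mismatch inside a declared
transition interval, rare maternal-transmission leakage outside it, and a
pair of COI-like amplicons that differ at a single transition which
creates/destroys the diagnostic HaeIII site.

``paper_fixtures`` bundles deterministic individual-level tables whose
stratum counts reproduce the published survey margins exactly; the
within-stratum allocation (e.g. host plant by period) is arbitrary where
the margins do not determine it, and sorted for determinism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .association import COLUMNS, validate_records
from .wave import KM_PER_DEGREE_LAT, PopulationSite

__all__ = [
    "SiteSpec",
    "SurveyDesign",
    "SurveyTable",
    "generate_survey",
    "generate_fixture_amplicons",
    "paper_fixtures",
    "logistic_cline",
]

_LN19 = math.log(19.0)  # logistic scale: p=0.95 at half the 5-95% width


def logistic_cline(position_km, centre_km: float, width_km: float):
    """Logistic frequency profile whose 5-95% range spans ``width_km``."""
    z = 2.0 * _LN19 * (np.asarray(position_km, dtype=float) - centre_km) / width_km
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class SiteSpec:
    """One survey site on the transect; ``freq`` overrides the cline model
    (e.g. with a frequency taken from a model trajectory)."""

    site: str
    position_km: float
    period: str = "2008"
    host_plant: str = "unknown"
    n: int = 0
    freq: float | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.freq is not None and not 0.0 <= self.freq <= 1.0:
            raise ValueError("freq must be in [0, 1]")


@dataclass(frozen=True)
class SurveyDesign:
    """Sampling design for a synthetic survey.

    The double-infection frequency follows a logistic cline in transect
    position (centre/width in km) unless a site carries an explicit
    ``freq``.  Doubly infected individuals carry the resident HT1 with
    probability ``p_mismatch_inside`` within the transition interval and
    ``p_mismatch_outside`` elsewhere; singly infected individuals carry
    HT2 with probability ``p_single_ht2`` (maternal-transmission leakage).
    """

    sites: tuple[SiteSpec, ...]
    cline_centre_km: float
    cline_width_km: float
    transition_interval: tuple[float, float]
    p_mismatch_inside: float = 0.2
    p_mismatch_outside: float = 0.015
    p_single_ht2: float = 0.005
    seed: int = 0
    origin_lat: float = 47.0
    origin_lon: float = 9.0

    def __post_init__(self) -> None:
        for name in ("p_mismatch_inside", "p_mismatch_outside", "p_single_ht2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if not self.cline_width_km > 0:
            raise ValueError("cline_width_km must be > 0")

    @classmethod
    def transect(
        cls,
        sigma_km: float,
        l_ci: float = 0.98,
        n_sites: int = 25,
        n_per_site: int = 40,
        span_factor: float = 3.0,
        seed: int = 0,
        **kwargs,
    ) -> "SurveyDesign":
        """Evenly spaced transect across a wave of known dispersal sigma.

        The cline width follows the travelling-wave relation
        ``3 * sigma / sqrt(l_ci)``; the transect spans ``span_factor``
        widths so both tails are sampled, and the transition interval is
        the central 5-95% band.
        """
        width = 3.0 * sigma_km / math.sqrt(l_ci)
        length = span_factor * width
        centre = length / 2.0
        positions = np.linspace(0.0, length, n_sites)
        sites = tuple(
            SiteSpec(f"s{i:02d}", float(x), n=n_per_site)
            for i, x in enumerate(positions)
        )
        return cls(
            sites=sites,
            cline_centre_km=centre,
            cline_width_km=width,
            transition_interval=(centre - width / 2.0, centre + width / 2.0),
            seed=seed,
            **kwargs,
        )

    def site_frequency(self, spec: SiteSpec) -> float:
        if spec.freq is not None:
            return spec.freq
        return float(
            logistic_cline(spec.position_km, self.cline_centre_km, self.cline_width_km)
        )

    def site_zone(self, spec: SiteSpec) -> str:
        lo, hi = self.transition_interval
        return "transition" if lo <= spec.position_km <= hi else "fixed"

    def site_lat(self, spec: SiteSpec) -> float:
        return self.origin_lat + spec.position_km / KM_PER_DEGREE_LAT


@dataclass(frozen=True)
class SurveyTable:
    """Individual records plus per-site metadata (sites with n=0 included)."""

    records: pd.DataFrame
    sites: pd.DataFrame
    seed: int

    def population_sites(self) -> list[PopulationSite]:
        return [
            PopulationSite(
                site=r.site,
                lat=r.lat,
                lon=r.lon,
                period=r.period,
                n=int(r.n),
                n_double=int(r.n_double),
            )
            for r in self.sites.itertuples()
        ]


def generate_survey(design: SurveyDesign) -> SurveyTable:
    """Draw individual infection/haplotype records for every design site.

    Infection status is binomial in the site's cline frequency; haplotype
    is binomial conditional on infection (mismatch inside the transition
    interval, leakage outside).  Sites from the 1998/1999 period are
    screened for infection only (haplotype ``untyped``).  Fully
    reproducible from ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    rec_rows, site_rows = [], []
    for spec in design.sites:
        freq = design.site_frequency(spec)
        zone = design.site_zone(spec)
        p_mis = (
            design.p_mismatch_inside
            if zone == "transition"
            else design.p_mismatch_outside
        )
        n_double = int(rng.binomial(spec.n, freq)) if spec.n else 0
        for i in range(spec.n):
            double = i < n_double
            if spec.period == "1998/1999":
                hap = "untyped"
            elif double:
                hap = "HT1" if rng.random() < p_mis else "HT2"
            else:
                hap = "HT2" if rng.random() < design.p_single_ht2 else "HT1"
            rec_rows.append(
                {
                    "population": spec.site,
                    "period": spec.period,
                    "zone": zone,
                    "host_plant": spec.host_plant,
                    "infection": "double" if double else "single",
                    "haplotype": hap,
                }
            )
        site_rows.append(
            {
                "site": spec.site,
                "position_km": spec.position_km,
                "lat": design.site_lat(spec),
                "lon": design.origin_lon,
                "period": spec.period,
                "zone": zone,
                "n": spec.n,
                "n_double": n_double,
                "design_freq": freq,
            }
        )
    records = pd.DataFrame(rec_rows, columns=list(COLUMNS))
    if len(records):
        validate_records(records)
    sites = pd.DataFrame(site_rows)
    return SurveyTable(records=records, sites=sites, seed=design.seed)


def generate_fixture_amplicons(seed: int = 0) -> tuple[SeqRecord, SeqRecord]:
    """A synthetic COI-like amplicon pair emulating the two haplotypes.

    Both sequences are 546 bp and identical except for one C/T transition
    at the third position of the diagnostic motif: the HT2-like sequence
    carries exactly one HaeIII site (GGCC) cutting after base 342, the
    HT1-like sequence carries none.  These are constructed stand-ins for
    the real GenBank amplicons, which are not bundled.
    """
    rng = np.random.default_rng(seed)
    length, motif_start = 546, 340  # cut = motif_start + 2 = 342
    seq = list(rng.choice(list("ACGT"), size=length))
    seq[motif_start : motif_start + 4] = list("GGTC")  # site-free HT1 core
    s = "".join(seq)
    while "GGCC" in s:  # scrub accidental sites; 'A' cannot seed a new one
        i = s.index("GGCC")
        s = s[:i] + "A" + s[i + 1 :]
    ht1 = s
    ht2 = s[: motif_start + 2] + "C" + s[motif_start + 3 :]
    assert ht2.count("GGCC") == 1 and "GGCC" not in ht1
    return (
        SeqRecord(Seq(ht1), id="HT1_synthetic", description="COI-like amplicon, no HaeIII site"),
        SeqRecord(Seq(ht2), id="HT2_synthetic", description="COI-like amplicon, HaeIII cut after 342"),
    )


# ---------------------------------------------------------------------------
# Published survey margins, bundled as individual-level tables.
# ---------------------------------------------------------------------------

# (period, host_plant, n, n_HT1) for doubly infected flies in the transition
# zone.  Period and host-plant margins are published (29/31/4 doubles with
# 9/4/1 on HT1 by period; 47 Lonicera with 12 HT1, 17 Prunus with 2 HT1);
# the joint allocation is one arbitrary consistent choice.
_TRANSITION_DOUBLE = (
    ("2000/2001", "Lonicera", 25, 8),
    ("2000/2001", "Prunus", 4, 1),
    ("2008", "Lonicera", 18, 3),
    ("2008", "Prunus", 13, 1),
    ("2014", "Lonicera", 4, 1),
)

# (period, n, n_HT2) for singly infected flies in the transition zone: the
# pooled margin is 197 HT1 + 1 HT2; the per-period split is arbitrary.
_TRANSITION_SINGLE = (("2000/2001", 90, 0), ("2008", 87, 1), ("2014", 21, 0))

# Outside (fixed-status) populations: doubles (period, n, n_HT1) and
# singles (period, n, n_HT2); the three 2014 HT2 singles are one
# exceptional population.
_OUTSIDE_DOUBLE = (("2000/2001", 66, 3), ("2008", 200, 1), ("2014", 10, 0))
_OUTSIDE_SINGLE = (("2000/2001", 121, 0), ("2008", 237, 1), ("2014", 25, 3))


def _rows(population, period, zone, host_plant, infection, n_mismatch, n_total):
    """n_total records of which n_mismatch carry the unexpected haplotype."""
    expected, unexpected = ("HT2", "HT1") if infection == "double" else ("HT1", "HT2")
    for i in range(n_total):
        yield {
            "population": population,
            "period": period,
            "zone": zone,
            "host_plant": host_plant,
            "infection": infection,
            "haplotype": unexpected if i < n_mismatch else expected,
        }


def paper_fixtures() -> dict[str, pd.DataFrame]:
    """Deterministic survey tables reproducing the published stratum counts.

    Keys: ``"transition"`` (the mixed-infection zone), ``"outside"``
    (populations with fixed infection status) and ``"germany"`` (both
    concatenated).
    """
    trans = []
    for period, plant, n, n_ht1 in _TRANSITION_DOUBLE:
        trans.extend(_rows(f"TZ-{period[:4]}-{plant[:3]}", period, "transition",
                           plant, "double", n_ht1, n))
    for period, n, n_ht2 in _TRANSITION_SINGLE:
        trans.extend(_rows(f"TZ-{period[:4]}-s", period, "transition",
                           "unknown", "single", n_ht2, n))
    out = []
    for period, n, n_ht1 in _OUTSIDE_DOUBLE:
        out.extend(_rows(f"OUT-{period[:4]}-d", period, "fixed",
                         "unknown", "double", n_ht1, n))
    for period, n, n_ht2 in _OUTSIDE_SINGLE:
        out.extend(_rows(f"OUT-{period[:4]}-s", period, "fixed",
                         "unknown", "single", n_ht2, n))
    cols = list(COLUMNS)
    transition = pd.DataFrame(trans, columns=cols).sort_values(cols, kind="stable").reset_index(drop=True)
    outside = pd.DataFrame(out, columns=cols).sort_values(cols, kind="stable").reset_index(drop=True)
    germany = pd.concat([transition, outside], ignore_index=True)
    for df in (transition, outside):
        validate_records(df)
    return {"transition": transition, "outside": outside, "germany": germany}
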