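"""Genetic-erosion assessment and genetic-rescue scenario planning.

For a candidate translocation, the expected benefit to the recipient
population is summarized by the mean inbreeding coefficient

    F = 1 - Ho(recipient) / He(source),

the proportional heterozygosity deficit of the (inbred) recipient
relative to the (outbred) donor. Four donor-selection scenarios are
assessed per recipient, restricted to the recipient's regional genetic
cluster: the geographically nearest site, and the sites with the
largest effective size (Ne), highest expected heterozygosity, and
largest adult abundance (Na). A recipient is flagged as showing
genetic erosion when it is demographically small (Na < 100 and
Ne < 100), and/or F against a donor exceeds a threshold (10% by
default).

Source "expected heterozygosity" is taken from the nucleotide-diversity
column (the sample-size-corrected estimator) of the diversity table by
default; the plug-in He column can be selected instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .genotype_io import SiteMetadata
from .geo import great_circle_km

SCENARIOS = ("neighbor", "max_Ne", "max_He", "max_Na")

#: Marker returned when a scenario's optimal donor is the recipient itself.
SELF = "self"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (0.125 -> 0.13), as in reported tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RescueAssessment:
    """One recipient x scenario cell of the rescue table."""

    recipient: str
    scenario: str
    source: str  # site name or SELF
    f: float | None  # None when source is SELF (dash convention)
    isolated: bool
    small: bool
    erosion: bool | None


def inbreeding_coefficient(ho_recipient: float, he_source: float) -> float:
    """F = 1 - Ho(recipient)/He(source), rounded to 2 decimals (half-up)."""
    if he_source <= 0:
        raise ValueError("source heterozygosity must be positive")
    return round_half_up(1.0 - ho_recipient / he_source, 2)


def _cluster_candidates(
    recipient: str, sites: list[SiteMetadata]
) -> list[SiteMetadata]:
    by_name = {s.site: s for s in sites}
    if recipient not in by_name:
        raise KeyError(f"unknown recipient site {recipient!r}")
    region = by_name[recipient].region
    cands = [s for s in sites if s.region == region and s.site != recipient]
    if not cands:
        raise ValueError(f"no candidate donors in the {region!r} cluster")
    return cands


def select_source(
    recipient: str,
    scenario: str,
    sites: list[SiteMetadata],
    diversity: pd.DataFrame | None = None,
    ne_points: dict[str, float] | None = None,
) -> str:
    """Donor site for one scenario, restricted to the recipient's cluster.

    ``neighbor``: minimum great-circle distance. ``max_Ne``/``max_Na``:
    argmax of the point Ne / modal Na over same-cluster sites *including*
    the recipient — when the recipient itself is the argmax the result
    is :data:`SELF` (rendered as a dash in tables). ``max_He``: argmax
    of expected heterozygosity, with ties broken by nucleotide
    diversity, then observed heterozygosity, then site name.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    by_name = {s.site: s for s in sites}
    rec = by_name[recipient]
    cands = _cluster_candidates(recipient, sites)

    if scenario == "neighbor":
        # an explicitly curated nearest-neighbor donor (e.g. reflecting
        # habitat connectivity rather than straight-line distance)
        # overrides the great-circle choice
        if rec.nearest_neighbor:
            if rec.nearest_neighbor not in {s.site for s in cands}:
                raise ValueError(
                    f"nearest neighbor {rec.nearest_neighbor!r} of {recipient!r} "
                    "is not a same-cluster candidate"
                )
            return rec.nearest_neighbor
        return min(
            cands,
            key=lambda s: great_circle_km(
                rec.latitude, rec.longitude, s.latitude, s.longitude
            ),
        ).site

    cluster = [rec] + cands
    if scenario == "max_Na":
        scored = [(s.site, s.modal_na) for s in cluster if s.modal_na is not None]
        if not scored:
            raise ValueError("no modal Na available in the cluster")
        best = max(scored, key=lambda kv: kv[1])[0]
    elif scenario == "max_Ne":
        if not ne_points:
            raise ValueError("max_Ne scenario requires ne_points")
        scored = [
            (s.site, ne_points[s.site])
            for s in cluster
            if s.site in ne_points and np.isfinite(ne_points[s.site])
        ]
        if not scored:
            raise ValueError("no finite Ne available in the cluster")
        best = max(scored, key=lambda kv: kv[1])[0]
    else:  # max_He: rank by He, break ties by pi, then Ho, then name
        if diversity is None:
            raise ValueError("max_He scenario requires a diversity table")
        div = diversity.set_index("population")
        rows = div.loc[[s.site for s in cluster if s.site in div.index]]
        if rows.empty:
            raise ValueError("no diversity rows for the cluster")
        top = rows[np.isclose(rows["He"], rows["He"].max())]
        top = top[np.isclose(top["pi"], top["pi"].max())]
        top = top[np.isclose(top["Ho"], top["Ho"].max())]
        best = sorted(top.index)[0]
    return SELF if best == recipient else best


def erosion_flags(
    na: int | None,
    ne: float | None,
    f_value: float | None,
    isolated: bool,
    f_threshold: float = 0.10,
) -> dict[str, bool | None]:
    """Erosion criteria: small = (Na < 100 and Ne < 100); erosion = F > threshold.

    The F comparison is a strict inequality; F exactly at the threshold
    does not flag erosion.
    """
    small = (
        None
        if na is None or ne is None
        else bool(na < 100 and np.isfinite(ne) and ne < 100)
    )
    erosion = None if f_value is None else bool(f_value > f_threshold)
    return {"isolated": isolated, "small": small, "erosion": erosion}


def rescue_table(
    sites: list[SiteMetadata],
    diversity: pd.DataFrame,
    ne_points: dict[str, float],
    f_threshold: float = 0.10,
    he_column: str = "pi",
) -> pd.DataFrame:
    """Full recipient x scenario rescue assessment.

    ``diversity`` must contain columns ``population``, ``Ho``, ``He``,
    ``pi``. F uses the recipient's Ho and the donor's ``he_column``
    (nucleotide diversity by default). The recipient-level erosion flag
    uses the largest F over its applicable scenarios — a recipient is
    flagged when any assessed donor shows F above threshold; per-cell F
    values are also reported.
    """
    div = diversity.set_index("population")
    rows = []
    for site in sites:
        rec = site.site
        if rec not in div.index:
            continue
        ho_rec = float(div.loc[rec, "Ho"])
        f_by_scenario: dict[str, float | None] = {}
        src_by_scenario: dict[str, str] = {}
        for scenario in SCENARIOS:
            source = select_source(
                rec, scenario, sites, diversity=diversity, ne_points=ne_points
            )
            src_by_scenario[scenario] = source
            if source == SELF:
                f_by_scenario[scenario] = None
            else:
                he_src = float(div.loc[source, he_column])
                f_by_scenario[scenario] = inbreeding_coefficient(ho_rec, he_src)
        f_values = [f for f in f_by_scenario.values() if f is not None]
        flags = erosion_flags(
            na=site.modal_na,
            ne=ne_points.get(rec),
            f_value=max(f_values) if f_values else None,
            isolated=site.isolated,
            f_threshold=f_threshold,
        )
        for scenario in SCENARIOS:
            rows.append(
                {
                    "recipient": rec,
                    "region": site.region,
                    "scenario": scenario,
                    "source": src_by_scenario[scenario],
                    "F": f_by_scenario[scenario],
                    "isolated": flags["isolated"],
                    "small": flags["small"],
                    "F_gt_threshold": flags["erosion"],
                }
            )
    return pd.DataFrame(rows)
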