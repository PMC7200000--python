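"""Bundled summary tables for the seven focal monitoring sites.

These are the published per-site summaries from the long-term San
Francisco gartersnake (*Thamnophis sirtalis tetrataenia*) monitoring
program on the San Francisco Peninsula: site metadata with regional
cluster membership, SNP diversity statistics, effective-size point
estimates, and modal adult abundance. Raw capture histories and
genotypes for that program are not public; these printed summaries are
the inputs to the rescue-scenario and Ne/Na analyses and also serve as
a realistic worked example.

Site coordinates are approximate public locations of the named
localities (decimal-degree WGS84), adequate for nearest-neighbor
donor selection and isolation-by-distance distances at the tens-of-km
scale of the Peninsula.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .genotype_io import SiteMetadata

# site, regional cluster, approx. coordinates, isolation flag (from
# hierarchical clustering), modal adult abundance, curated
# nearest-neighbor donor (habitat-connectivity based, used by the
# rescue neighbor scenario in preference to straight-line distance)
_SITES_CSV = """\
site,region,longitude,latitude,isolated,modal_na,nearest_neighbor
Pacifica,northern,-122.490,37.630,True,47,Skyline
Skyline,northern,-122.340,37.490,True,48,Crystal Springs
Crystal Springs,northern,-122.360,37.528,True,50,Skyline
San Bruno,northern,-122.435,37.685,True,1317,Skyline
Mindego,southern,-122.210,37.335,True,204,Pescadero
Pescadero,southern,-122.410,37.260,False,73,"Año Nuevo"
"Año Nuevo",southern,-122.330,37.120,False,123,Pescadero
"""

# population, survey year, mean individuals per locus, rarefied
# allelic richness, observed/expected heterozygosity, nucleotide
# diversity (2016-2018 SNP panel)
_DIVERSITY_CSV = """\
population,period,N,Ar,Ho,He,pi
Pacifica,2018,20,1.31,0.092,0.090,0.092
Skyline,2018,17,1.41,0.123,0.123,0.127
Crystal Springs,2018,17,1.44,0.127,0.123,0.127
San Bruno,2017,20,1.42,0.114,0.114,0.117
Mindego,2016,22,1.38,0.112,0.112,0.115
Pescadero,2016,18,1.45,0.122,0.124,0.128
"Año Nuevo",2018,49,1.41,0.120,0.121,0.122
"""

# single-sample (LD) and two-sample temporal point estimates; empty
# temporal cells mean no second sampling period exists for the site
_NE_CSV = """\
site,ld_ne,ld_ci_lower,ld_ci_upper,temporal_ne,temporal_ci_lower,temporal_ci_upper
Pacifica,13,8,24,9,8,9
Skyline,30,17,83,,,
Crystal Springs,10,5,23,,,
San Bruno,255,46,inf,254,145,1021
Mindego,33,17,139,,,
Pescadero,60,23,inf,56,49,66
"Año Nuevo",41,30,60,49,44,56
"""


def load_focal_sites() -> list[SiteMetadata]:
    """Site metadata for the seven focal monitoring sites."""
    df = pd.read_csv(StringIO(_SITES_CSV))
    return [
        SiteMetadata(
            site=r.site,
            region=r.region,
            longitude=r.longitude,
            latitude=r.latitude,
            isolated=bool(r.isolated),
            modal_na=int(r.modal_na),
            nearest_neighbor=r.nearest_neighbor,
        )
        for r in df.itertuples(index=False)
    ]


def load_diversity_summary() -> pd.DataFrame:
    """Per-site diversity statistics (N, Ar, Ho, He, pi)."""
    return pd.read_csv(StringIO(_DIVERSITY_CSV))


def load_ne_summary() -> pd.DataFrame:
    """Per-site LD and temporal Ne point estimates with 95% CIs."""
    return pd.read_csv(StringIO(_NE_CSV))


def preferred_ne_points(prefer: str = "temporal") -> dict[str, float]:
    """Point Ne per site, preferring the temporal estimate when present."""
    ne = load_ne_summary()
    out: dict[str, float] = {}
    for r in ne.itertuples(index=False):
        if prefer == "temporal" and pd.notna(r.temporal_ne):
            out[r.site] = float(r.temporal_ne)
        else:
            out[r.site] = float(r.ld_ne)
    return out
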