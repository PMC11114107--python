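"""Published screening counts for the emulated survey.

The survey screened *D. discoideum* isolates from 22 collection trips to 21
locations across the eastern United States (one site, Mountain Lake
Biological Station, was sampled twice 14 years apart and is keyed as two
collections).  Per collection we carry the number of screened hosts, the
collection year, and the count positive for each of the five symbionts.
These published counts serve as a reference input: a host-level table with
exactly these totals can be reconstructed for prevalence summaries.  The
reconstruction fixes only the marginal counts -- which hosts are coinfected
is not recoverable from the published table and is assigned deterministically
-- so it supports prevalence checks, not coinfection analyses.
"""

from __future__ import annotations

import pandas as pd

from .data_io import SYMBIONTS, validate_host_table

__all__ = ["survey_counts", "reconstruct_survey_hosts"]

# location key, year, total screened, then positives for
# agricolaris, hayleyella, bonniea, amoebophilus, chlamydiae
_SURVEY = [
    ("AR-forest-city", 2004, 9, 0, 3, 0, 0, 1),
    ("GA-cooper-creek", 2000, 14, 0, 0, 0, 0, 10),
    ("IL-effingham", 2005, 7, 2, 0, 0, 0, 0),
    ("IN-bloomington", 2005, 18, 0, 9, 0, 1, 3),
    ("IN-patoka-lake", 2005, 13, 4, 8, 0, 1, 3),
    ("KY-land-between-lakes", 2004, 10, 6, 6, 0, 0, 4),
    ("MA-mt-greylock", 2001, 12, 4, 1, 0, 0, 1),
    ("MA-boston", 2000, 9, 0, 0, 0, 0, 5),
    ("MO-st-louis", 2005, 13, 0, 0, 0, 0, 1),
    ("NC-linville-falls", 2001, 24, 10, 0, 0, 0, 0),
    ("NC-little-butts-gap", 2001, 24, 1, 0, 3, 1, 3),
    ("TN-indian-gap", 2001, 10, 2, 0, 1, 0, 1),
    ("TN-rhodo-thicket", 2001, 7, 3, 0, 0, 1, 3),
    ("TN-road", 2001, 13, 0, 0, 0, 0, 0),
    ("TN-sugarlands", 2001, 6, 0, 0, 2, 1, 0),
    ("TX-armand-bayou", 2004, 7, 0, 0, 0, 2, 0),
    ("TX-carthage", 2004, 12, 0, 0, 0, 0, 0),
    ("TX-houston-arboretum", 2001, 59, 19, 2, 0, 14, 27),
    ("TX-linden", 2005, 7, 1, 1, 0, 0, 1),
    ("TX-webster", 2004, 4, 0, 0, 0, 0, 0),
    ("VA-mountain-lake-2014", 2014, 226, 3, 0, 4, 23, 92),
    ("VA-mountain-lake-2000", 2000, 188, 48, 26, 8, 70, 33),
]


def survey_counts() -> pd.DataFrame:
    """Per-collection screened totals and positive counts (22 collections)."""
    return pd.DataFrame(
        _SURVEY,
        columns=["location_id", "year", "total_screened", *SYMBIONTS],
    )


def reconstruct_survey_hosts() -> pd.DataFrame:
    """Host-level 0/1 table matching the published per-collection counts.

    For each collection the first k hosts are marked positive for a symbiont
    with count k, independently per symbiont; marginal counts are exact,
    coinfection structure is arbitrary.
    """
    rows = []
    for rec in _SURVEY:
        loc, year, total = rec[0], rec[1], rec[2]
        counts = dict(zip(SYMBIONTS, rec[3:]))
        for i in range(total):
            row = {"host_id": f"{loc}-{i:03d}", "location_id": loc, "year": year}
            for sym in SYMBIONTS:
                row[sym] = 1 if i < counts[sym] else 0
            rows.append(row)
    return validate_host_table(pd.DataFrame(rows))
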