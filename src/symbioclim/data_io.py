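"""Reading, validation and assembly of the host / location / precipitation tables.

The survey design: *Dictyostelium discoideum* isolates ("hosts") screened by
16S for five bacterial endosymbionts -- three facultative *Paraburkholderia*
species (*P. agricolaris*, *P. hayleyella*, *P. bonniea*) plus the obligate
*Amoebophilus* and Chlamydiae lineages -- across ~22 location-collections in
the eastern United States.  A site sampled twice (14 years apart) is keyed as
two distinct location_ids.  Statuses are 0/1 with missing allowed: the two
source screens covered overlapping but not identical isolate sets, and
missing statuses are excluded pairwise per analysis rather than imputed.
"""

from __future__ import annotations

import decimal

import numpy as np
import pandas as pd

__all__ = [
    "SYMBIONTS",
    "PARABURKHOLDERIA",
    "read_host_table",
    "write_host_table",
    "read_location_table",
    "read_precip_table",
    "summarize_prevalence",
    "build_model_frame",
    "round_half_up",
]

SYMBIONTS = ("agricolaris", "hayleyella", "bonniea", "amoebophilus", "chlamydiae")
PARABURKHOLDERIA = ("agricolaris", "hayleyella", "bonniea")

HOST_COLUMNS = ("host_id", "location_id", "year") + SYMBIONTS
LOCATION_COLUMNS = (
    "location_id", "name", "latitude", "longitude", "year",
    "soil_ph", "soil_mat", "cn_ratio", "map_mm",
)
COVARIATES = ("colwell_long", "colwell_5yr", "soil_mat", "cn_ratio", "map_mm", "soil_ph")


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def read_host_table(path) -> pd.DataFrame:
    """Read and validate the host screening table.

    Empty cells are missing statuses (host screened in only one of the two
    source surveys).  Statuses other than 0/1 are rejected with their CSV row
    numbers; duplicate host_ids are rejected.
    """
    df = pd.read_csv(path, dtype={"host_id": str, "location_id": str})
    _require_columns(df, HOST_COLUMNS, "host table")
    return validate_host_table(df)


def validate_host_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, HOST_COLUMNS, "host table")
    df = df.copy()
    dupes = df["host_id"][df["host_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate host_id values: {sorted(set(dupes))}")
    if df["location_id"].isna().any() or (df["location_id"] == "").any():
        raise ValueError("empty location_id")
    years = df["year"].to_numpy()
    if ((years < 1900) | (years > 2100)).any():
        raise ValueError("collection year outside [1900, 2100]")
    bad_rows: list[int] = []
    for sym in SYMBIONTS:
        col = pd.to_numeric(df[sym], errors="coerce")
        invalid = df[sym].notna() & ~col.isin([0, 1])
        # CSV data rows are 1-based after the header
        bad_rows.extend((df.index[invalid] + 2).tolist())
        df[sym] = col.astype("Int8")
    if bad_rows:
        raise ValueError(
            f"malformed symbiont status (not 0/1/empty) on row(s) {sorted(set(bad_rows))}"
        )
    return df


def write_host_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_location_table(path) -> pd.DataFrame:
    """Read the per-location covariate table and check physical ranges."""
    df = pd.read_csv(path, dtype={"location_id": str, "name": str})
    _require_columns(df, LOCATION_COLUMNS, "location table")
    if df["location_id"].duplicated().any():
        raise ValueError("duplicate location_id in location table")
    lat, lon = df["latitude"], df["longitude"]
    if ((lat < -90) | (lat > 90)).any():
        raise ValueError("latitude outside [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise ValueError("longitude outside [-180, 180]")
    if ((df["soil_ph"] <= 0) | (df["soil_ph"] >= 14)).any():
        raise ValueError("soil_ph outside (0, 14)")
    if (df["cn_ratio"] <= 0).any():
        raise ValueError("cn_ratio must be > 0")
    if (df["map_mm"] < 0).any():
        raise ValueError("map_mm must be >= 0")
    return df


def read_precip_table(path) -> pd.DataFrame:
    """Read the long-format monthly precipitation table."""
    df = pd.read_csv(path, dtype={"location_id": str})
    _require_columns(df, ("location_id", "year", "month", "precip_mm"), "precip table")
    if ((df["month"] < 1) | (df["month"] > 12)).any():
        raise ValueError("month outside 1..12")
    if (df["precip_mm"] < 0).any():
        raise ValueError("negative precip_mm")
    if df.duplicated(["location_id", "year", "month"]).any():
        raise ValueError("duplicate (location_id, year, month)")
    return df


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for prevalence percents)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def summarize_prevalence(hosts: pd.DataFrame) -> pd.DataFrame:
    """Per-location, per-symbiont prevalence counts and percents.

    Counts positives among non-missing statuses; ``total_screened`` is the
    number of isolates collected at the location.  An ``any`` row per
    location gives overall symbiosis prevalence (isolate positive for at
    least one of the five taxa).  Percents are rounded half-up to one
    decimal; they need not sum to 100 because of coinfections.
    """
    if hosts.empty:
        raise ValueError("no isolates")
    rows = []
    for loc, grp in hosts.groupby("location_id", sort=True):
        total = len(grp)
        for sym in SYMBIONTS:
            count = int((grp[sym] == 1).sum())
            rows.append(
                {
                    "location_id": loc,
                    "symbiont": sym,
                    "count": count,
                    "total_screened": total,
                    "percent": round_half_up(100.0 * count / total),
                }
            )
        any_pos = int((grp[list(SYMBIONTS)] == 1).any(axis=1).sum())
        rows.append(
            {
                "location_id": loc,
                "symbiont": "any",
                "count": any_pos,
                "total_screened": total,
                "percent": round_half_up(100.0 * any_pos / total),
            }
        )
    return pd.DataFrame(rows)


def _response_column(hosts: pd.DataFrame, response: str) -> pd.Series:
    """0/1/NA response for a single symbiont, 'any', or a coinfection pair
    written as 'a_x_b' (1 iff both members present)."""
    if response in SYMBIONTS:
        return hosts[response]
    if response == "any":
        status = hosts[list(SYMBIONTS)]
        any_one = (status == 1).any(axis=1)
        all_known = status.notna().all(axis=1)
        out = pd.Series(pd.NA, index=hosts.index, dtype="Int8")
        out[any_one] = 1
        out[~any_one & all_known] = 0
        return out
    if "_x_" in response:
        a, b = response.split("_x_")
        if a not in SYMBIONTS or b not in SYMBIONTS:
            raise ValueError(f"unknown coinfection pair {response!r}")
        both_known = hosts[a].notna() & hosts[b].notna()
        out = pd.Series(pd.NA, index=hosts.index, dtype="Int8")
        out[both_known] = ((hosts[a] == 1) & (hosts[b] == 1)).astype("Int8")[both_known]
        return out
    raise ValueError(f"unknown response {response!r}")


def build_model_frame(
    hosts: pd.DataFrame,
    locations: pd.DataFrame,
    colwell: pd.DataFrame,
    response: str,
) -> pd.DataFrame:
    """Assemble the per-host modeling frame for one analysis target.

    One row per isolate with a non-missing response (isolates missing the
    target status are dropped and the drop count recorded in the frame's
    ``attrs``); location-level covariates -- both predictability windows,
    soil temperature, C/N, mean annual precipitation, pH -- joined by
    location_id.  The response is any of the five symbionts, ``"any"``, or a
    coinfection pair such as ``"hayleyella_x_amoebophilus"``.
    """
    missing_locs = sorted(set(hosts["location_id"]) - set(locations["location_id"]))
    if missing_locs:
        raise ValueError(f"host locations without a location record: {missing_locs}")
    missing_cw = sorted(set(hosts["location_id"]) - set(colwell["location_id"]))
    if missing_cw:
        raise ValueError(f"host locations without predictability values: {missing_cw}")

    resp = _response_column(hosts, response)
    keep = resp.notna()
    frame = hosts.loc[keep, ["host_id", "location_id"]].copy()
    frame["response"] = resp[keep].astype(int)

    covars = locations.set_index("location_id")[
        ["soil_mat", "cn_ratio", "map_mm", "soil_ph", "latitude", "longitude"]
    ]
    cw = colwell.set_index("location_id")[["colwell_long", "colwell_5yr"]]
    frame = frame.join(covars, on="location_id").join(cw, on="location_id")
    frame = frame.reset_index(drop=True)
    frame.attrs["response"] = response
    frame.attrs["n_dropped_missing_response"] = int((~keep).sum())
    return frame
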