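"""Cultural Techno-Unit (CTU) level cleaning and aggregation.

The archaeological site list, the zooarchaeological NISP-proportion table
and the gridded suitability/climate/population estimates share no common
key except their macro-archaeological unit, so the analysis distils every
variable to one row per CTU: site records are deduplicated within
(site, century), raw technocomplex labels are mapped up to the six-unit
CTU vocabulary, and each variable is averaged per CTU.  The resulting
summary table is the input to the structural path models.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import InsufficientDataError
from .sdm import round_to_century

__all__ = [
    "CTU_VOCABULARY",
    "ANALYSIS_CTUS",
    "FOCAL_SPECIES",
    "load_default_ctu_mapping",
    "dedupe_sites",
    "reclassify_fauna",
    "summarize_ctu",
    "zooarch_share_combined",
]

#: the six macro-archaeological units, in rough chronological order
CTU_VOCABULARY = ("Magdalenian", "Epigravettian", "ABC", "TPC", "BBT", "Mesolithic")

#: CTUs entering the statistical analysis (BBT dropped for small sample size)
ANALYSIS_CTUS = ("Magdalenian", "Epigravettian", "ABC", "TPC", "Mesolithic")

#: prey species tracked through aggregation and path models
FOCAL_SPECIES = ("reindeer", "boar", "red_deer", "elk", "horse")


def load_default_ctu_mapping() -> pd.DataFrame:
    """The shipped raw-technocomplex-label -> CTU mapping (editable CSV)."""
    with resources.files("paleoforage.data").joinpath("ctu_mapping.csv").open() as fh:
        return pd.read_csv(fh)


def dedupe_sites(sites: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop duplicate dates from the same site in the same century.

    ``sites`` needs ``site_id`` and ``age_bp`` (median calibrated age);
    the century is the half-up rounding of ``age_bp``. Within each
    (site_id, century) group exactly one record is retained -- the first
    by ``lab_id`` order when present, otherwise by input order -- so the
    operation is deterministic and idempotent. Returns the retained table
    (with a ``century`` column) and a report of kept/removed counts.
    """
    df = sites.copy()
    df["century"] = round_to_century(df["age_bp"].to_numpy())
    sort_cols = ["site_id", "century"] + (["lab_id"] if "lab_id" in df.columns else [])
    df = df.sort_values(sort_cols, kind="mergesort")
    kept = df.drop_duplicates(subset=["site_id", "century"], keep="first").reset_index(drop=True)
    report = {"n_in": len(sites), "n_kept": len(kept), "n_removed": len(sites) - len(kept)}
    return kept, report


def reclassify_fauna(records: pd.DataFrame, mapping: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Map raw technocomplex labels to CTUs and drop unmapped records.

    ``mapping`` has columns ``raw_label, ctu``; rows with an empty ctu
    mark labels explicitly unmapped. Matching is case-insensitive on the
    stripped raw label. Returns the retained records with a ``ctu``
    column plus kept/dropped counts.
    """
    m = mapping.dropna(subset=["ctu"])
    lut = {str(k).strip().lower(): v for k, v in zip(m["raw_label"], m["ctu"])}
    raw = records["technocomplex"].astype(str).str.strip().str.lower()
    ctu = raw.map(lut)
    out = records.copy()
    out["ctu"] = ctu.to_numpy()
    kept = out[out["ctu"].notna()].reset_index(drop=True)
    if len(kept) == 0:
        raise InsufficientDataError("no faunal records map to any CTU")
    report = {"n_in": len(records), "n_kept": len(kept), "n_dropped": len(records) - len(kept)}
    return kept, report


def _ctu_mean(df: pd.DataFrame, value_col: str, stat: str) -> pd.Series:
    g = df.groupby("ctu")[value_col]
    return g.median() if stat == "median" else g.mean()


def summarize_ctu(
    site_suitability: pd.DataFrame,
    faunal: pd.DataFrame,
    site_spd: pd.DataFrame,
    site_climate: pd.DataFrame,
    species: tuple[str, ...] = FOCAL_SPECIES,
    ctus: tuple[str, ...] = ANALYSIS_CTUS,
    stat: str = "mean",
) -> pd.DataFrame:
    """Central-tendency table: one row per CTU.

    Inputs (all keyed by ``ctu``):

    - ``site_suitability``: columns ``ctu, species, suitability`` (one row
      per site x species),
    - ``faunal``: columns ``ctu`` plus ``nisp_<species>`` proportions
      (one row per assemblage),
    - ``site_spd``: columns ``ctu, spd`` (population proxy at each site's
      century),
    - ``site_climate``: columns ``ctu, warm_t`` (maximum temperature of
      the warmest month at each site).

    Output columns: ``suit_<sp>`` and ``nisp_<sp>`` per species,
    ``mean_spd``, ``mean_warm_t``, ``n_sites``, ``n_assemblages``.
    Variables missing for a CTU stay NaN (flagged missing, never zero).
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    suit_ctus = set(site_suitability["ctu"].unique())
    faunal_ctus = set(faunal["ctu"].unique())
    if not (suit_ctus & faunal_ctus & set(ctus)):
        raise InsufficientDataError("site and faunal CTU sets do not overlap")
    out = pd.DataFrame(index=pd.Index(list(ctus), name="ctu"))
    for sp in species:
        sub = site_suitability[site_suitability["species"] == sp]
        out[f"suit_{sp}"] = _ctu_mean(sub, "suitability", stat)
        out[f"nisp_{sp}"] = _ctu_mean(faunal, f"nisp_{sp}", stat)
    out["mean_spd"] = _ctu_mean(site_spd, "spd", stat)
    out["mean_warm_t"] = _ctu_mean(site_climate, "warm_t", stat)
    out["n_sites"] = site_spd.groupby("ctu").size().reindex(out.index).fillna(0).astype(int)
    out["n_assemblages"] = faunal.groupby("ctu").size().reindex(out.index).fillna(0).astype(int)
    return out.reset_index()


def zooarch_share_combined(summary: pd.DataFrame, species_subset) -> pd.Series:
    """Per-CTU combined zooarchaeological share of a species subset.

    Sums the subset's mean NISP proportions per CTU, capped at 1. An
    empty subset gives 0.
    """
    unknown = [s for s in species_subset if f"nisp_{s}" not in summary.columns]
    if unknown:
        raise KeyError(f"species not in summary: {unknown}")
    if not list(species_subset):
        return pd.Series(0.0, index=summary.index)
    total = sum(summary[f"nisp_{s}"] for s in species_subset)
    return total.clip(upper=1.0)
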