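"""Treatment-episode construction for opioid agonist treatment records.

An episode is a maximal run of a client's dispensations of one drug without
an untreated gap reaching the drug-specific threshold. The gap between
consecutive dispensations is counted as fully untreated calendar days
(date difference minus one, since each record is a daily dispensation with
no days-supply field); an episode breaks when that count reaches at least
5 days for methadone or 6 days for buprenorphine/naloxone. Episodes are
built per (client, drug): a drug switch always starts a new episode, and
the episode end date is the last dispensation date (no carry-forward).
"""

from __future__ import annotations

import pandas as pd

from .synthetic import DRUG_BUPRENORPHINE, DRUG_METHADONE

#: Untreated-day counts at which an episode breaks, per drug.
GAP_THRESHOLD_DAYS = {DRUG_METHADONE: 5, DRUG_BUPRENORPHINE: 6}

EPISODE_COLUMNS = ["client_id", "drug", "episode", "start_date", "end_date", "physician_ids"]


def label_episodes(records: pd.DataFrame, thresholds: dict[str, int] | None = None) -> pd.DataFrame:
    """Return the records with an ``episode`` column (0-based per client+drug).

    Row order and same-day duplicates do not affect the labelling: rows are
    sorted internally and a same-day repeat has an untreated gap of -1.
    """
    thresholds = thresholds or GAP_THRESHOLD_DAYS
    df = records.copy()
    df["dispense_date"] = pd.to_datetime(df["dispense_date"])
    df = df.sort_values(["client_id", "drug", "dispense_date", "physician_id"], kind="mergesort")
    grp = df.groupby(["client_id", "drug"], observed=True, sort=False)
    gap = grp["dispense_date"].diff().dt.days - 1  # NaN at each group start
    thr = df["drug"].astype(str).map(thresholds)
    new_episode = gap.isna() | (gap >= thr)
    df["episode"] = new_episode.groupby(
        [df["client_id"], df["drug"]], observed=True, sort=False
    ).cumsum().astype(int) - 1
    return df.reset_index(drop=True)


def build_episodes(records: pd.DataFrame, thresholds: dict[str, int] | None = None) -> pd.DataFrame:
    """Aggregate records into episodes.

    Returns one row per (client, drug, episode) with ``start_date``,
    ``end_date`` and ``physician_ids`` (frozenset of physicians with at least
    one dispensation inside the episode).
    """
    labelled = label_episodes(records, thresholds)
    if labelled.empty:
        return pd.DataFrame(columns=EPISODE_COLUMNS)
    agg = (
        labelled.groupby(["client_id", "drug", "episode"], observed=True, sort=True)
        .agg(
            start_date=("dispense_date", "min"),
            end_date=("dispense_date", "max"),
            physician_ids=("physician_id", lambda s: frozenset(s.astype(str))),
        )
        .reset_index()
    )
    return agg[EPISODE_COLUMNS]


def write_episodes(episodes: pd.DataFrame, path) -> None:
    """CSV export: client_id,drug,start_date,end_date,n_physicians."""
    out = episodes.copy()
    out["n_physicians"] = out["physician_ids"].map(len)
    out["start_date"] = pd.to_datetime(out["start_date"]).dt.strftime("%Y-%m-%d")
    out["end_date"] = pd.to_datetime(out["end_date"]).dt.strftime("%Y-%m-%d")
    out[["client_id", "drug", "start_date", "end_date", "n_physicians"]].to_csv(path, index=False)
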