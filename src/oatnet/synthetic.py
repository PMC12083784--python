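"""Synthetic prescription-record cohorts with planted clinic structure.

The generator emulates the structure of opioid agonist treatment (OAT)
dispensation records from a multi-clinic treatment organization: a roster of
clinics staffed by a small number of physicians (some of whom work at two
clinics), client panels assigned to a home physician, co-prescribing within
and across clinics, and near-daily dispensation schedules whose day gaps
occasionally grow large enough to break a treatment episode.

Because the ground truth (which physician works at which clinic, which
clients they share) is planted, every downstream stage — network
construction, community detection, gold-standard concordance — can be
validated exactly.

All randomness flows through a single ``numpy`` generator seeded from
``SyntheticConfig.seed``; the draw order is fixed, so equal configurations
reproduce byte-identical cohorts. Structure and client panels are drawn
before any dispensation dates, which lets :func:`generate_truth` return the
exact ground truth of :func:`generate_cohort` without emitting records.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._dist import Choice, ConfigurationError, Distribution, Lognormal, parse_distribution

DRUG_METHADONE = "methadone"
DRUG_BUPRENORPHINE = "buprenorphine_naloxone"
DRUGS = (DRUG_METHADONE, DRUG_BUPRENORPHINE)

RECORD_COLUMNS = ["client_id", "physician_id", "clinic_id", "drug", "dispense_date"]

#: Default clinic staffing: median 2 physicians per clinic. Combined with 105
#: clinics and 30% dual-clinic physicians this lands the distinct-physician
#: count near the cohort scale the generator is calibrated to (~144).
_DEFAULT_PHYSICIANS_PER_CLINIC = {
    "kind": "choice",
    "values": [1, 2, 3, 4, 5],
    "probs": [0.45, 0.35, 0.12, 0.05, 0.03],
}

#: Yearly home-panel size per physician: lognormal with median 93 clients.
_DEFAULT_CLIENTS_PER_PHYSICIAN = {"kind": "lognormal", "median": 93, "sigma": 0.7}

#: Day differences between consecutive dispensations. Mostly daily pickup with
#: weekly carries; the tail (6/7/8/14/21 day differences = 5/6/7/13/20
#: untreated days) exercises both episode-breaking thresholds.
_DEFAULT_GAP_MODEL = {
    "kind": "choice",
    "values": [1, 2, 3, 6, 7, 8, 14, 21],
    "probs": [0.53, 0.15, 0.08, 0.04, 0.08, 0.04, 0.05, 0.03],
}


@dataclass
class SyntheticConfig:
    """Parameters of the planted cohort. Defaults are calibrated to an
    eight-year, ~105-clinic, ~144-physician, ~33k-client organization."""

    n_clinics: int = 105
    physicians_per_clinic: object = field(default_factory=lambda: dict(_DEFAULT_PHYSICIANS_PER_CLINIC))
    clients_per_physician: object = field(default_factory=lambda: dict(_DEFAULT_CLIENTS_PER_PHYSICIAN))
    multi_clinic_fraction: float = 0.3
    secondary_clinic_load_share: float = 0.3
    within_clinic_share_prob: float = 0.4
    cross_clinic_share_prob: float = 0.05
    drug_mix: float = 0.7  # proportion methadone (rest buprenorphine/naloxone)
    years: tuple[int, int] = (2013, 2020)
    dispense_gap_model: object = field(default_factory=lambda: dict(_DEFAULT_GAP_MODEL))
    client_retention: float = 0.85  # per-year probability a client continues treatment
    home_script_share: float = 0.7  # share of dispensations written by the home physician
    seed: int = 0

    def validate(self) -> None:
        if self.n_clinics < 1:
            raise ConfigurationError("n_clinics: must be >= 1")
        for name in (
            "multi_clinic_fraction",
            "secondary_clinic_load_share",
            "within_clinic_share_prob",
            "cross_clinic_share_prob",
            "drug_mix",
            "client_retention",
            "home_script_share",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}: must lie in [0, 1], got {v}")
        if self.client_retention >= 1.0:
            raise ConfigurationError("client_retention: must be < 1")
        y0, y1 = self.years
        if y1 < y0:
            raise ConfigurationError(f"years: end {y1} precedes start {y0}")
        # distribution specs must parse; errors name the field
        self._dist("physicians_per_clinic")
        self._dist("clients_per_physician")
        self._dist("dispense_gap_model")

    def _dist(self, name: str) -> Distribution:
        return parse_distribution(getattr(self, name), name)

    # -- config file round trip ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in ("physicians_per_clinic", "clients_per_physician", "dispense_gap_model"):
            dist = self._dist(name)
            d[name] = dist.to_dict()
        d["years"] = list(self.years)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        if "years" in d:
            d["years"] = tuple(d["years"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Planted memberships underlying a synthetic cohort.

    physician_clinics maps physician -> {clinic -> distinct planted clients};
    clinics a physician staffs but where no client was planted appear with
    count 0. client_assignments maps client -> list of (physician, clinic)
    pairs the client was planted with (home physician first).
    """

    physician_clinics: dict[str, dict[str, int]]
    client_assignments: dict[str, list[tuple[str, str]]]

    @property
    def n_physicians(self) -> int:
        return len(self.physician_clinics)

    @property
    def n_clients(self) -> int:
        return len(self.client_assignments)

    @property
    def n_clinics(self) -> int:
        return len({c for cs in self.physician_clinics.values() for c in cs})

    def physicians_frame(self) -> pd.DataFrame:
        rows = [
            (p, c, n)
            for p, cs in self.physician_clinics.items()
            for c, n in sorted(cs.items())
        ]
        return pd.DataFrame(rows, columns=["physician_id", "clinic_id", "n_clients"])

    def clients_frame(self) -> pd.DataFrame:
        rows = [
            (cl, p, c)
            for cl, pairs in self.client_assignments.items()
            for p, c in pairs
        ]
        return pd.DataFrame(rows, columns=["client_id", "physician_id", "clinic_id"])


# ---------------------------------------------------------------------------
# internal planted-structure state
# ---------------------------------------------------------------------------


@dataclass
class _Structure:
    n_physicians: int
    primary: np.ndarray  # clinic index per physician
    secondary: np.ndarray  # clinic index or -1
    clinic_members: list[np.ndarray]  # sorted physician indices per clinic
    loads: np.ndarray  # yearly home-panel size per physician
    # client registry (index = creation order)
    cl_home: np.ndarray
    cl_clinic: np.ndarray
    cl_co1: np.ndarray  # within-clinic co-prescriber or -1 (records at cl_clinic)
    cl_co2: np.ndarray  # cross-clinic co-prescriber or -1
    cl_co2_clinic: np.ndarray
    cl_drug: np.ndarray  # 0 = methadone, 1 = buprenorphine/naloxone
    cl_start_year: np.ndarray
    cl_end_year: np.ndarray


def _id_width(n: int, minimum: int) -> int:
    return max(minimum, len(str(max(n - 1, 0))))


def _make_ids(prefix: str, n: int, minimum_width: int) -> np.ndarray:
    w = _id_width(n, minimum_width)
    return np.array([f"{prefix}{i:0{w}d}" for i in range(n)], dtype=object)


def _plant(config: SyntheticConfig, rng: np.random.Generator) -> _Structure:
    """Phase 1: clinics, physicians, memberships and the full client registry."""
    n_clinics = config.n_clinics
    sizes = config._dist("physicians_per_clinic").sample(rng, n_clinics)
    slots = np.repeat(np.arange(n_clinics), sizes)
    rng.shuffle(slots)
    n_slots = len(slots)

    m = config.multi_clinic_fraction
    n_phys = max(1, int(round(n_slots / (1.0 + m))))
    n_multi = int(np.clip(n_slots - n_phys, 0, n_phys))
    n_phys = n_slots - n_multi

    slots = list(slots)
    primary = np.full(n_phys, -1, dtype=np.int64)
    secondary = np.full(n_phys, -1, dtype=np.int64)
    # dual-clinic physicians take two slots at distinct clinics
    pos = 0
    demoted = 0
    for p in range(n_multi):
        a = slots[pos]
        b = slots[pos + 1]
        if a == b:
            for j in range(pos + 2, n_slots):
                if slots[j] != a:
                    slots[pos + 1], slots[j] = slots[j], slots[pos + 1]
                    b = slots[pos + 1]
                    break
        if a == b:  # every remaining slot is at clinic a: demote to single
            primary[p] = a
            secondary[p] = -1
            pos += 1
            demoted += 1
        else:
            primary[p] = a
            secondary[p] = b
            pos += 2
    # demotion frees slots -> extra single-clinic physicians
    singles = slots[pos:]
    extra = len(singles) - (n_phys - n_multi)
    if extra > 0:
        primary = np.concatenate([primary, np.full(extra, -1, dtype=np.int64)])
        secondary = np.concatenate([secondary, np.full(extra, -1, dtype=np.int64)])
        n_phys += extra
    for i, c in enumerate(singles):
        primary[n_multi + i] = c

    members: list[list[int]] = [[] for _ in range(n_clinics)]
    for p in range(n_phys):
        members[primary[p]].append(p)
        if secondary[p] >= 0:
            members[secondary[p]].append(p)
    clinic_members = [np.array(sorted(ms), dtype=np.int64) for ms in members]

    loads = config._dist("clients_per_physician").sample(rng, n_phys)

    # -- client panels, year by year ----------------------------------------
    y0, y1 = config.years
    home_parts, clinic_parts, co1_parts, co2_parts = [], [], [], []
    co2_clinic_parts, drug_parts, sy_parts, ey_parts = [], [], [], []
    sec_share = config.secondary_clinic_load_share
    within_p = config.within_clinic_share_prob
    cross_p = config.cross_clinic_share_prob

    for year in range(y0, y1 + 1):
        if year == y0:
            need = loads.copy()
        else:
            carried = np.zeros(n_phys, dtype=np.int64)
            for h, e in zip(home_parts, ey_parts):
                active = e >= year
                if active.any():
                    carried += np.bincount(h[active], minlength=n_phys)
            need = np.maximum(loads - carried, 0)
        n_new = int(need.sum())
        if n_new == 0:
            continue
        home = np.repeat(np.arange(n_phys), need)
        tenure = rng.geometric(1.0 - config.client_retention, n_new)
        end_year = np.minimum(year + tenure - 1, y1)

        clinic = primary[home].copy()
        u_sec = rng.random(n_new)
        has_sec = secondary[home] >= 0
        to_sec = has_sec & (u_sec < sec_share)
        clinic[to_sec] = secondary[home][to_sec]

        # within-clinic co-prescriber
        co1 = np.full(n_new, -1, dtype=np.int64)
        want1 = rng.random(n_new) < within_p
        for c in range(n_clinics):
            ms = clinic_members[c]
            if len(ms) < 2:
                continue
            sel = np.nonzero(want1 & (clinic == c))[0]
            if len(sel) == 0:
                continue
            r = rng.integers(0, len(ms) - 1, size=len(sel))
            cand = ms[r]
            clash = cand == home[sel]
            cand[clash] = ms[-1]
            co1[sel] = cand

        # cross-clinic co-prescriber
        co2 = np.full(n_new, -1, dtype=np.int64)
        if n_phys > 1 and cross_p > 0:
            want2 = np.nonzero(rng.random(n_new) < cross_p)[0]
            pending = want2
            for _ in range(10):
                if len(pending) == 0:
                    break
                cand = rng.integers(0, n_phys, size=len(pending))
                ok = (
                    (primary[cand] != clinic[pending])
                    & (cand != home[pending])
                    & (cand != co1[pending])
                )
                co2[pending[ok]] = cand[ok]
                pending = pending[~ok]
        co2_clinic = np.where(co2 >= 0, primary[np.maximum(co2, 0)], -1)

        drug = (rng.random(n_new) >= config.drug_mix).astype(np.int8)

        home_parts.append(home)
        clinic_parts.append(clinic)
        co1_parts.append(co1)
        co2_parts.append(co2)
        co2_clinic_parts.append(co2_clinic)
        drug_parts.append(drug)
        sy_parts.append(np.full(n_new, year, dtype=np.int64))
        ey_parts.append(end_year)

    def cat(parts, dtype=np.int64):
        if not parts:
            return np.empty(0, dtype=dtype)
        return np.concatenate(parts).astype(dtype)

    return _Structure(
        n_physicians=n_phys,
        primary=primary,
        secondary=secondary,
        clinic_members=clinic_members,
        loads=loads,
        cl_home=cat(home_parts),
        cl_clinic=cat(clinic_parts),
        cl_co1=cat(co1_parts),
        cl_co2=cat(co2_parts),
        cl_co2_clinic=cat(co2_clinic_parts),
        cl_drug=cat(drug_parts, np.int8),
        cl_start_year=cat(sy_parts),
        cl_end_year=cat(ey_parts),
    )


def _truth_from_structure(s: _Structure, config: SyntheticConfig) -> GroundTruth:
    phys_ids = _make_ids("p", s.n_physicians, 3)
    clinic_ids = _make_ids("k", config.n_clinics, 3)
    client_ids = _make_ids("c", len(s.cl_home), 6)

    physician_clinics: dict[str, dict[str, int]] = {}
    for p in range(s.n_physicians):
        d = {clinic_ids[s.primary[p]]: 0}
        if s.secondary[p] >= 0:
            d.setdefault(clinic_ids[s.secondary[p]], 0)
        physician_clinics[phys_ids[p]] = d

    client_assignments: dict[str, list[tuple[str, str]]] = {}
    for i in range(len(s.cl_home)):
        pairs = [(phys_ids[s.cl_home[i]], clinic_ids[s.cl_clinic[i]])]
        if s.cl_co1[i] >= 0:
            pairs.append((phys_ids[s.cl_co1[i]], clinic_ids[s.cl_clinic[i]]))
        if s.cl_co2[i] >= 0:
            pairs.append((phys_ids[s.cl_co2[i]], clinic_ids[s.cl_co2_clinic[i]]))
        client_assignments[client_ids[i]] = pairs
        for p, c in pairs:
            d = physician_clinics.setdefault(p, {})
            d[c] = d.get(c, 0) + 1
    return GroundTruth(physician_clinics=physician_clinics, client_assignments=client_assignments)


def generate_truth(config: SyntheticConfig) -> GroundTruth:
    """Planted structure only (no dispensation records); identical to the
    truth returned by :func:`generate_cohort` for the same config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    return _truth_from_structure(_plant(config, rng), config)


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a full dispensation-record cohort plus its ground truth.

    Returns a DataFrame with columns ``client_id, physician_id, clinic_id,
    drug, dispense_date`` sorted by (client, date, physician), and the
    :class:`GroundTruth` of the planted structure.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    s = _plant(config, rng)
    truth = _truth_from_structure(s, config)

    gap_dist = config._dist("dispense_gap_model")
    y0, y1 = config.years
    hs = config.home_script_share

    client_codes, phys_codes, clinic_codes, drug_codes, dates = [], [], [], [], []
    n_clients = len(s.cl_home)

    for year in range(y0, y1 + 1):
        act = np.nonzero((s.cl_start_year <= year) & (s.cl_end_year >= year))[0]
        n_act = len(act)
        if n_act == 0:
            continue
        year_start = np.datetime64(f"{year}-01-01")
        n_days = int((np.datetime64(f"{year + 1}-01-01") - year_start) / np.timedelta64(1, "D"))

        is_new = s.cl_start_year[act] == year
        d0 = np.where(
            is_new,
            rng.integers(0, max(n_days - 65, 1), size=n_act),
            rng.integers(0, 21, size=n_act),
        )
        continuing = s.cl_end_year[act] > year
        span = rng.integers(30, 340, size=n_act)
        last = np.where(continuing, n_days - 1, np.minimum(d0 + span, n_days - 1))

        # dispensation days: cumulative day-differences from the gap model
        max_n = n_days + 1
        diffs = gap_dist.sample(rng, n_act * max_n).reshape(n_act, max_n)
        days = d0[:, None] + np.concatenate(
            [np.zeros((n_act, 1), dtype=np.int64), np.cumsum(diffs, axis=1)], axis=1
        )
        keep = days <= last[:, None]
        counts = keep.sum(axis=1)
        row_client = np.repeat(act, counts)
        row_days = days[keep]
        # position of each row within its client's yearly stream
        offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
        pos = np.arange(len(row_client)) - np.repeat(offsets, counts)

        home = s.cl_home[row_client]
        co1 = s.cl_co1[row_client]
        co2 = s.cl_co2[row_client]
        has1 = co1 >= 0
        has2 = co2 >= 0

        u = rng.random(len(row_client))
        choice = np.zeros(len(row_client), dtype=np.int8)
        both = has1 & has2
        mid = hs + (1.0 - hs) / 2.0
        choice[both & (u >= hs) & (u < mid)] = 1
        choice[both & (u >= mid)] = 2
        choice[has1 & ~has2 & (u >= hs)] = 1
        choice[~has1 & has2 & (u >= hs)] = 2
        # guarantee planted co-prescribers appear at least once per year
        choice[pos == 0] = 0
        first_co = np.where(has1, 1, np.where(has2, 2, 0)).astype(np.int8)
        at1 = pos == 1
        choice[at1] = first_co[at1]
        at2 = (pos == 2) & both
        choice[at2] = 2

        phys = home.copy()
        phys[choice == 1] = co1[choice == 1]
        phys[choice == 2] = co2[choice == 2]
        clin = s.cl_clinic[row_client].copy()
        c2 = choice == 2
        clin[c2] = s.cl_co2_clinic[row_client][c2]

        client_codes.append(row_client)
        phys_codes.append(phys)
        clinic_codes.append(clin)
        drug_codes.append(s.cl_drug[row_client])
        dates.append(year_start + row_days.astype("timedelta64[D]"))

    client_ids = pd.CategoricalDtype(_make_ids("c", n_clients, 6), ordered=False)
    phys_ids = pd.CategoricalDtype(_make_ids("p", s.n_physicians, 3), ordered=False)
    clinic_ids = pd.CategoricalDtype(_make_ids("k", config.n_clinics, 3), ordered=False)
    drug_dtype = pd.CategoricalDtype(list(DRUGS), ordered=False)

    def col(parts, dtype):
        codes = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        return pd.Categorical.from_codes(codes, dtype=dtype)

    records = pd.DataFrame(
        {
            "client_id": col(client_codes, client_ids),
            "physician_id": col(phys_codes, phys_ids),
            "clinic_id": col(clinic_codes, clinic_ids),
            "drug": col([d.astype(np.int64) for d in drug_codes], drug_dtype),
            "dispense_date": (
                np.concatenate(dates) if dates else np.empty(0, dtype="datetime64[D]")
            ).astype("datetime64[ns]"),
        }
    )
    records = records.sort_values(
        ["client_id", "dispense_date", "physician_id"], kind="mergesort"
    ).reset_index(drop=True)
    return records, truth


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_records(records: pd.DataFrame, path) -> None:
    """CSV with header client_id,physician_id,clinic_id,drug,dispense_date."""
    out = records.copy()
    out["dispense_date"] = pd.to_datetime(out["dispense_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_truth(truth: GroundTruth, path) -> None:
    """Write the ground truth as two CSV sidecars next to ``path``:
    ``<stem>.physicians.csv`` and ``<stem>.clients.csv``."""
    base = Path(path)
    stem = base.with_suffix("")
    truth.physicians_frame().to_csv(f"{stem}.physicians.csv", index=False)
    truth.clients_frame().to_csv(f"{stem}.clients.csv", index=False)


def read_truth(path) -> GroundTruth:
    stem = Path(path).with_suffix("")
    phys = pd.read_csv(f"{stem}.physicians.csv")
    clients = pd.read_csv(f"{stem}.clients.csv")
    physician_clinics: dict[str, dict[str, int]] = {}
    for row in phys.itertuples(index=False):
        physician_clinics.setdefault(row.physician_id, {})[row.clinic_id] = int(row.n_clients)
    client_assignments: dict[str, list[tuple[str, str]]] = {}
    for row in clients.itertuples(index=False):
        client_assignments.setdefault(row.client_id, []).append((row.physician_id, row.clinic_id))
    return GroundTruth(physician_clinics=physician_clinics, client_assignments=client_assignments)
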