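"""Gold-standard clinic assignment and pairwise concordance evaluation.

The gold standard comes from the clinic labels on prescription records: a
connection rule decides which clinics a physician "truly" belongs to (any
clinic with a record; the plurality clinic; or every clinic holding at
least 15/30/45% of the physician's distinct yearly clients). Two physicians
are a gold-positive pair if their clinic sets intersect.

A community partition classifies the same pairs (same community or not),
yielding a 2x2 confusion over all C(P,2) physician pairs from which the
agreement suite is computed: overall / positive / negative agreement,
Gwet's AC1 (chance-corrected agreement robust to the low prevalence of
same-clinic pairs, where Cohen's kappa degenerates), and sensitivity /
specificity / PPV / NPV with Wilson 95% CIs. AC1 interval defaults to the
delta-method variance treating pairs as independent ratings, with a
pair-resampling bootstrap alternative.

Community-to-clinic matching reports, for each detected community, the
best-overlap clinic with recall (overlap / network physicians attached to
the clinic), 1-purity (share of community members outside that clinic) and
the F-measure (harmonic mean of purity and recall).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .communities import CommunityPartition

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClinicConnectionRule:
    """``any`` | ``majority`` (plurality with lexicographic tie-break) |
    ``percent`` (clinics with >= threshold% of the physician's clients;
    ``strict=True`` switches to >)."""

    variant: str
    threshold: float | None = None
    strict: bool = False

    def __post_init__(self) -> None:
        if self.variant not in ("any", "majority", "percent"):
            raise ValueError(f"unknown connection rule variant {self.variant!r}")
        if self.variant == "percent":
            if self.threshold is None or not (0 < self.threshold < 100):
                raise ValueError(f"percent rule needs threshold in (0, 100), got {self.threshold}")
        elif self.threshold is not None:
            raise ValueError(f"{self.variant} rule takes no threshold")

    @classmethod
    def parse(cls, text: str) -> "ClinicConnectionRule":
        if ":" in text:
            variant, thr = text.split(":", 1)
            return cls(variant.strip(), float(thr))
        return cls(text.strip())

    def __str__(self) -> str:
        if self.threshold is None:
            return self.variant
        return f"{self.variant}:{self.threshold:g}"


@dataclass(frozen=True)
class GoldStandardAssignment:
    """Physician -> set of clinics under a connection rule; induces the
    pairwise same-clinic gold labels."""

    clinics_of: dict[str, frozenset[str]]
    rule: ClinicConnectionRule

    def same_clinic(self, i: str, j: str) -> bool:
        return bool(self.clinics_of[i] & self.clinics_of[j])

    def clinic_members(self, physicians=None) -> dict[str, set[str]]:
        """Clinic -> physicians attached to it (restricted to ``physicians``
        when given)."""
        pool = self.clinics_of if physicians is None else {
            p: self.clinics_of[p] for p in physicians
        }
        out: dict[str, set[str]] = {}
        for p, clinics in pool.items():
            for c in clinics:
                out.setdefault(c, set()).add(p)
        return out


def assign_clinics(records: pd.DataFrame, rule: ClinicConnectionRule) -> GoldStandardAssignment:
    """Derive each physician's gold clinic set from one year of records.

    Client counts are distinct clients per (physician, clinic); the percent
    rule's denominator is the physician's total distinct clients that year.
    """
    inc = records[["physician_id", "clinic_id", "client_id"]].astype(str).drop_duplicates()
    per_clinic = (
        inc.groupby(["physician_id", "clinic_id"], observed=True)["client_id"]
        .nunique()
        .reset_index(name="n")
    )
    totals = (
        records[["physician_id", "client_id"]]
        .astype(str)
        .drop_duplicates()
        .groupby("physician_id", observed=True)
        .size()
    )
    clinics_of: dict[str, frozenset[str]] = {}
    for phys, grp in per_clinic.groupby("physician_id", observed=True):
        counts = dict(zip(grp["clinic_id"], grp["n"]))
        if rule.variant == "any":
            chosen = set(counts)
        elif rule.variant == "majority":
            top = max(counts.values())
            candidates = sorted(c for c, n in counts.items() if n == top)
            chosen = {candidates[0]}
            if top * 2 <= totals[phys]:
                log.debug("physician %s: plurality clinic holds <= 50%% of clients", phys)
        else:  # percent
            cut = rule.threshold / 100.0 * totals[phys]
            if rule.strict:
                chosen = {c for c, n in counts.items() if n > cut}
            else:
                chosen = {c for c, n in counts.items() if n >= cut}
        clinics_of[str(phys)] = frozenset(chosen)
    return GoldStandardAssignment(clinics_of=clinics_of, rule=rule)


# ---------------------------------------------------------------------------
# pairwise confusion and agreement metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairConfusion:
    """Counts over unordered physician pairs: a = same clinic & same
    community, b = different clinic & same community, c = same clinic &
    different community, d = different clinic & different community."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def pair_confusion(
    partition: CommunityPartition | dict,
    gold: GoldStandardAssignment,
    physicians,
) -> PairConfusion:
    """Count the 2x2 cells over all C(P,2) unordered pairs of ``physicians``."""
    assignment = partition.assignment if isinstance(partition, CommunityPartition) else dict(partition)
    phys = sorted(map(str, physicians))
    missing_part = [p for p in phys if p not in assignment]
    missing_gold = [p for p in phys if p not in gold.clinics_of]
    if missing_part or missing_gold:
        raise ValueError(
            f"coverage mismatch: partition misses {missing_part[:10]}, gold misses {missing_gold[:10]}"
        )
    labels = pd.Series([assignment[p] for p in phys]).astype("category").cat.codes.to_numpy()
    clinics = sorted({c for p in phys for c in gold.clinics_of[p]})
    cindex = {c: i for i, c in enumerate(clinics)}
    B = np.zeros((len(phys), max(len(clinics), 1)), dtype=bool)
    for i, p in enumerate(phys):
        for c in gold.clinics_of[p]:
            B[i, cindex[c]] = True
    same_clinic = B @ B.T
    same_comm = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(phys), k=1)
    sc = same_clinic[iu]
    sm = same_comm[iu]
    return PairConfusion(
        a=int(np.sum(sc & sm)),
        b=int(np.sum(~sc & sm)),
        c=int(np.sum(sc & ~sm)),
        d=int(np.sum(~sc & ~sm)),
    )


@dataclass(frozen=True)
class Interval:
    lo: float
    hi: float

    def contains(self, x: float) -> bool:
        return self.lo - 1e-12 <= x <= self.hi + 1e-12


def _ratio(num: float, den: float) -> float:
    """Ratios with zero denominator are undefined (NaN), never 0."""
    return num / den if den > 0 else float("nan")


def gwet_ac1(confusion: PairConfusion) -> float:
    """Gwet's first-order agreement coefficient on the 2x2 pair table:
    AC1 = (p_a - p_e)/(1 - p_e) with p_e = 2 pi (1 - pi),
    pi = ((a+b)/n + (a+c)/n)/2."""
    n = confusion.n
    if n == 0:
        raise ValueError("empty confusion table")
    pa = (confusion.a + confusion.d) / n
    p1 = (confusion.a + confusion.b) / n
    p2 = (confusion.a + confusion.c) / n
    pi = (p1 + p2) / 2.0
    pe = 2.0 * pi * (1.0 - pi)
    if pe >= 1.0:
        return float("nan")
    return (pa - pe) / (1.0 - pe)


def gwet_ac1_ci(
    confusion: PairConfusion,
    level: float = 0.95,
    method: str = "delta",
    n_boot: int = 2000,
    seed: int = 0,
) -> Interval:
    """Confidence interval for AC1 treating pairs as independent ratings.

    ``delta`` uses the linearized (delta-method) variance of the estimator;
    ``bootstrap`` resamples pairs with replacement. Degenerate tables give a
    point interval.
    """
    n = confusion.n
    if n <= 1:
        raise ValueError("need at least two pairs for an interval")
    ac1 = gwet_ac1(confusion)
    if math.isnan(ac1):
        return Interval(float("nan"), float("nan"))
    if method == "delta":
        var = _ac1_delta_variance(confusion)
        z = norm.ppf(0.5 + level / 2.0)
        half = z * math.sqrt(var)
        return Interval(max(ac1 - half, -1.0), min(ac1 + half, 1.0))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        cells = np.array([confusion.a, confusion.b, confusion.c, confusion.d])
        draws = rng.multinomial(n, cells / n, size=n_boot)
        vals = []
        for a, b, c, d in draws:
            v = gwet_ac1(PairConfusion(int(a), int(b), int(c), int(d)))
            if not math.isnan(v):
                vals.append(v)
        lo, hi = np.quantile(vals, [(1 - level) / 2.0, 0.5 + level / 2.0])
        return Interval(float(lo), float(hi))
    raise ValueError(f"unknown AC1 CI method {method!r}")


def _ac1_delta_variance(confusion: PairConfusion) -> float:
    """Linearized variance of AC1 over n independent pair ratings.

    Each pair falls in one of the four cells; per-pair agreement pa_i is 1
    for cells a/d and 0 for b/c, and the per-pair category prevalence is
    pi_i = (r1 + r2)/2 (1, 0.5, 0.5, 0 for a, b, c, d). The linearization
    is ac1_i* = ac1_i - 2 (1 - ac1) (pe_i - pe)/(1 - pe) with
    ac1_i = (pa_i - pe)/(1 - pe) and pe_i = pi_i (1 - pi) + (1 - pi_i) pi.
    """
    n = confusion.n
    counts = np.array([confusion.a, confusion.b, confusion.c, confusion.d], dtype=float)
    pa_i = np.array([1.0, 0.0, 0.0, 1.0])
    pi_i = np.array([1.0, 0.5, 0.5, 0.0])
    pa = counts @ pa_i / n
    pi = counts @ pi_i / n
    pe = 2.0 * pi * (1.0 - pi)
    ac1 = (pa - pe) / (1.0 - pe)
    pe_i = pi_i * (1.0 - pi) + (1.0 - pi_i) * pi
    ac1_i = (pa_i - pe) / (1.0 - pe)
    ac1_star = ac1_i - 2.0 * (1.0 - ac1) * (pe_i - pe) / (1.0 - pe)
    ss = counts @ (ac1_star - ac1) ** 2
    return float(ss / (n * (n - 1)))


def _wilson(successes: float, trials: float, level: float) -> Interval:
    if trials <= 0 or math.isnan(successes):
        return Interval(float("nan"), float("nan"))
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method="wilson")
    return Interval(float(lo), float(hi))


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement and validity suite over the physician-pair confusion table."""

    confusion: PairConfusion
    overall: float
    positive_agreement: float
    negative_agreement: float
    ac1: float
    ac1_ci: Interval
    sensitivity: float
    sensitivity_ci: Interval
    specificity: float
    specificity_ci: Interval
    ppv: float
    ppv_ci: Interval
    npv: float
    npv_ci: Interval
    level: float = 0.95
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "a": self.confusion.a,
            "b": self.confusion.b,
            "c": self.confusion.c,
            "d": self.confusion.d,
            "n_pairs": self.confusion.n,
            "overall": self.overall,
            "positive_agreement": self.positive_agreement,
            "negative_agreement": self.negative_agreement,
            "ac1": self.ac1,
            "ac1_lo": self.ac1_ci.lo,
            "ac1_hi": self.ac1_ci.hi,
            "sensitivity": self.sensitivity,
            "sensitivity_lo": self.sensitivity_ci.lo,
            "sensitivity_hi": self.sensitivity_ci.hi,
            "specificity": self.specificity,
            "specificity_lo": self.specificity_ci.lo,
            "specificity_hi": self.specificity_ci.hi,
            "ppv": self.ppv,
            "ppv_lo": self.ppv_ci.lo,
            "ppv_hi": self.ppv_ci.hi,
            "npv": self.npv,
            "npv_lo": self.npv_ci.lo,
            "npv_hi": self.npv_ci.hi,
        }


def concordance_metrics(
    confusion: PairConfusion, level: float = 0.95, ac1_method: str = "delta", seed: int = 0
) -> ConcordanceReport:
    """Compute the full agreement/validity suite with confidence intervals.

    Undefined ratios (zero denominators) are reported as NaN and flagged.
    """
    a, b, c, d, n = confusion.a, confusion.b, confusion.c, confusion.d, confusion.n
    if n == 0:
        raise ValueError("empty confusion table")
    overall = (a + d) / n
    pa = _ratio(2 * a, 2 * a + b + c)
    na = _ratio(2 * d, 2 * d + b + c)
    ac1 = gwet_ac1(confusion)
    flags = []
    if math.isnan(ac1):
        flags.append("ac1_undefined")
    ac1_ci = (
        gwet_ac1_ci(confusion, level=level, method=ac1_method, seed=seed)
        if n > 1 and not math.isnan(ac1)
        else Interval(float("nan"), float("nan"))
    )
    sens = _ratio(a, a + c)
    spec = _ratio(d, b + d)
    ppv = _ratio(a, a + b)
    npv = _ratio(d, c + d)
    for name, v in (("positive_agreement", pa), ("negative_agreement", na),
                    ("sensitivity", sens), ("specificity", spec), ("ppv", ppv), ("npv", npv)):
        if math.isnan(v):
            flags.append(f"{name}_undefined")
    return ConcordanceReport(
        confusion=confusion,
        overall=overall,
        positive_agreement=pa,
        negative_agreement=na,
        ac1=ac1,
        ac1_ci=ac1_ci,
        sensitivity=sens,
        sensitivity_ci=_wilson(a, a + c, level),
        specificity=spec,
        specificity_ci=_wilson(d, b + d, level),
        ppv=ppv,
        ppv_ci=_wilson(a, a + b, level),
        npv=npv,
        npv_ci=_wilson(d, c + d, level),
        level=level,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# community-to-clinic matching
# ---------------------------------------------------------------------------


@dataclass
class CommunityMatchReport:
    """Per-community best-matching clinic with recall / 1-purity / F, plus
    medians and quartiles across communities."""

    detail: pd.DataFrame  # community, size, matched_clinic, overlap, recall, one_minus_purity, f
    summary: dict[str, dict[str, float]]


def community_match(
    partition: CommunityPartition | dict, gold: GoldStandardAssignment
) -> CommunityMatchReport:
    """Match each detected community to its best-overlap clinic.

    Ties in overlap go to the clinic with more attached network physicians,
    then to the lexicographically smaller clinic ID. Recall divides by the
    number of network physicians attached to the matched clinic; purity by
    the community size; F is their harmonic mean (0 when either is 0).
    """
    assignment = partition.assignment if isinstance(partition, CommunityPartition) else dict(partition)
    physicians = sorted(assignment)
    members_of = gold.clinic_members(physicians)
    comms: dict[str, list[str]] = {}
    for p, lab in assignment.items():
        comms.setdefault(lab, []).append(p)
    rows = []
    for lab in sorted(comms):
        members = comms[lab]
        overlap: dict[str, int] = {}
        for p in members:
            for c in gold.clinics_of.get(p, ()):  # physicians may have no clinic under strict rules
                overlap[c] = overlap.get(c, 0) + 1
        if not overlap:
            rows.append((lab, len(members), None, 0, float("nan"), float("nan"), float("nan")))
            continue
        matched = min(
            overlap, key=lambda c: (-overlap[c], -len(members_of[c]), c)
        )
        ov = overlap[matched]
        recall = ov / len(members_of[matched])
        purity = ov / len(members)
        f = 2 * purity * recall / (purity + recall) if purity + recall > 0 else 0.0
        rows.append((lab, len(members), matched, ov, recall, 1.0 - purity, f))
    detail = pd.DataFrame(
        rows,
        columns=["community", "size", "matched_clinic", "overlap", "recall", "one_minus_purity", "f"],
    )
    summary = {}
    for col in ("recall", "one_minus_purity", "f"):
        vals = detail[col].dropna().to_numpy()
        if len(vals):
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        else:
            q1 = med = q3 = float("nan")
        summary[col] = {"median": float(med), "q1": float(q1), "q3": float(q3)}
    return CommunityMatchReport(detail=detail, summary=summary)


# ---------------------------------------------------------------------------
# grouping structure summaries
# ---------------------------------------------------------------------------


def summarize_structures(groups: dict[str, set], records: pd.DataFrame, network=None) -> pd.DataFrame:
    """Median (Q1-Q3) of per-group physician counts, distinct clients,
    physician client loads (pooled over physicians) and within-group ties.

    ``groups`` maps a label (community or clinic) to its physician set;
    ``network`` supplies the tie counts (edges among group members) and is
    built from the records when omitted. Quantiles use the linear
    interpolation convention.
    """
    from .network import build_shared_client_network

    if network is None:
        network = build_shared_client_network(records)
    inc = records[["physician_id", "client_id"]].astype(str).drop_duplicates()
    load = inc.groupby("physician_id", observed=True)["client_id"].nunique()
    clients_of = inc.groupby("physician_id", observed=True)["client_id"].agg(set)

    n_phys, n_clients, n_ties, loads_pooled = [], [], [], []
    for lab in sorted(groups):
        members = sorted(map(str, groups[lab]))
        n_phys.append(len(members))
        clients: set = set()
        for p in members:
            clients |= clients_of.get(p, set())
            loads_pooled.append(int(load.get(p, 0)))
        n_clients.append(len(clients))
        sub = network.subgraph([m for m in members if m in network])
        n_ties.append(sum(w for _, _, w in sub.edges(data="weight")))

    def stats(vals):
        arr = np.asarray(vals, dtype=float)
        if len(arr) == 0:
            return dict(median=float("nan"), q1=float("nan"), q3=float("nan"))
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
        return dict(median=float(med), q1=float(q1), q3=float(q3))

    rows = {
        "n_physicians": stats(n_phys),
        "n_clients": stats(n_clients),
        "client_load": stats(loads_pooled),
        "n_ties": stats(n_ties),
    }
    return pd.DataFrame(rows).T[["median", "q1", "q3"]]
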