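"""Experimental grid: tie definitions x detection algorithms x connection
rules x years, reproducing the comparison-table layout on a cohort.

Each grid row evaluates one configuration for one year: filter to the year,
build the network under the tie definition, detect communities, derive the
gold standard under the connection rule, and compute the concordance suite
and community-matching summaries. Failing configurations become error rows
rather than aborting the run, and re-running with the same config and seeds
reproduces the output byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .communities import detect
from .evaluation import (
    ClinicConnectionRule,
    assign_clinics,
    community_match,
    concordance_metrics,
    pair_confusion,
)
from .network import TieDefinition, build_shared_client_network
from .records import filter_calendar_year

log = logging.getLogger(__name__)

#: 10 tie definitions x 7 algorithms x 5 connection rules = 350 network
#: versions per calendar year.
DEFAULT_TIE_DEFINITIONS = [
    "absolute:1",
    "absolute:2",
    "absolute:5",
    "absolute:10",
    "absolute:20",
    "shared_episode",
    "relative:20",
    "relative:40",
    "relative:60",
    "relative:80",
]
DEFAULT_ALGORITHMS = [
    "modularity:1",
    "modularity:2",
    "modularity:3",
    "modularity:4",
    "louvain",
    "walktrap",
    "label_propagation",
]
DEFAULT_CONNECTION_RULES = ["any", "majority", "percent:15", "percent:30", "percent:45"]

RESULT_COLUMNS = [
    "year",
    "tie_definition",
    "algorithm",
    "iterations",
    "connection_rule",
    "seed",
    "n_physicians",
    "n_edges",
    "n_communities",
    "a",
    "b",
    "c",
    "d",
    "n_pairs",
    "overall",
    "positive_agreement",
    "negative_agreement",
    "ac1",
    "ac1_lo",
    "ac1_hi",
    "sensitivity",
    "sensitivity_lo",
    "sensitivity_hi",
    "specificity",
    "specificity_lo",
    "specificity_hi",
    "ppv",
    "ppv_lo",
    "ppv_hi",
    "npv",
    "npv_lo",
    "npv_hi",
    "recall_median",
    "one_minus_purity_median",
    "f_median",
    "error",
]


@dataclass
class GridConfig:
    """Enumeration of the experimental grid; defaults reproduce the full
    350-versions-per-year comparison."""

    tie_definitions: list[str] = field(default_factory=lambda: list(DEFAULT_TIE_DEFINITIONS))
    algorithms: list[str] = field(default_factory=lambda: list(DEFAULT_ALGORITHMS))
    connection_rules: list[str] = field(default_factory=lambda: list(DEFAULT_CONNECTION_RULES))
    years: list[int] | None = None  # None = every year present in the records
    seeds: list[int] = field(default_factory=lambda: [0])

    def validate(self) -> None:
        for name in ("tie_definitions", "algorithms", "connection_rules", "seeds"):
            if not getattr(self, name):
                raise ValueError(f"grid config field {name} must be non-empty")
        for t in self.tie_definitions:
            TieDefinition.parse(t)
        for r in self.connection_rules:
            ClinicConnectionRule.parse(r)

    @property
    def n_configurations(self) -> int:
        return (
            len(self.tie_definitions)
            * len(self.algorithms)
            * len(self.connection_rules)
            * len(self.seeds)
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "GridConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text()))
        cfg.validate()
        return cfg


def _algorithm_iterations(algorithm: str) -> int:
    if algorithm.startswith("modularity") and ":" in algorithm:
        return int(algorithm.split(":", 1)[1])
    return 1


def run_grid(records: pd.DataFrame, config: GridConfig, progress: bool = False) -> pd.DataFrame:
    """Evaluate every grid configuration on every requested year.

    Returns one row per (year, tie definition, algorithm, connection rule,
    seed); a configuration that raises is recorded as an error row.
    """
    config.validate()
    years = config.years
    if years is None:
        years = sorted(pd.to_datetime(records["dispense_date"]).dt.year.unique())
    total = len(years) * config.n_configurations
    log.info("running grid: %d configurations over %d year(s) (%d rows)",
             config.n_configurations, len(years), total)

    rows = []
    done = 0
    for year in years:
        recs = filter_calendar_year(records, int(year))
        base = build_shared_client_network(recs, year=int(year)) if not recs.empty else None
        golds = {}
        for rule_s in config.connection_rules:
            try:
                golds[rule_s] = assign_clinics(recs, ClinicConnectionRule.parse(rule_s))
            except Exception as exc:  # pragma: no cover - defensive
                golds[rule_s] = exc
        for tie_s in config.tie_definitions:
            tie = TieDefinition.parse(tie_s)
            try:
                network = tie.build(recs, base=base, year=int(year))
            except Exception as exc:
                network = exc
            for alg in config.algorithms:
                for seed in config.seeds:
                    try:
                        if isinstance(network, Exception):
                            raise network
                        partition = detect(network, alg, seed=seed)
                    except Exception as exc:
                        partition = exc
                    for rule_s in config.connection_rules:
                        done += 1
                        row = {
                            "year": int(year),
                            "tie_definition": tie_s,
                            "algorithm": alg,
                            "iterations": _algorithm_iterations(alg),
                            "connection_rule": rule_s,
                            "seed": seed,
                            "error": "",
                        }
                        try:
                            if isinstance(partition, Exception):
                                raise partition
                            gold = golds[rule_s]
                            if isinstance(gold, Exception):
                                raise gold
                            confusion = pair_confusion(partition, gold, list(network.nodes))
                            report = concordance_metrics(confusion)
                            match = community_match(partition, gold)
                            row.update(report.to_dict())
                            row.update(
                                n_physicians=network.number_of_nodes(),
                                n_edges=network.number_of_edges(),
                                n_communities=partition.n_communities,
                                recall_median=match.summary["recall"]["median"],
                                one_minus_purity_median=match.summary["one_minus_purity"]["median"],
                                f_median=match.summary["f"]["median"],
                            )
                        except Exception as exc:
                            row["error"] = f"{type(exc).__name__}: {exc}"
                            log.warning("grid row failed (%s/%s/%s/%s): %s",
                                        year, tie_s, alg, rule_s, exc)
                        rows.append(row)
                        if progress and done % 50 == 0:
                            log.info("grid progress: %d/%d rows", done, total)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def select_best(
    rows: pd.DataFrame,
    specificity_floor: float = 0.9,
    npv_floor: float = 0.9,
) -> pd.Series:
    """Pick the best-balanced configuration.

    Sensitivity and PPV are prioritized while specificity and NPV are
    expected to be high: among rows with specificity and NPV at or above the
    floors, maximize min(sensitivity, PPV); if none qualifies, maximize over
    all valid rows. Ties resolve to the earliest row (configuration order).
    """
    if rows.empty:
        raise ValueError("no grid rows to select from")
    valid = rows[rows["error"].fillna("").eq("") & rows["sensitivity"].notna() & rows["ppv"].notna()]
    if valid.empty:
        raise ValueError("all grid rows have undefined metrics")
    eligible = valid[(valid["specificity"] >= specificity_floor) & (valid["npv"] >= npv_floor)]
    pool = eligible if not eligible.empty else valid
    score = pool[["sensitivity", "ppv"]].min(axis=1)
    return pool.loc[score.idxmax()]
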