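"""Summary artifacts combining the three selection criteria.

Produces Table-1-style counts and percentages of elevated/lowered
miRNAs per criterion, a Table-2-style ranked listing of the
DC-SIS-selected miRNAs, and the pairwise/triple intersections of the
three selected sets. Percentages are 100 * count / n_selected rounded
half-up to one decimal, matching the usual printed style.

miRNAs with an exactly zero mean difference (possible on synthetic
data) are counted in a separate logged ``unchanged`` bucket rather than
being forced into elevated/lowered.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (2.25 -> 2.3 at one decimal)."""
    exp = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(exp, rounding=ROUND_HALF_UP))


def percent_split(n_elevated: int, n_lowered: int) -> tuple[float, float]:
    """Percentages of elevated/lowered among the selected, half-up to 0.1."""
    total = n_elevated + n_lowered
    if total == 0:
        return 0.0, 0.0
    return (round_half_up(100.0 * n_elevated / total),
            round_half_up(100.0 * n_lowered / total))


@dataclass
class CriterionCounts:
    n_selected: int
    n_elevated: int
    n_lowered: int
    n_unchanged: int
    pct_elevated: float
    pct_lowered: float
    flagged_empty: bool = False


@dataclass
class CriteriaSummary:
    """Per-criterion direction counts plus intersection sizes."""

    criteria: dict = field(default_factory=dict)
    intersections: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, c in self.criteria.items():
            rows.append({"criterion": name, "n_selected": c.n_selected,
                         "n_elevated": c.n_elevated,
                         "n_lowered": c.n_lowered,
                         "n_unchanged": c.n_unchanged,
                         "pct_elevated": c.pct_elevated,
                         "pct_lowered": c.pct_lowered})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Criteria summary", "================",
                 self.to_frame().to_string(index=False), "",
                 "Intersections:"]
        for key, val in self.intersections.items():
            if key.startswith("n_") or key.endswith("_subset"):
                lines.append(f"  {key}: {val}")
        return "\n".join(lines)


def summarize_criterion(selected_ids, de_table: pd.DataFrame) -> CriterionCounts:
    """Direction counts and percentages for one criterion's selected set."""
    selected_ids = set(selected_ids)
    known = set(de_table["mirna_id"])
    unknown = selected_ids - known
    if unknown:
        raise InputError(f"selected ids absent from the differential table: "
                         f"{sorted(unknown)[:5]}")
    sub = de_table[de_table["mirna_id"].isin(selected_ids)]
    n_elevated = int((sub["direction"] == "elevated").sum())
    n_lowered = int((sub["direction"] == "lowered").sum())
    n_unchanged = int((sub["direction"] == "unchanged").sum())
    if n_unchanged:
        logger.info("%d selected miRNAs with exactly zero mean difference "
                    "counted as 'unchanged'", n_unchanged)
    flagged_empty = len(selected_ids) == 0
    if flagged_empty:
        logger.warning("criterion selected no miRNAs; percentages reported "
                       "as 0")
    pct_elevated, pct_lowered = percent_split(n_elevated, n_lowered)
    return CriterionCounts(n_selected=len(selected_ids),
                           n_elevated=n_elevated, n_lowered=n_lowered,
                           n_unchanged=n_unchanged,
                           pct_elevated=pct_elevated,
                           pct_lowered=pct_lowered,
                           flagged_empty=flagged_empty)


def intersect_criteria(sets: dict) -> dict:
    """Sizes and members of every pairwise and the triple intersection.

    Expects keys among {"t_test", "fdr", "dcsis"}; asserts the
    structural nesting fdr within t_test (BH never shrinks a p-value)
    and reports whether fdr is contained in dcsis (empirical, not
    guaranteed).
    """
    names = sorted(sets)
    report: dict = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = sorted(sets[a] & sets[b])
            report[f"{a}&{b}"] = inter
            report[f"n_{a}&{b}"] = len(inter)
    if len(names) >= 3:
        triple = set.intersection(*(set(sets[n]) for n in names))
        report["&".join(names)] = sorted(triple)
        report["n_" + "&".join(names)] = len(triple)
    if "fdr" in sets and "t_test" in sets:
        if not set(sets["fdr"]) <= set(sets["t_test"]):
            raise AssertionError(
                "FDR-significant set not contained in the t-test set; "
                "the q >= p invariant is violated upstream")
        report["fdr_in_t_test_subset"] = True
    if "fdr" in sets and "dcsis" in sets:
        report["fdr_in_dcsis_subset"] = bool(
            set(sets["fdr"]) <= set(sets["dcsis"]))
    return report


def ranked_listing(de_table: pd.DataFrame,
                   screen_table: pd.DataFrame) -> pd.DataFrame:
    """Table-2-style listing of the DC-SIS-selected miRNAs.

    Columns: id, direction, fold change, p, q, omega, rank; sorted by
    omega descending.
    """
    selected = screen_table[screen_table["selected"]]
    missing = set(selected["mirna_id"]) - set(de_table["mirna_id"])
    if missing:
        raise InputError(f"screened ids absent from the differential "
                         f"table: {sorted(missing)[:5]}")
    merged = selected.merge(de_table, on="mirna_id", how="left")
    cols = ["mirna_id", "direction", "fold_change", "p", "q", "omega", "rank"]
    return (merged[cols].sort_values(["omega", "mirna_id"],
                                     ascending=[False, True], kind="stable")
            .reset_index(drop=True))


def criteria_summary(de_table: pd.DataFrame, screen_table: pd.DataFrame,
                     alpha: float = 0.05) -> CriteriaSummary:
    """Full three-criteria summary from the two result tables."""
    sets = {
        "t_test": set(de_table.loc[de_table["p"] <= alpha, "mirna_id"]),
        "fdr": set(de_table.loc[de_table["q"] <= alpha, "mirna_id"]),
        "dcsis": set(screen_table.loc[screen_table["selected"], "mirna_id"]),
    }
    summary = CriteriaSummary()
    for name, ids in sets.items():
        summary.criteria[name] = summarize_criterion(ids, de_table)
    summary.intersections = intersect_criteria(sets)
    return summary


def write_report(summary: CriteriaSummary, listing: pd.DataFrame,
                 directory) -> dict:
    """Write summary.tsv, listing.tsv and intersections.json."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {"summary": directory / "summary.tsv",
             "listing": directory / "listing.tsv",
             "intersections": directory / "intersections.json"}
    summary.to_frame().to_csv(paths["summary"], sep="\t", index=False)
    listing.to_csv(paths["listing"], sep="\t", index=False)
    paths["intersections"].write_text(
        json.dumps(summary.intersections, indent=1, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
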