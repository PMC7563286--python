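"""Comparative analysis of simulated flux distributions.

Two conditions are compared on a common reaction set: strictly
positive fluxes are log2-transformed and normalized by the sample SD
of each dataset's log2 values; the per-reaction difference of the
normalized values is the fold change.  A data-driven cut-off is then
chosen as the smallest value for which fewer than a fixed proportion
(default 30%) of reactions change significantly, and reactions are
classified up / down / unchanged.  Fluxes <= 0, for which the log2
transform is undefined, are carried through unchanged and classified
``nonpositive`` — they appear in the counts but not in the numeric
comparison.

Pathway- and category-level summaries aggregate the classification
(e.g. the carbon-vs-nitrogen affected-reaction ratio), and the
classification can be exported as a KEGG Mapper color file.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .fba import FluxDistribution, SolverStatus
from .model_io import MetabolicModel

logger = logging.getLogger(__name__)

FluxClass = Literal["up", "down", "unchanged", "nonpositive"]

KEGG_COLORS = {
    "up": "blue",
    "down": "red",
    "unchanged": "lightgreen",
    "nonpositive": "gray",
}


@dataclass
class FluxComparison:
    """Per-reaction fold changes and classes between two conditions."""

    condition_pair: tuple[str, str]
    table: pd.DataFrame  # index reaction_id; flux_a, flux_b, transformed_a,
    # transformed_b, fold_change, class
    cutoff: float
    sd_a: float
    sd_b: float

    def classes(self) -> pd.Series:
        return self.table["class"]

    def counts(self) -> dict[str, int]:
        counts = self.table["class"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in KEGG_COLORS}

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="reaction_id")


@dataclass
class PathwaySummary:
    """Class counts per pathway and per reaction category."""

    per_pathway: pd.DataFrame  # index pathway; n_total, n_up, n_down, ...
    per_category: pd.DataFrame
    cn_ratio: float  # carbon affected proportion / nitrogen affected proportion
    nc_ratio: float
    anabolic_up_pct: float
    anabolic_down_pct: float
    catabolic_up_pct: float
    catabolic_down_pct: float


def transform_flux(fd: FluxDistribution) -> tuple[dict[str, float], dict[str, bool], float]:
    """log2-transform positive fluxes and normalize by the dataset SD.

    Returns (transformed values, nonpositive flags, sd).  For v > 0
    the transformed value is log2(v) / SD(log2 of the positive fluxes
    in this distribution); for v <= 0 the original value is carried
    and flagged.  With fewer than two positive fluxes the SD is
    undefined and 1.0 is used (warned).
    """
    if fd.status is not SolverStatus.OPTIMAL:
        raise ValueError("cannot transform a non-optimal flux distribution")
    positive = {r: v for r, v in fd.fluxes.items() if v > 0}
    flags = {r: v <= 0 for r, v in fd.fluxes.items()}
    if not positive:
        warnings.warn("all fluxes nonpositive; empty transformed set")
        return {r: v for r, v in fd.fluxes.items()}, flags, 1.0
    logs = np.log2(np.array(list(positive.values())))
    sd = float(np.std(logs, ddof=1)) if len(logs) > 1 else 0.0
    if not np.isfinite(sd) or sd <= 0:
        warnings.warn("SD of log2 fluxes undefined or zero; using 1.0")
        sd = 1.0
    out = {}
    for r, v in fd.fluxes.items():
        out[r] = float(np.log2(v) / sd) if v > 0 else v
    return out, flags, sd


def fold_changes(
    fd_a: FluxDistribution, fd_b: FluxDistribution
) -> tuple[pd.DataFrame, float, float]:
    """Per-reaction fold change: transformed_b - transformed_a.

    Reactions nonpositive in either condition get fold_change = NaN
    and are excluded from the numeric comparison.  Returns the
    comparison frame plus both normalization SDs.
    """
    set_a, set_b = set(fd_a.fluxes), set(fd_b.fluxes)
    if set_a != set_b:
        diff = sorted(set_a.symmetric_difference(set_b))
        raise ValueError(f"mismatched reaction sets: {diff[:10]}")
    ta, flags_a, sd_a = transform_flux(fd_a)
    tb, flags_b, sd_b = transform_flux(fd_b)
    rows = []
    for rid in fd_a.fluxes:
        nonpos = flags_a[rid] or flags_b[rid]
        fc = np.nan if nonpos else tb[rid] - ta[rid]
        rows.append(
            (rid, fd_a.fluxes[rid], fd_b.fluxes[rid], ta[rid], tb[rid], fc)
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "reaction_id",
            "flux_a",
            "flux_b",
            "transformed_a",
            "transformed_b",
            "fold_change",
        ],
    ).set_index("reaction_id")
    return df, sd_a, sd_b


def determine_cutoff(
    fcs: pd.Series | dict[str, float] | np.ndarray,
    max_proportion: float = 0.30,
    grid: np.ndarray | None = None,
) -> float:
    """Smallest cut-off leaving fewer than ``max_proportion`` reactions affected.

    ``fcs`` are per-reaction fold changes (NaN = nonpositive, counted
    in the total but never significant).  The candidate grid defaults
    to 0.001 steps over (0, max|fc|] — a zero cut-off would call any
    nonzero change significant, so candidates start at 0.001.
    Returns the smallest candidate c with
    #{|fc| > c} / n_total < max_proportion.
    """
    values = np.asarray(
        list(fcs.values()) if isinstance(fcs, dict) else fcs, dtype=float
    )
    if values.size == 0:
        raise ValueError("no fold changes supplied")
    finite = np.abs(values[np.isfinite(values)])
    n_total = values.size
    if finite.size == 0:
        return 0.001
    if grid is None:
        hi = max(float(finite.max()), 0.001)
        grid = np.arange(0.001, hi + 0.001, 0.001)
    grid = np.asarray(grid, dtype=float)
    # #{|fc| > c} for every candidate at once; exceedance is
    # non-increasing in c, so the first admissible candidate is minimal
    counts = finite.size - np.searchsorted(np.sort(finite), grid, side="right")
    ok = counts / n_total < max_proportion
    idx = int(np.argmax(ok))
    if not ok[idx]:
        return float(grid[-1])
    return float(grid[idx])


def classify(
    df: pd.DataFrame,
    cutoff: float,
    condition_pair: tuple[str, str] = ("a", "b"),
    sd_a: float = float("nan"),
    sd_b: float = float("nan"),
) -> FluxComparison:
    """Assign up / down / unchanged / nonpositive classes at a cut-off."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    fc = df["fold_change"]
    cls = pd.Series("unchanged", index=df.index, dtype=object)
    cls[fc > cutoff] = "up"
    cls[fc < -cutoff] = "down"
    cls[fc.isna()] = "nonpositive"
    out = df.copy()
    out["class"] = cls
    return FluxComparison(condition_pair, out, cutoff, sd_a, sd_b)


def compare(
    fd_a: FluxDistribution,
    fd_b: FluxDistribution,
    condition_pair: tuple[str, str] = ("a", "b"),
    max_proportion: float = 0.30,
    cutoff: float | None = None,
) -> FluxComparison:
    """Full comparison: transform, fold changes, cut-off, classes."""
    df, sd_a, sd_b = fold_changes(fd_a, fd_b)
    if cutoff is None:
        cutoff = determine_cutoff(df["fold_change"], max_proportion=max_proportion)
    return classify(df, cutoff, condition_pair, sd_a, sd_b)


def correlation(
    fd_a: FluxDistribution,
    fd_b: FluxDistribution,
    method: Literal["pearson", "spearman"] = "pearson",
) -> float:
    """Correlation of the two flux vectors over shared reactions.

    Returns NaN (with a warning) when either vector is constant.
    """
    shared = sorted(set(fd_a.fluxes) & set(fd_b.fluxes))
    if len(shared) < 3:
        raise ValueError("need >= 3 shared reactions for a correlation")
    xa = np.array([fd_a.fluxes[r] for r in shared])
    xb = np.array([fd_b.fluxes[r] for r in shared])
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        warnings.warn("constant flux vector: correlation undefined")
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(xa, xb).statistic)
    return float(stats.spearmanr(xa, xb).statistic)


def _summarize(groups: dict[str, pd.Series]) -> pd.DataFrame:
    rows = []
    for name, cls in groups.items():
        counts = cls.value_counts()
        n_up = int(counts.get("up", 0))
        n_down = int(counts.get("down", 0))
        n_unch = int(counts.get("unchanged", 0))
        n_nonpos = int(counts.get("nonpositive", 0))
        n_total = int(len(cls))
        affected = n_up + n_down
        rows.append(
            {
                "group": name,
                "n_total": n_total,
                "n_up": n_up,
                "n_down": n_down,
                "n_unchanged": n_unch,
                "n_nonpositive": n_nonpos,
                "pct_up": 100.0 * n_up / n_total if n_total else 0.0,
                "pct_down": 100.0 * n_down / n_total if n_total else 0.0,
                "pct_affected": 100.0 * affected / n_total if n_total else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def pathway_summary(cmp: FluxComparison, model: MetabolicModel) -> PathwaySummary:
    """Aggregate classes per pathway (subsystem) and per category tag.

    The C/N ratio divides the affected-reaction proportion among
    carbon-tagged reactions by that among nitrogen-tagged reactions
    (NaN when either side has no reactions or nitrogen is unaffected);
    the inverse ratio is reported alongside.
    """
    cls = cmp.classes()
    sub_of = {r.id: r.subsystem or "unassigned" for r in model.reactions}
    cat_of = {r.id: r.categories for r in model.reactions}

    pathways: dict[str, pd.Series] = {}
    for name in sorted({sub_of.get(rid, "unassigned") for rid in cls.index}):
        members = [rid for rid in cls.index if sub_of.get(rid, "unassigned") == name]
        pathways[name] = cls.loc[members]
    per_pathway = _summarize(pathways)

    categories: dict[str, pd.Series] = {}
    for tag in ("carbon", "nitrogen", "anabolic", "catabolic", "exchange"):
        members = [rid for rid in cls.index if tag in cat_of.get(rid, frozenset())]
        if members:
            categories[tag] = cls.loc[members]
    per_category = _summarize(categories)

    def affected_prop(tag: str) -> float:
        if tag not in per_category.index:
            return float("nan")
        return float(per_category.loc[tag, "pct_affected"]) / 100.0

    pc, pn = affected_prop("carbon"), affected_prop("nitrogen")
    cn = pc / pn if pn and np.isfinite(pn) and pn > 0 and np.isfinite(pc) else float("nan")
    nc = pn / pc if pc and np.isfinite(pc) and pc > 0 and np.isfinite(pn) else float("nan")

    def pct(tag: str, col: str) -> float:
        if tag not in per_category.index:
            return float("nan")
        return float(per_category.loc[tag, col])

    return PathwaySummary(
        per_pathway=per_pathway,
        per_category=per_category,
        cn_ratio=cn,
        nc_ratio=nc,
        anabolic_up_pct=pct("anabolic", "pct_up"),
        anabolic_down_pct=pct("anabolic", "pct_down"),
        catabolic_up_pct=pct("catabolic", "pct_up"),
        catabolic_down_pct=pct("catabolic", "pct_down"),
    )


def kegg_export(
    cmp: FluxComparison, annotation: dict[str, str], path: str | Path
) -> int:
    """Write a KEGG Mapper 'Color' input file (KEGG id, color per line).

    ``annotation`` maps model reaction ids to KEGG reaction/KO ids.
    Unannotated reactions are omitted (their count is logged).
    Returns the number of lines written.
    """
    written = 0
    skipped = 0
    with open(Path(path), "w") as fh:
        for rid, cls in cmp.classes().items():
            kegg_id = annotation.get(rid)
            if kegg_id is None:
                skipped += 1
                continue
            fh.write(f"{kegg_id} {KEGG_COLORS[cls]}\n")
            written += 1
    if skipped:
        logger.warning("%d reactions had no KEGG annotation, omitted", skipped)
    if written == 0:
        warnings.warn("empty KEGG export: no annotated reactions")
    return written
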