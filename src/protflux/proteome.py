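"""Quantitative proteome handling: normalization, fold changes, DE calls.

A :class:`ProteomeTable` holds replicate intensities per protein and
condition (long-form: protein_id, condition, replicate, intensity).
Differential expression follows the classic thresholding scheme used
for intensity proteomics: per-protein Welch two-sample t-test between
a condition and the control, combined with an absolute log2
fold-change cutoff.  Proteins passing both are flagged DE, and their
normalized condition means become the expression levels that bound
reaction fluxes downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: gene/protein id -> non-negative expression level used as a bound magnitude
ExpressionMap = dict[str, float]

NormalizationMethod = Literal["total_intensity", "median", "none"]


@dataclass
class DEResult:
    protein: str
    log2_fold_change: float
    p_value: float
    is_de: bool
    q_value: float | None = None


class ProteomeTable:
    """Replicate intensities per protein and condition.

    Wraps a long-form DataFrame with columns
    ``protein_id, condition, replicate, intensity``.
    """

    COLUMNS = ["protein_id", "condition", "replicate", "intensity"]

    def __init__(self, data: pd.DataFrame):
        missing = set(self.COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"proteome table missing columns {sorted(missing)}")
        df = data[self.COLUMNS].copy()
        df["intensity"] = df["intensity"].astype(float)
        if (df["intensity"] <= 0).any():
            bad = df.loc[df["intensity"] <= 0, "protein_id"].unique()[:5]
            raise ValueError(
                f"intensities must be positive (offending proteins: {list(bad)})"
            )
        self.data = df

    @property
    def proteins(self) -> list[str]:
        return sorted(self.data["protein_id"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    def replicate_matrix(self, condition: str) -> pd.DataFrame:
        """proteins x replicates intensity matrix for one condition."""
        sub = self.data[self.data["condition"] == condition]
        return sub.pivot_table(
            index="protein_id", columns="replicate", values="intensity"
        )

    def condition_means(self, condition: str) -> pd.Series:
        sub = self.data[self.data["condition"] == condition]
        return sub.groupby("protein_id")["intensity"].mean()

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProteomeTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "ProteomeTable":
        """Wide form: index=protein_id, columns '<condition>_r<k>'."""
        records = []
        for protein, row in df.iterrows():
            for col, val in row.items():
                condition, rep = str(col).rsplit("_r", maxsplit=1)
                records.append((protein, condition, int(rep), float(val)))
        return cls(pd.DataFrame(records, columns=cls.COLUMNS))


def normalize_proteome(
    raw: ProteomeTable, method: NormalizationMethod = "total_intensity"
) -> ProteomeTable:
    """Rescale replicate columns so a summary statistic is equal across them.

    ``total_intensity`` equalizes each replicate's total to the mean
    total within its condition; ``median`` does the same for the
    replicate median; ``none`` is the identity.
    """
    if method == "none":
        return ProteomeTable(raw.data)
    df = raw.data.copy()
    stat = {"total_intensity": "sum", "median": "median"}[method]
    per_rep = df.groupby(["condition", "replicate"])["intensity"].agg(stat)
    target = per_rep.groupby("condition").mean()
    factor = (target / per_rep).rename("factor").reset_index()
    df = df.merge(factor, on=["condition", "replicate"], how="left")
    df["intensity"] = df["intensity"] * df["factor"]
    return ProteomeTable(df.drop(columns="factor"))


def compute_log2fc(
    table: ProteomeTable, condition: str, control: str
) -> dict[str, float]:
    """Per-protein log2 of the ratio of condition means over control means.

    Proteins absent from either condition are excluded (logged).
    """
    mc = table.condition_means(condition)
    mk = table.condition_means(control)
    shared = mc.index.intersection(mk.index)
    dropped = set(mc.index).symmetric_difference(mk.index)
    if dropped:
        logger.warning(
            "%d proteins missing in one condition, excluded from log2FC",
            len(dropped),
        )
    return {p: float(np.log2(mc[p] / mk[p])) for p in shared}


def select_de(
    table: ProteomeTable,
    condition: str,
    control: str,
    fc_threshold: float = 1.2,
    alpha: float = 0.05,
    adjust: Literal["none", "bh"] = "none",
) -> list[DEResult]:
    """Call differentially expressed proteins between two conditions.

    A protein is DE when |log2 fold change| > ``fc_threshold`` (log2
    scale) and its Welch two-sample t-test p-value < ``alpha``.  All
    testable proteins are returned with flags; proteins with fewer
    than two replicates in either group are excluded with a warning.
    ``adjust='bh'`` applies Benjamini-Hochberg and tests the q-value
    against ``alpha`` instead (off by default).
    """
    mat_c = table.replicate_matrix(condition)
    mat_k = table.replicate_matrix(control)
    fcs = compute_log2fc(table, condition, control)

    rows = []
    for protein in sorted(fcs):
        xc = mat_c.loc[protein].dropna().to_numpy() if protein in mat_c.index else np.array([])
        xk = mat_k.loc[protein].dropna().to_numpy() if protein in mat_k.index else np.array([])
        if len(xc) < 2 or len(xk) < 2:
            warnings.warn(
                f"protein {protein}: <2 replicates in a group, excluded from t-test"
            )
            continue
        t_res = stats.ttest_ind(xc, xk, equal_var=False)
        rows.append((protein, fcs[protein], float(t_res.pvalue)))

    pvals = np.array([p for _, _, p in rows])
    if adjust == "bh" and len(pvals):
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        qvals_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        qvals = np.empty_like(pvals)
        qvals[order] = np.clip(qvals_sorted, 0, 1)
    else:
        qvals = [None] * len(rows)

    results = []
    for (protein, fc, p), q in zip(rows, qvals):
        p_eff = q if q is not None else p
        results.append(
            DEResult(
                protein=protein,
                log2_fold_change=fc,
                p_value=p,
                q_value=q,
                is_de=bool(abs(fc) > fc_threshold and p_eff < alpha),
            )
        )
    return results


def to_expression_map(
    table: ProteomeTable,
    condition: str,
    de_only: bool = False,
    de: list[DEResult] | None = None,
) -> ExpressionMap:
    """Condition means as bound magnitudes, optionally restricted to DE hits."""
    means = table.condition_means(condition)
    if de_only:
        if de is None:
            raise ValueError("de_only=True requires a DE result list")
        keep = {r.protein for r in de if r.is_de}
        means = means[means.index.isin(keep)]
    out = {p: float(v) for p, v in means.items()}
    if not out:
        warnings.warn(
            "empty expression map: the model will be largely unconstrained"
        )
    return out
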