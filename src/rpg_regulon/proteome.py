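"""TOP3 label-free protein quantification and ribosome-content summaries.

Protein abundance per replicate is the mean of its three most intense
peptide areas (TOP3; fewer peptides fall back to the mean of what is
available, flagged).  Replicates are brought to a common scale with the
correction factor sum(TOP3, replicate) / mean over replicates of that sum,
dividing each replicate by its factor so all post-normalization replicate
sums equal the pre-normalization mean sum.  Downstream summaries: per-protein
differential abundance between conditions (t-test or Mann-Whitney behind a
Shapiro-Wilk normality gate), the ribosomal-protein (RP) mass fraction of
the analyzed fraction, per-RP stoichiometry (share of total RP intensity)
and protein/mRNA log-ratios with Spearman correlations across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as rstats

__all__ = [
    "top3_quantify",
    "normalize_replicates",
    "differential_abundance",
    "rp_mass_fraction",
    "stoichiometry",
    "protein_mrna_ratio",
]

MIN_REPLICATES = 3
PEPTIDE_COLUMNS = ["protein_id", "peptide_id", "condition", "replicate", "area"]


@dataclass
class ProteinQuant:
    """TOP3 values per (condition, replicate) with detection flags."""

    top3: pd.DataFrame          # index protein_id, columns (condition, replicate)
    n_peptides: pd.DataFrame    # peptides used per cell, same shape
    detected: pd.Series         # quantified in >= min_replicates of a condition
    low_peptide: pd.Series      # True if any cell used < 3 peptides
    min_replicates: int


def top3_quantify(table: pd.DataFrame,
                  min_replicates: int = MIN_REPLICATES) -> ProteinQuant:
    """TOP3 per (protein, condition, replicate) from a peptide area table.

    ``table`` needs columns protein_id, peptide_id, condition, replicate,
    area.  Proteins quantified in fewer than ``min_replicates`` replicates of
    every condition are retained with ``detected=False`` and are excluded
    from downstream statistics by the callers.
    """
    missing = [c for c in PEPTIDE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peptide table lacks columns {missing}")
    if table.empty:
        raise ValueError("empty peptide table")
    if (table["area"] < 0).any():
        raise ValueError("negative peptide area")
    dup = table.duplicated(subset=["protein_id", "peptide_id",
                                   "condition", "replicate"])
    if dup.any():
        raise ValueError("duplicate (protein, peptide, condition, replicate) rows")

    def _top3(areas: pd.Series) -> float:
        top = np.sort(areas.values)[::-1][:3]
        return float(top.mean())

    grouped = table.groupby(["protein_id", "condition", "replicate"])["area"]
    top3 = grouped.apply(_top3).unstack(["condition", "replicate"])
    n_pep = grouped.count().unstack(["condition", "replicate"])
    top3 = top3.sort_index(axis=1)
    n_pep = n_pep.reindex(columns=top3.columns)

    conditions = top3.columns.get_level_values(0).unique()
    reps_per_cond = pd.DataFrame({
        cond: top3[cond].notna().sum(axis=1) for cond in conditions
    })
    detected = (reps_per_cond >= min_replicates).any(axis=1)
    detected.name = "detected"
    low = (n_pep < 3).any(axis=1)
    low.name = "low_peptide"
    return ProteinQuant(top3, n_pep, detected, low, min_replicates)


def normalize_replicates(top3: pd.DataFrame, per_condition: bool = True
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Equalize replicate TOP3 sums with the sum/mean-of-sums correction.

    factor_r = sum_p TOP3(p, r) / mean_r' sum_p TOP3(p, r'); each replicate
    column is divided by its factor, making every post-normalization column
    sum equal to the pre-normalization mean sum (missing values skipped).

    With ``per_condition`` (default) and (condition, replicate) columns, the
    factor is computed within each condition: the correction removes
    technical loading differences among replicates but must not cancel a
    genuine global abundance shift between conditions (equalizing sums
    across conditions would absorb most of a ribosome-content change, the
    proteomic analog of total-count RNA-seq normalization hiding a global
    transcriptional shift).
    """
    sums = top3.sum(axis=0, skipna=True)
    if (sums <= 0).any():
        zero = list(sums.index[sums <= 0])
        raise ValueError(f"replicate(s) with non-positive total TOP3: {zero}")
    if per_condition and isinstance(top3.columns, pd.MultiIndex):
        factors = sums / sums.groupby(level=0).transform("mean")
    else:
        factors = sums / sums.mean()
    factors.name = "correction_factor"
    return top3 / factors, factors


def differential_abundance(normalized: pd.DataFrame, detected: pd.Series,
                           control: str, treatment: str,
                           min_replicates: int = MIN_REPLICATES,
                           alpha_normality: float = 0.05) -> pd.DataFrame:
    """Per-protein log2FC (treatment vs control) and p-values.

    Proteins with >= min_replicates quantified replicates in both conditions
    are tested on log2 values: Student's t if both groups pass the
    Shapiro-Wilk gate, Mann-Whitney otherwise.  Proteins quantified in only
    one condition are labeled condition-unique (log2FC and p are NA); all
    others are untested.
    """
    rows = []
    for pid in normalized.index:
        if not detected.get(pid, False):
            rows.append((pid, np.nan, np.nan, "not_detected", np.nan))
            continue
        a = normalized.loc[pid, control].dropna()
        b = normalized.loc[pid, treatment].dropna()
        if len(a) >= min_replicates and len(b) == 0:
            rows.append((pid, np.nan, np.nan, f"unique_{control}", np.nan))
            continue
        if len(b) >= min_replicates and len(a) == 0:
            rows.append((pid, np.nan, np.nan, f"unique_{treatment}", np.nan))
            continue
        if len(a) < min_replicates or len(b) < min_replicates:
            rows.append((pid, np.nan, np.nan, "untested", np.nan))
            continue
        la, lb = np.log2(a.values), np.log2(b.values)
        lfc = float(lb.mean() - la.mean())
        if np.ptp(la) == 0 and np.ptp(lb) == 0 and lfc == 0:
            p, test = 1.0, "degenerate"
        elif rstats.normality_gate([la, lb], alpha_normality) == "parametric":
            from scipy import stats as sps
            p = float(sps.ttest_ind(lb, la, equal_var=False).pvalue)
            test = "t"
        else:
            p = rstats.mann_whitney_u(lb, la).p_value
            test = "mann-whitney"
        rows.append((pid, lfc, p, test, np.nan))
    out = pd.DataFrame(rows, columns=["protein_id", "log2fc", "p_value",
                                      "test", "q_value"]).set_index("protein_id")
    tested = out["p_value"].notna()
    if tested.any():
        q = rstats.bh_adjust(out.loc[tested, "p_value"].values)
        out.loc[tested, "q_value"] = q
    if not tested.any() and not out.index.str.len().any():
        raise ValueError("no testable proteins")
    return out


def rp_mass_fraction(top3: pd.DataFrame, rp_proteins) -> pd.Series:
    """Per-replicate RP mass fraction: sum of RP TOP3 / sum of all TOP3."""
    if top3.empty:
        raise ValueError("empty quantification")
    totals = top3.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        raise ValueError("replicate with zero total intensity")
    rp = top3.loc[top3.index.isin(set(rp_proteins))]
    frac = rp.sum(axis=0, skipna=True) / totals
    frac.name = "rp_mass_fraction"
    return frac


def stoichiometry(top3: pd.DataFrame, rp_proteins,
                  per_replicate: bool = False) -> pd.DataFrame:
    """Per-RP share of total RP intensity.

    Default: condition means of the replicate TOP3 values, one share vector
    per condition (columns sum to 1).  ``per_replicate`` keeps replicate
    resolution instead.
    """
    rp = top3.loc[top3.index.isin(set(rp_proteins))]
    if rp.empty:
        raise ValueError("no RP with quantified intensity")
    if per_replicate:
        intensity = rp
    else:
        intensity = rp.T.groupby(level=0).mean().T
    totals = intensity.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        raise ValueError("zero total RP intensity")
    shares = intensity / totals
    return shares


def protein_mrna_ratio(log2_protein: pd.Series, log2_mrna: pd.Series
                       ) -> pd.Series:
    """Per-gene log2(protein) - log2(mRNA); inputs are already log2 scale."""
    shared = log2_protein.index.intersection(log2_mrna.index)
    if shared.empty:
        raise ValueError("no genes shared between protein and mRNA inputs")
    ratio = log2_protein[shared] - log2_mrna[shared]
    ratio.name = "protein_mrna_log2_ratio"
    return ratio


def ratio_correlation(ratio_a: pd.Series, ratio_b: pd.Series,
                      subsets: dict | None = None) -> pd.DataFrame:
    """Spearman rho between two conditions' protein/mRNA ratio vectors,
    overall and per gene subset."""
    shared = ratio_a.index.intersection(ratio_b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes")
    groups = {"all": list(shared)}
    if subsets:
        for name, genes in subsets.items():
            groups[name] = [g for g in genes if g in shared]
    rows = []
    for name, genes in groups.items():
        if len(genes) < 3:
            rows.append((name, np.nan, np.nan, len(genes)))
            continue
        rho, rep = rstats.spearman_rho(ratio_a[genes].values,
                                       ratio_b[genes].values)
        rows.append((name, rho, rep.p_value, len(genes)))
    return pd.DataFrame(rows, columns=["subset", "rho", "p_value", "n"]
                        ).set_index("subset")
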