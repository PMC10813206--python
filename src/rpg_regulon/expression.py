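"""Spike-in normalized differential expression for knockdown RNA-seq.

The experimental design mixes a fixed amount of exogenous (Drosophila)
spike-in material with equal cell numbers per condition, so sample scaling
factors estimated from the spike-in genes alone remain valid when the
endogenous transcriptome shifts globally - exactly the situation after the
knockdown, where ribosomal-protein transcripts drop across the board and
total-count normalization would absorb the signal.

Size factors are median-of-ratios restricted to spike genes (geometric-mean
rescaled); genes with more than ``min_avg`` average normalized CPM are kept;
a minimal per-gene negative-binomial Wald test (method-of-moments dispersion
with empirical-Bayes moderation toward the dataset median, no shrinkage of
fold changes) provides log2FC and p-values, thresholded at |log2FC| > 0.7
and p <= 0.05 for up/down calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as rstats

__all__ = [
    "CountMatrix",
    "DEResult",
    "spikein_size_factors",
    "totalcount_size_factors",
    "normalize_filter",
    "nb_wald_test",
    "call_de",
    "top_percentile_flag",
    "stratify_by_occupancy",
]

LFC_THRESHOLD = 0.7
P_THRESHOLD = 0.05
MIN_AVG_CPM = 10.0
DISPERSION_FLOOR = 1e-4
#: prior weight (degrees of freedom) for moderating per-gene dispersions
DISPERSION_PRIOR_DF = 4.0
SPIKE_PREFIX = "SPIKE_"


@dataclass
class CountMatrix:
    """Genes x samples integer counts with spike flags and condition labels."""

    counts: pd.DataFrame               # index = gene_id, columns = samples
    is_spike: pd.Series                # bool per gene
    condition: pd.Series               # label per sample

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.is_spike.index.equals(self.counts.index):
            raise ValueError("spike flags must align with genes")
        if not self.condition.index.equals(self.counts.columns):
            raise ValueError("condition labels must align with samples")

    @classmethod
    def from_tsv(cls, path, condition: dict, spike_prefix: str = SPIKE_PREFIX,
                 spike_genes=None) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        if spike_genes is not None:
            is_spike = counts.index.to_series().isin(set(spike_genes))
        else:
            is_spike = counts.index.to_series().str.startswith(spike_prefix)
        return cls(counts, is_spike, pd.Series(condition)[counts.columns])


@dataclass
class DEResult:
    table: pd.DataFrame   # gene_id index; base_mean, log2fc, se, p_value, q_value, status


def _geometric_mean_rows(values: np.ndarray) -> np.ndarray:
    return np.exp(np.mean(np.log(values), axis=1))


def spikein_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors computed on spike genes only.

    Spike genes with a zero count in any sample are dropped (their geometric
    mean is undefined); per-sample factors are the median ratio to the
    per-gene geometric mean, rescaled to geometric mean 1.
    """
    spike = cm.counts.loc[cm.is_spike]
    spike = spike[(spike > 0).all(axis=1)]
    if spike.empty:
        raise ValueError("no spike gene with nonzero counts in every sample")
    v = spike.values.astype(float)
    gm = _geometric_mean_rows(v)
    ratios = v / gm[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def totalcount_size_factors(cm: CountMatrix) -> pd.Series:
    """Library-size factors (total counts / geometric mean) for comparison."""
    totals = cm.counts.sum(axis=0).astype(float)
    factors = totals / np.exp(np.mean(np.log(totals)))
    factors.name = "size_factor"
    return factors


def normalize_filter(cm: CountMatrix, factors: pd.Series,
                     min_avg: float = MIN_AVG_CPM
                     ) -> tuple[pd.DataFrame, pd.Series]:
    """Divide counts by size factors; keep genes with mean CPM > min_avg.

    CPM uses the normalized library sizes.  The filter is strict: a gene at
    exactly ``min_avg`` is dropped.
    """
    if (factors <= 0).any() or not np.isfinite(factors).all():
        raise ValueError("size factors must be positive and finite")
    normalized = cm.counts / factors
    lib = normalized.sum(axis=0)
    cpm = normalized * 1e6 / lib
    kept = cpm.mean(axis=1) > min_avg
    kept.name = "kept"
    return normalized, kept


def _moments_by_condition(values: np.ndarray, groups: list[np.ndarray]):
    means = np.stack([values[:, g].mean(axis=1) for g in groups])
    variances = np.stack([values[:, g].var(axis=1, ddof=1) for g in groups])
    return means, variances


def nb_wald_test(normalized: pd.DataFrame, condition: pd.Series,
                 control: str | None = None) -> pd.DataFrame:
    """Minimal per-gene negative-binomial Wald test (condition vs control).

    Per-gene dispersion is estimated by method of moments, pooled over the
    two conditions, moderated toward the dataset median dispersion
    (empirical-Bayes weighting of the residual df against a prior weight)
    and floored; log2FC is the log-ratio of +0.5-shifted condition means;
    the Wald statistic uses the delta-method SE on the NB mean model and a
    Student-t reference with residual + prior degrees of freedom (the
    moderated-t result for hierarchical variance models).  Genes that are
    all-zero in both conditions get NA results.
    """
    levels = list(pd.unique(condition))
    if len(levels) != 2:
        raise ValueError("exactly two conditions are required")
    if control is None:
        control = levels[0]
    treat = [lv for lv in levels if lv != control][0]
    g_ctrl = np.flatnonzero((condition == control).values)
    g_trt = np.flatnonzero((condition == treat).values)
    if len(g_ctrl) < 2 or len(g_trt) < 2:
        raise ValueError("need >= 2 replicates per condition")

    v = normalized.values.astype(float)
    (m_c, m_t), (s2_c, s2_t) = _moments_by_condition(v, [g_ctrl, g_trt])

    # pooled method-of-moments dispersion: alpha = (var - mean) / mean^2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_c = (s2_c - m_c) / m_c**2
        alpha_t = (s2_t - m_t) / m_t**2
    alpha = np.nanmean(np.stack([alpha_c, alpha_t]), axis=0)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    positive = alpha[alpha > 0]
    prior = float(np.median(positive)) if positive.size else DISPERSION_FLOOR
    df = (len(g_ctrl) - 1) + (len(g_trt) - 1)
    alpha = (df * alpha + DISPERSION_PRIOR_DF * prior) / (df + DISPERSION_PRIOR_DF)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    log2fc = np.log2(m_t + 0.5) - np.log2(m_c + 0.5)
    ln2sq = np.log(2.0) ** 2
    var_log2 = ((m_c + alpha * m_c**2) / (len(g_ctrl) * (m_c + 0.5) ** 2)
                + (m_t + alpha * m_t**2) / (len(g_trt) * (m_t + 0.5) ** 2)) / ln2sq
    se = np.sqrt(var_log2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * sps.t.sf(np.abs(z), df=df + DISPERSION_PRIOR_DF)

    all_zero = (m_c == 0) & (m_t == 0)
    result = pd.DataFrame({
        "base_mean": v.mean(axis=1),
        "log2fc": np.where(all_zero, np.nan, log2fc),
        "se": np.where(all_zero, np.nan, se),
        "p_value": np.where(all_zero, np.nan, p),
    }, index=normalized.index)
    mask = result["p_value"].notna()
    q = np.full(len(result), np.nan)
    q[mask.values] = rstats.bh_adjust(result.loc[mask, "p_value"].values)
    result["q_value"] = q
    return result


def call_de(results: pd.DataFrame, lfc_threshold: float = LFC_THRESHOLD,
            p_threshold: float = P_THRESHOLD,
            use_adjusted: bool = False) -> pd.Series:
    """Status per gene: up / down / unchanged / filtered.

    up: log2FC > threshold (strict) and p <= alpha; down symmetric; genes
    with NA results are 'filtered'.  ``use_adjusted`` switches p to the BH
    q-value.
    """
    p = results["q_value"] if use_adjusted else results["p_value"]
    lfc = results["log2fc"]
    status = pd.Series("unchanged", index=results.index, name="status")
    status[(lfc > lfc_threshold) & (p <= p_threshold)] = "up"
    status[(lfc < -lfc_threshold) & (p <= p_threshold)] = "down"
    status[lfc.isna() | p.isna()] = "filtered"
    return status


def top_percentile_flag(expression: pd.Series, q: float = 5.0) -> pd.Series:
    """Flag the top-q% most strongly expressed genes (ties all included)."""
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    if expression.empty:
        raise ValueError("empty expression vector")
    cutoff = np.percentile(expression.values, 100 - q)
    flags = expression >= cutoff
    flags.name = f"top_{q:g}pct"
    return flags


@dataclass
class StratifiedComparison:
    group_medians: dict
    report: rstats.TestReport
    n_per_group: dict


def stratify_by_occupancy(values, calls, paired_values=None) -> StratifiedComparison:
    """Compare a per-gene metric between occupancy-positive and negative genes.

    Unpaired mode (default): Mann-Whitney between bound and unbound genes on
    ``values``.  Paired mode (``paired_values`` given, same genes in two
    conditions): Wilcoxon matched-pairs signed-rank within the bound group on
    (values, paired_values); run it twice (bound and unbound subsets) to
    mirror a per-group knockdown comparison.
    """
    values = pd.Series(values)
    bound_ids = {c.gene_id for c in calls if c.bound}
    unbound_ids = {c.gene_id for c in calls if not c.bound}
    missing = set(values.index) - bound_ids - unbound_ids
    if missing:
        raise ValueError(f"{len(missing)} genes lack an occupancy call")
    in_bound = values.index.isin(bound_ids)
    x = values[in_bound]
    y = values[~in_bound]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each occupancy group needs >= 2 genes")
    if paired_values is None:
        report = rstats.mann_whitney_u(x.values, y.values)
        medians = {"bound": float(x.median()), "unbound": float(y.median())}
        n = {"bound": len(x), "unbound": len(y)}
    else:
        paired = pd.Series(paired_values)[values.index]
        report = rstats.wilcoxon_signed_rank(values.values, paired.values)
        medians = {"first": float(values.median()),
                   "second": float(paired.median())}
        n = {"pairs": len(values)}
    return StratifiedComparison(medians, report, n)
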