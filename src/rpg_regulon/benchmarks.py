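"""End-to-end benchmark measurements on synthetic data with known truth.

Each function regenerates its inputs from a seed, runs the relevant part of
the pipeline and returns the measured quantities (oracle errors, recovery
rates, calibration rates).  They back both the acceptance test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import chip, expression, motif, polysome, proteome, simulate
from . import stats as rstats


def _derive_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2**31 - 1))


# ---------------------------------------------------------------- motif ---

def _enumerate_all_sequences(L: int) -> np.ndarray:
    idx = np.arange(4**L, dtype=np.int64)
    cols = [(idx // 4**k) % 4 for k in range(L - 1, -1, -1)]
    return np.stack(cols, axis=1).astype(np.int8)


def pwm_pvalue_oracle(consensus: str = motif.DYRK1A_CONSENSUS) -> dict:
    """Max relative error of the DP p-value table vs full enumeration.

    Enumerates every sequence of the PWM's length (4^L of them), computes
    exact tail probabilities by sorting, and compares the DP table at every
    distinct achievable score.  Returns errors for the length-8 prefix and
    for the full-length matrix.
    """
    out = {}
    for key, cons in [("rel_err_L8", consensus[:8]), ("rel_err_L10", consensus)]:
        pwm = motif.build_pwm(consensus=cons)
        table = motif.ScorePValueTable(pwm)
        L = pwm.length
        seqs = _enumerate_all_sequences(L)
        ints = table.int_scores[np.arange(L)[None, :],
                                seqs.astype(np.int64)].sum(axis=1)
        probs = pwm.background[seqs.astype(np.int64)].prod(axis=1)
        order = np.argsort(ints)[::-1]
        sorted_ints = ints[order]
        tails = np.cumsum(probs[order])
        # last index of each run of equal scores = full tail at that score
        boundary = np.flatnonzero(np.diff(sorted_ints) != 0)
        idx = np.concatenate([boundary, [len(sorted_ints) - 1]])
        rel = np.array([
            abs(table.pvalue(int(sorted_ints[i])) - tails[i]) / tails[i]
            for i in idx
        ])
        out[key] = float(rel.max())
    return out


def motif_tier_assignments() -> dict:
    return {p: motif.classify_promoter_motif(p)
            for p in (5e-5, 2e-4, 3.5e-4)}


def central_enrichment_calibration(seed: int, n_null_seeds: int = 100) -> dict:
    """Centered planting significance and null (uniform) super-uniformity."""
    pwm = motif.build_pwm(consensus=motif.DYRK1A_CONSENSUS)
    table = motif.ScorePValueTable(pwm)
    recs, _ = simulate.gen_promoter_set(n=100, motif_fraction=1.0,
                                        central_sd=0.0,
                                        seed=_derive_seed(seed, 1))
    centred = motif.central_enrichment(recs, pwm, table=table)
    n_calm = 0
    L = len(motif.DYRK1A_CONSENSUS)
    for s in range(n_null_seeds):
        rng = np.random.default_rng(_derive_seed(seed, 100 + s))
        base, _ = simulate.gen_promoter_set(n=100, motif_fraction=0.0,
                                            seed=_derive_seed(seed, 10_000 + s))
        recs = []
        for gid, seq in base:
            off = int(rng.integers(0, len(seq) - L + 1))
            recs.append((gid, seq[:off] + motif.DYRK1A_CONSENSUS
                         + seq[off + L:]))
        res = motif.central_enrichment(recs, pwm, table=table)
        n_calm += res.p_central > 0.1
    return {"centered_log10_p": float(np.log10(centred.p_central)),
            "uniform_frac_p_gt_0.1": n_calm / n_null_seeds,
            "n_null_seeds": n_null_seeds}


# ----------------------------------------------------------------- chip ---

def occupancy_recovery(seed: int, depth: int = 100_000,
                       enrichment: float = 8.0, theta: float = 5.0) -> dict:
    """Sensitivity and FDR of promoter occupancy calls on synthetic ChIP."""
    catalog = simulate.rpg_catalog()
    anchors = [r.anchor for r in catalog]
    rng = np.random.default_rng(_derive_seed(seed, 2))
    bound = set(rng.choice([a.gene_id for a in anchors], size=23,
                           replace=False).tolist())
    reads, _ = simulate.gen_chip_experiment(anchors, bound, depth=depth,
                                            enrichment=enrichment,
                                            seed=_derive_seed(seed, 3))
    track = chip.coverage_rpm(reads, 50, simulate.toy_chrom_sizes())
    sig = chip.poisson_track(track)
    calls = [chip.call_occupancy(sig, a, 500, theta) for a in anchors]
    tp = sum(c.bound and c.gene_id in bound for c in calls)
    fp = sum(c.bound and c.gene_id not in bound for c in calls)
    fn = sum(not c.bound and c.gene_id in bound for c in calls)
    return {"sensitivity": tp / (tp + fn),
            "fdr": fp / max(tp + fp, 1),
            "n_promoters": len(anchors)}


# ----------------------------------------------------------- expression ---

def spikein_benchmark(seed: int) -> dict:
    """Size-factor error of spike-in vs total-count normalization under a
    planted -50% global shift of every endogenous gene."""
    genes = [r.symbol for r in simulate.rpg_catalog()]
    target = [f"GENE_{i:04d}" for i in range(2000 - len(genes))] + genes
    cm, truth = simulate.gen_count_matrix(rpg_genes=target, n_genes=2000,
                                          global_shift_log2=-1.0,
                                          seed=_derive_seed(seed, 4))
    spike_f = expression.spikein_size_factors(cm)
    total_f = expression.totalcount_size_factors(cm)
    true_f = pd.Series(truth["true_size_factors"])[cm.counts.columns]
    return {
        "spike_factor_max_rel_err": float(
            (spike_f / true_f - 1.0).abs().max()),
        "total_factor_max_rel_err": float(
            (total_f / true_f - 1.0).abs().max()),
    }


def de_benchmark(seed: int, n_sims: int = 10) -> dict:
    """Recall/FDR for a planted RPG knockdown and the null positive rate.

    Each replicate simulation plants log2FC = -1 on the 90 RPGs among 2,000
    genes (n = 3 vs 3, dispersion 0.05); results are pooled over
    ``n_sims`` replicate simulations.
    """
    genes = [r.symbol for r in simulate.rpg_catalog()]
    tp = fp = fn = 0
    null_p = []
    med_lfc = []
    for i in range(n_sims):
        cm, _ = simulate.gen_count_matrix(rpg_genes=genes,
                                          global_shift_log2=-1.0,
                                          seed=_derive_seed(seed, 20 + i))
        factors = expression.spikein_size_factors(cm)
        norm, kept = expression.normalize_filter(cm, factors)
        res = expression.nb_wald_test(norm.loc[~cm.is_spike & kept],
                                      cm.condition)
        status = expression.call_de(res)
        planted = res.index.isin(genes)
        down = status == "down"
        tp += int((down & planted).sum())
        fp += int((down & ~planted).sum())
        fn += int((~down & planted).sum())
        med_lfc.append(res.loc[planted, "log2fc"].median())

        cm, _ = simulate.gen_count_matrix(rpg_genes=genes,
                                          global_shift_log2=0.0,
                                          seed=_derive_seed(seed, 50 + i))
        factors = expression.spikein_size_factors(cm)
        norm, kept = expression.normalize_filter(cm, factors)
        res = expression.nb_wald_test(norm.loc[~cm.is_spike & kept],
                                      cm.condition)
        null_p.append(res["p_value"].dropna().values)
    null_p = np.concatenate(null_p)
    return {"recall": tp / (tp + fn),
            "fdr": fp / max(tp + fp, 1),
            "null_positive_rate": float((null_p <= 0.05).mean()),
            "median_planted_log2fc": float(np.median(med_lfc)),
            "n_sims": n_sims}


# ------------------------------------------------------------- proteome ---

def top3_normalization_exactness(seed: int) -> dict:
    """Max relative deviation of replicate sums after the correction factor."""
    table, _ = simulate.gen_peptide_table(seed=_derive_seed(seed, 6))
    quant = proteome.top3_quantify(table)
    devs = []
    for per_condition in (True, False):
        norm, _ = proteome.normalize_replicates(quant.top3, per_condition)
        sums = norm.sum(axis=0)
        if per_condition:
            target = sums.groupby(level=0).transform("mean")
        else:
            target = sums.mean()
        devs.append(float((sums / target - 1.0).abs().max()))
    return {"replicate_sum_max_rel_dev": max(devs)}


def proteome_recovery(seed: int) -> dict:
    """RP mass-fraction, log2FC and stoichiometry recovery on planted data."""
    table, truth = simulate.gen_peptide_table(rp_share=0.75, rp_reduction=0.3,
                                              seed=_derive_seed(seed, 7))
    rp = truth["rp_proteins"]
    quant = proteome.top3_quantify(table)
    norm, _ = proteome.normalize_replicates(quant.top3)
    frac = proteome.rp_mass_fraction(norm["shControl"], rp)
    diff = proteome.differential_abundance(norm, quant.detected,
                                           "shControl", "shDYRK1A")
    rp_lfc = diff.loc[diff.index.isin(rp), "log2fc"].dropna()
    shares = proteome.stoichiometry(norm, rp)
    rho, _ = rstats.spearman_rho(shares["shControl"].values,
                                 shares["shDYRK1A"].values)
    return {
        "rp_mass_fraction": float(frac.mean()),
        "rp_share_abs_err": float(abs(frac.mean() - 0.75)),
        "median_rp_log2fc": float(rp_lfc.median()),
        "rp_log2fc_abs_err": float(abs(rp_lfc.median() - np.log2(0.7))),
        "stoichiometry_sum_max_dev": float(
            (shares.sum(axis=0) - 1.0).abs().max()),
        "stoichiometry_rho": float(rho),
    }


# ------------------------------------------------------------- polysome ---

def polysome_benchmark(seed: int, n_noisy: int = 20) -> dict:
    trace, truth = simulate.gen_polysome_trace(noise_sd=0.0)
    seg = polysome.segment_profile(trace)
    noiseless_err = abs(seg.pm_ratio / truth["pm_ratio"] - 1.0)
    ok = 0
    for s in range(n_noisy):
        noisy, _ = simulate.gen_polysome_trace(noise_sd=0.01,
                                               seed=_derive_seed(seed, 200 + s))
        ratio = polysome.segment_profile(noisy).pm_ratio
        ok += abs(ratio / truth["pm_ratio"] - 1.0) <= 0.10
    return {"pm_ratio": float(seg.pm_ratio),
            "pm_ratio_true": float(truth["pm_ratio"]),
            "noiseless_rel_err": float(noiseless_err),
            "noisy_frac_within_10pct": ok / n_noisy,
            "n_noisy": n_noisy}


# ---------------------------------------------------------------- stats ---

def exact_test_oracles(seed: int, n_cases: int = 30) -> dict:
    """Max |error| of exact Mann-Whitney / Wilcoxon p vs full enumeration."""
    rng = np.random.default_rng(_derive_seed(seed, 8))
    mw_err = 0.0
    for _ in range(n_cases):
        n, m = rng.integers(2, 9, size=2)
        tie = rng.random() < 0.5
        x = (rng.integers(0, 5, n) if tie else rng.normal(size=n)).astype(float)
        y = (rng.integers(0, 5, m) if tie else rng.normal(size=m)).astype(float)
        rep = rstats.mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        w_obs = ranks[:n].sum()
        sums = np.array([ranks[list(c)].sum() for c in
                         itertools.combinations(range(n + m), int(n))])
        lower = np.mean(sums <= w_obs + 1e-9)
        upper = np.mean(sums >= w_obs - 1e-9)
        oracle = min(1.0, 2 * min(lower, upper))
        mw_err = max(mw_err, abs(rep.p_value - oracle))

    wx_err = 0.0
    for _ in range(n_cases):
        n = int(rng.integers(2, 9))
        x = rng.normal(size=n)
        y = x - rng.normal(0.5, 1.0, size=n)
        d = x - y
        d = d[d != 0]
        if len(d) == 0:
            continue
        rep = rstats.wilcoxon_signed_rank(x, y)
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        sums = np.array([sum(r for s, r in zip(signs, ranks) if s)
                         for signs in itertools.product([0, 1],
                                                        repeat=len(d))])
        lower = np.mean(sums <= w_obs + 1e-9)
        upper = np.mean(sums >= w_obs - 1e-9)
        oracle = min(1.0, 2 * min(lower, upper))
        wx_err = max(wx_err, abs(rep.p_value - oracle))

    bh = rstats.bh_adjust([0.01, 0.02, 0.03])
    bh_err = float(np.abs(bh - np.array([0.03, 0.03, 0.03])).max())
    bh2 = rstats.bh_adjust([0.01, 0.04, 0.03, 0.005])
    bh_err = max(bh_err, float(
        np.abs(bh2 - np.array([0.02, 0.04, 0.04, 0.02])).max()))
    return {"mann_whitney_max_abs_err": float(mw_err),
            "wilcoxon_max_abs_err": float(wx_err),
            "bh_max_abs_err": bh_err,
            "n_cases": n_cases}
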