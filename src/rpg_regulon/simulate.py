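"""Seeded generators for every input the pipeline consumes, with ground truth.

Each generator is a pure function of (parameters, seed) built on
``numpy.random.default_rng`` and returns both the dataset and a JSON-ready
truth sidecar recording what was planted (motif offsets, bound genes, true
log2 fold changes, RP reductions, analytic peak areas) plus the generator
parameters, so every downstream stage can be scored against known truth
without external downloads.

The default ribosomal-protein-gene catalog holds the 80 canonical RPs plus
10 paralogs with synthetic TSS coordinates on a toy two-chromosome genome;
real coordinates are always user-supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chip import GenomicInterval, TSSAnchor
from .motif import DYRK1A_CONSENSUS
from .polysome import PolysomeTrace

__all__ = [
    "RPGRecord",
    "rpg_catalog",
    "toy_chrom_sizes",
    "gen_promoter_set",
    "gen_chip_experiment",
    "gen_count_matrix",
    "gen_peptide_table",
    "gen_polysome_trace",
]

TOY_CHROM_SIZES = {"chr1": 1_000_000, "chr2": 1_000_000}

_LARGE_SUBUNIT = (
    "RPL3 RPL4 RPL5 RPL6 RPL7 RPL7A RPL8 RPL9 RPL10 RPL10A RPL11 RPL12 "
    "RPL13 RPL13A RPL14 RPL15 RPL17 RPL18 RPL18A RPL19 RPL21 RPL22 RPL23 "
    "RPL23A RPL24 RPL26 RPL27 RPL27A RPL28 RPL29 RPL30 RPL31 RPL32 RPL34 "
    "RPL35 RPL35A RPL36 RPL36A RPL37 RPL37A RPL38 RPL39 RPL41 RPLP0 RPLP1 "
    "RPLP2 UBA52"
).split()
_SMALL_SUBUNIT = (
    "RPSA RPS2 RPS3 RPS3A RPS4X RPS5 RPS6 RPS7 RPS8 RPS9 RPS10 RPS11 RPS12 "
    "RPS13 RPS14 RPS15 RPS15A RPS16 RPS17 RPS18 RPS19 RPS20 RPS21 RPS23 "
    "RPS24 RPS25 RPS26 RPS27 RPS27A RPS28 RPS29 FAU RPS4Y1"
).split()
_PARALOGS = (
    "RPL3L RPL7L1 RPL10L RPL22L1 RPL26L1 RPL36AL RPL39L RPS4Y2 RPS27L RPS17L"
).split()


@dataclass(frozen=True)
class RPGRecord:
    symbol: str
    subunit: str          # 'RPL' (large) or 'RPS' (small)
    paralog: bool
    anchor: TSSAnchor


def rpg_catalog() -> list[RPGRecord]:
    """Default catalog: 80 canonical RPs + 10 paralogs, toy TSS coordinates.

    Genes alternate between the two toy chromosomes, 21 kb apart, with
    alternating strands - deterministic, no RNG involved.
    """
    records = []
    entries = (
        [(s, "RPL", False) for s in _LARGE_SUBUNIT]
        + [(s, "RPS", False) for s in _SMALL_SUBUNIT]
        + [(s, "RPL" if s.startswith("RPL") else "RPS", True) for s in _PARALOGS]
    )
    chroms = list(TOY_CHROM_SIZES)
    for i, (symbol, subunit, paralog) in enumerate(entries):
        chrom = chroms[i % len(chroms)]
        pos = 15_000 + (i // len(chroms)) * 21_000
        strand = "+" if i % 4 < 2 else "-"
        records.append(RPGRecord(symbol, subunit, paralog,
                                 TSSAnchor(symbol, chrom, pos, strand)))
    assert len(records) == 90
    return records


def toy_chrom_sizes() -> dict[str, int]:
    return dict(TOY_CHROM_SIZES)


def _planted_count(n: int, fraction: float) -> int:
    return int(np.floor(n * fraction + 0.5))  # round half up


def gen_promoter_set(n: int = 90, motif_fraction: float = 0.25,
                     gc: float = 0.5, width: int = 500, central_sd: float = 50.0,
                     consensus: str = DYRK1A_CONSENSUS, seed: int = 0,
                     gene_ids=None, planted_genes=None):
    """Random promoters with the consensus planted in a seeded subset.

    Background bases are i.i.d. at the given GC content; planted promoters
    receive one consensus insertion whose start offset is drawn
    normal(centre, central_sd), clipped to the sequence.  Returns
    ``(records, truth)`` with records ``[(id, seq), ...]``.
    """
    if not 0 <= motif_fraction <= 1:
        raise ValueError("motif_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"promoter_{i:03d}" for i in range(n)]
    if len(gene_ids) != n:
        raise ValueError("gene_ids length must equal n")
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    if planted_genes is not None:
        planted_idx = {i for i, g in enumerate(gene_ids)
                       if g in set(planted_genes)}
        n_planted = len(planted_idx)
    else:
        n_planted = _planted_count(n, motif_fraction)
        planted_idx = set(rng.choice(n, size=n_planted, replace=False).tolist())
    L = len(consensus)
    centre = (width - L) / 2.0
    records, truth_genes = [], {}
    for i, gid in enumerate(gene_ids):
        seq = rng.choice(alphabet, size=width, p=base_p)
        offset = None
        if i in planted_idx:
            offset = int(np.clip(round(rng.normal(centre, central_sd)),
                                 0, width - L))
            seq[offset: offset + L] = list(consensus)
        records.append((gid, "".join(seq)))
        truth_genes[gid] = {"planted": i in planted_idx, "offset": offset}
    truth = {
        "generator": "gen_promoter_set",
        "seed": seed,
        "params": {"n": n, "motif_fraction": motif_fraction, "gc": gc,
                   "width": width, "central_sd": central_sd,
                   "consensus": consensus},
        "n_planted": n_planted,
        "genes": truth_genes,
    }
    return records, truth


def gen_chip_experiment(anchors, bound_genes, chrom_sizes=None,
                        depth: int = 100_000, enrichment: float = 8.0,
                        peak_sd: float = 100.0, peak_offset: int = -100,
                        read_length: int = 50, peak_window: int = 1000,
                        seed: int = 0):
    """Synthetic ChIP reads: uniform background plus TSS-proximal enrichment.

    Background ``depth`` reads are uniform over the genome; each bound
    anchor receives extra reads placed normal(TSS + peak_offset, peak_sd)
    (strand-aware: the offset is upstream of the TSS), sized so the read
    density over ``peak_window`` bp is ``enrichment``-fold the background.
    Returns ``(reads, truth)``; reads are GenomicIntervals counted by 5' end.
    """
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    if depth < 1_000:
        raise ValueError("depth must be >= 1e3")
    anchors = list(anchors)
    by_gene = {a.gene_id: a for a in anchors}
    unknown = set(bound_genes) - set(by_gene)
    if unknown:
        raise ValueError(f"bound genes not among anchors: {sorted(unknown)}")
    if chrom_sizes is None:
        chrom_sizes = toy_chrom_sizes()
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    genome = sizes.sum()

    reads = []

    def add_read(chrom, pos, strand, size):
        pos = int(np.clip(pos, 0, size - 1))
        if strand == "+":
            start, end = pos, min(pos + read_length, size)
        else:
            start, end = max(pos - read_length + 1, 0), pos + 1
        reads.append(GenomicInterval(chrom, start, end, strand))

    chrom_choice = rng.choice(len(chroms), size=depth, p=sizes / genome)
    positions = rng.integers(0, sizes[chrom_choice].astype(int))
    strands = rng.choice(["+", "-"], size=depth)
    for ci, pos, st in zip(chrom_choice, positions, strands):
        add_read(chroms[ci], pos, st, int(sizes[ci]))

    density = depth / genome
    n_extra = int(round((enrichment - 1.0) * density * peak_window))
    for gid in sorted(bound_genes):
        a = by_gene[gid]
        sign = 1 if a.strand == "+" else -1
        centre = a.pos + sign * peak_offset
        pos = rng.normal(centre, peak_sd, size=n_extra)
        st = rng.choice(["+", "-"], size=n_extra)
        for p, s in zip(pos, st):
            add_read(a.chrom, round(p), s, chrom_sizes[a.chrom])

    truth = {
        "generator": "gen_chip_experiment",
        "seed": seed,
        "params": {"depth": depth, "enrichment": enrichment,
                   "peak_sd": peak_sd, "peak_offset": peak_offset,
                   "read_length": read_length, "peak_window": peak_window},
        "bound_genes": sorted(bound_genes),
        "reads_per_peak": n_extra,
        "library_size": len(reads),
    }
    return reads, truth


def gen_count_matrix(n_genes: int = 2000, n_spike: int = 500,
                     reps_per_condition: int = 3, rpg_genes=None,
                     global_shift_log2: float = -1.0, dispersion: float = 0.05,
                     rpg_mean: float = 2000.0, base_mean_median: float = 500.0,
                     base_mean_sigma: float = 0.5, spike_mean_median: float = 400.0,
                     conditions=("shControl", "shDYRK1A"), seed: int = 0):
    """Negative-binomial count matrix with a planted knockdown shift.

    Spike genes have identical expected values in both conditions (the fixed
    exogenous pool); genes in ``rpg_genes`` are shifted by
    ``global_shift_log2`` in the second condition.  RPG genes are drawn
    highly expressed (they sit in the top expression tier in real data).
    Returns ``(CountMatrix, truth)``.
    """
    from .expression import CountMatrix

    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if n_spike < 1:
        raise ValueError("need at least one spike gene")
    rng = np.random.default_rng(seed)
    rpg_genes = list(rpg_genes) if rpg_genes is not None else []
    n_other = n_genes - len(rpg_genes)
    if n_other < 0:
        raise ValueError("more RPG genes than total genes")

    gene_ids = ([f"SPIKE_{i:04d}" for i in range(n_spike)]
                + list(rpg_genes)
                + [f"GENE_{i:04d}" for i in range(n_other)])
    means = np.concatenate([
        rng.lognormal(np.log(spike_mean_median), 1.0, size=n_spike),
        rng.lognormal(np.log(rpg_mean), 0.5, size=len(rpg_genes)),
        rng.lognormal(np.log(base_mean_median), base_mean_sigma, size=n_other),
    ])
    true_lfc = np.zeros(len(gene_ids))
    true_lfc[n_spike: n_spike + len(rpg_genes)] = global_shift_log2

    samples, conds = [], {}
    counts = {}
    for c_idx, cond in enumerate(conditions):
        shift = np.where(c_idx == 0, 0.0, true_lfc)
        mu = means * 2.0 ** shift
        r = 1.0 / dispersion
        p = r / (r + mu)
        for rep in range(1, reps_per_condition + 1):
            name = f"{cond}_{rep}"
            counts[name] = rng.negative_binomial(r, p)
            conds[name] = cond
            samples.append(name)
    df = pd.DataFrame(counts, index=gene_ids)[samples]
    is_spike = pd.Series(df.index.str.startswith("SPIKE_"), index=df.index)
    cm = CountMatrix(df, is_spike, pd.Series(conds)[df.columns])
    truth = {
        "generator": "gen_count_matrix",
        "seed": seed,
        "params": {"n_genes": n_genes, "n_spike": n_spike,
                   "reps_per_condition": reps_per_condition,
                   "global_shift_log2": global_shift_log2,
                   "dispersion": dispersion},
        "true_log2fc": dict(zip(gene_ids, true_lfc.tolist())),
        "true_size_factors": {s: 1.0 for s in samples},
        "rpg_genes": list(rpg_genes),
    }
    return cm, truth


def gen_peptide_table(n_proteins: int = 500, rp_share: float = 0.75,
                      peptides_per_protein: int = 6, sigma_log: float = 0.25,
                      rp_reduction: float = 0.3, reps: int = 6,
                      rp_proteins=None,
                      conditions=("shControl", "shDYRK1A"), seed: int = 0):
    """Log-normal peptide areas with a planted RP reduction in the knockdown.

    RP base areas are rescaled so the expected RP share of the summed TOP3
    signal equals ``rp_share`` in the control condition; knockdown RP areas
    are multiplied by ``1 - rp_reduction``.  ``sigma_log`` is the per
    peptide-replicate log2-scale noise SD.  Returns ``(table, truth)``.
    """
    if not 0 < rp_share < 1:
        raise ValueError("rp_share must be in (0, 1)")
    if not 0 <= rp_reduction < 1:
        raise ValueError("rp_reduction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if rp_proteins is None:
        rp_proteins = [r.symbol for r in rpg_catalog()]
    rp_proteins = list(rp_proteins)
    if len(rp_proteins) >= n_proteins:
        raise ValueError("need non-RP proteins in the mixture")
    other = [f"PROT_{i:04d}" for i in range(n_proteins - len(rp_proteins))]
    proteins = rp_proteins + other
    is_rp = np.array([p in set(rp_proteins) for p in proteins])

    abundance = rng.lognormal(np.log(1e6), 1.0, size=n_proteins)
    pep_factors = rng.lognormal(0.0, 0.5,
                                size=(n_proteins, peptides_per_protein))
    base_areas = abundance[:, None] * pep_factors

    def top3(areas):
        return np.sort(areas, axis=1)[:, ::-1][:, :3].mean(axis=1)

    base_top3 = top3(base_areas)
    scale = (rp_share / (1 - rp_share)
             * base_top3[~is_rp].sum() / base_top3[is_rp].sum())
    base_areas[is_rp] *= scale

    rows = []
    for cond in conditions:
        cond_scale = np.where(is_rp & (cond == conditions[1]),
                              1.0 - rp_reduction, 1.0)
        for rep in range(1, reps + 1):
            noise = 2.0 ** rng.normal(0.0, sigma_log, size=base_areas.shape)
            areas = base_areas * cond_scale[:, None] * noise
            for pi, prot in enumerate(proteins):
                for pj in range(peptides_per_protein):
                    rows.append((prot, f"{prot}_pep{pj}", cond, rep,
                                 areas[pi, pj]))
    table = pd.DataFrame(rows, columns=["protein_id", "peptide_id",
                                        "condition", "replicate", "area"])
    truth = {
        "generator": "gen_peptide_table",
        "seed": seed,
        "params": {"n_proteins": n_proteins, "rp_share": rp_share,
                   "peptides_per_protein": peptides_per_protein,
                   "sigma_log": sigma_log, "rp_reduction": rp_reduction,
                   "reps": reps},
        "rp_proteins": rp_proteins,
        "true_rp_log2fc": float(np.log2(1.0 - rp_reduction))
        if rp_reduction > 0 else 0.0,
    }
    return table, truth


DEFAULT_PEAKS = ((10.0, 0.5, 0.2), (14.0, 0.5, 0.3),
                 (18.0, 0.6, 1.0), (30.0, 2.5, 0.8))


def gen_polysome_trace(peak_params=DEFAULT_PEAKS, baseline_slope: float = 0.0,
                       baseline_offset: float = 0.0, noise_sd: float = 0.0,
                       n_points: int = 800, x_max: float = 40.0,
                       seed: int = 0):
    """Gaussian-mixture A254 trace with analytic ground-truth areas.

    ``peak_params`` is an ordered list of (centre, sd, amplitude) for the
    40S, 60S, 80S and polysome peaks; a linear baseline and i.i.d. Gaussian
    noise are added on top.  Truth stores the analytic area
    amplitude * sd * sqrt(2*pi) of each peak and the implied P:M ratio.
    """
    peak_params = [tuple(map(float, p)) for p in peak_params]
    if len(peak_params) < 4:
        raise ValueError("need at least four peaks (40S, 60S, 80S, polysome)")
    centres = [p[0] for p in peak_params]
    if any(b <= a for a, b in zip(centres, centres[1:])):
        raise ValueError("peak centres must be strictly increasing")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, x_max, n_points)
    signal = baseline_offset + baseline_slope * x
    for centre, sd, amp in peak_params:
        signal = signal + amp * np.exp(-0.5 * ((x - centre) / sd) ** 2)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=n_points)
    areas = [amp * sd * np.sqrt(2 * np.pi) for _, sd, amp in peak_params]
    truth = {
        "generator": "gen_polysome_trace",
        "seed": seed,
        "params": {"peak_params": peak_params,
                   "baseline_slope": baseline_slope,
                   "baseline_offset": baseline_offset,
                   "noise_sd": noise_sd, "n_points": n_points, "x_max": x_max},
        "areas": areas,
        "pm_ratio": float(sum(areas[3:]) / areas[2]),
    }
    return PolysomeTrace(x, signal), truth
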