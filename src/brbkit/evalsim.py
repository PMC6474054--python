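"""Differential-expression benchmarking and negative-binomial power simulation.

Two halves:

* **Evaluation against a gold standard.** A deeply sequenced reference
  experiment yields a self-assigned positive set of DE genes (|FC| >= 2 and
  BH FDR <= 0.05 by default) inside a universe of expressed genes; shallower
  or alternative libraries are scored by empirical power (true-positive
  rate) and by ROC / precision-recall curves built by sweeping every cutoff
  of the ranked p-value list.

* **Power simulation.** Counts are drawn from a negative binomial whose
  mean-dispersion relationship is estimated from real (or simulated) data;
  a configurable fraction of genes receives a log2 fold change drawn from a
  narrow gamma with random sign, split symmetrically between the two
  groups. A moment-based Wald test provides the built-in DE caller so power
  curves over replicate numbers can be computed end to end; externally
  produced DE tables are accepted everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DE_TABLE_COLUMNS = ["gene_id", "log2fc", "pvalue", "padj"]


# ---------------------------------------------------------------------------
# gold standard and evaluation
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def make_de_table(gene_ids, log2fc, pvalue, padj=None) -> pd.DataFrame:
    """Assemble a DE result table; padj is BH-computed when omitted."""
    tab = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "log2fc": np.asarray(log2fc, dtype=float),
            "pvalue": np.asarray(pvalue, dtype=float),
        }
    )
    tab["padj"] = bh_adjust(tab["pvalue"]) if padj is None else np.asarray(padj, float)
    return tab


@dataclass(frozen=True)
class GoldStandard:
    """Positive DE gene set inside a universe of expressed genes."""

    positives: frozenset
    universe: frozenset

    def __post_init__(self):
        if not self.positives <= self.universe:
            raise ValueError("positives must be a subset of the universe")

    @property
    def negatives(self) -> frozenset:
        return self.universe - self.positives

    @classmethod
    def from_sets(cls, positives: Iterable, universe: Iterable) -> "GoldStandard":
        return cls(frozenset(positives), frozenset(universe))


def filter_de(
    table: pd.DataFrame, fc_cut: float = 2.0, fdr_cut: float = 0.05
) -> Set[str]:
    """Genes passing |log2FC| >= log2(fc_cut) and padj <= fdr_cut."""
    if len(table) == 0:
        return set()
    keep = (table["log2fc"].abs() >= math.log2(fc_cut)) & (table["padj"] <= fdr_cut)
    return set(table.loc[keep, "gene_id"])


def empirical_power(test_set: Iterable, gold: GoldStandard) -> Dict[str, float]:
    """Overlap of a called DE set with the gold standard positives."""
    called = set(test_set)
    tp = len(called & gold.positives)
    n_pos = len(gold.positives)
    return {
        "n_de": len(called),
        "n_true_positive": tp,
        "tpr": tp / n_pos if n_pos else 0.0,
        "positives_empty": n_pos == 0,
    }


@dataclass
class CurveSet:
    """ROC and precision-recall curves from a ranked p-value list."""

    roc: np.ndarray  # columns: FPR, TPR
    pr: np.ndarray  # columns: recall, precision
    roc_auc: float
    pr_auc: float

    def write_tsv(self, path) -> None:
        from ._utils import atomic_write

        with atomic_write(path) as fh:
            fh.write(f"# roc_auc={self.roc_auc:.6g}\tpr_auc={self.pr_auc:.6g}\n")
            fh.write("curve\tx\ty\n")
            for x, y in self.roc:
                fh.write(f"roc\t{x:.6g}\t{y:.6g}\n")
            for x, y in self.pr:
                fh.write(f"pr\t{x:.6g}\t{y:.6g}\n")


def roc_pr_from_ranked(table: pd.DataFrame, gold: GoldStandard) -> CurveSet:
    """Sweep every p-value cutoff of the ranked list to build ROC/PR curves.

    The table is restricted to the gold universe; universe genes absent
    from the table are penalized with p = 1 so that comparisons across
    methods keep a fixed universe. At each unique p-value cutoff, genes
    with p <= cutoff are "called"; FPR, TPR and precision follow from the
    gold positives/negatives. AUCs are trapezoidal.
    """
    n_pos, n_neg = len(gold.positives), len(gold.negatives)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("gold standard needs non-empty positives and negatives")
    pmap = dict(zip(table["gene_id"], table["pvalue"]))
    genes = sorted(gold.universe)
    p = np.array([pmap.get(g, 1.0) for g in genes])
    y = np.array([g in gold.positives for g in genes], dtype=bool)

    order = np.argsort(p, kind="stable")
    p_sorted, y_sorted = p[order], y[order]
    cum_tp = np.cumsum(y_sorted)
    cum_fp = np.cumsum(~y_sorted)
    # indices where a run of tied p-values ends: these are the cutoffs
    last_of_tie = np.nonzero(np.diff(np.append(p_sorted, np.inf)) > 0)[0]
    tp = cum_tp[last_of_tie].astype(float)
    fp = cum_fp[last_of_tie].astype(float)
    tpr = tp / n_pos
    fpr = fp / n_neg
    precision = tp / (tp + fp)

    roc = np.column_stack([np.concatenate([[0.0], fpr]), np.concatenate([[0.0], tpr])])
    roc_auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    pr = np.column_stack(
        [np.concatenate([[0.0], tpr]), np.concatenate([[precision[0]], precision])]
    )
    pr_auc = float(np.trapezoid(pr[:, 1], pr[:, 0]))
    return CurveSet(roc=roc, pr=pr, roc_auc=roc_auc, pr_auc=pr_auc)


def depth_for_detection(cpm: float, prob: float = 0.95) -> int:
    """Minimal sequencing depth detecting a gene of given CPM reliably.

    A gene expressed at ``cpm`` counts-per-million is hit by each sequenced
    read with probability cpm/1e6; detection means at least one read. The
    smallest depth D with 1 - (1 - cpm/1e6)^D >= prob is
    ceil(ln(1 - prob) / ln(1 - cpm/1e6)).
    """
    if not (0 < cpm <= 1e6):
        raise ValueError("cpm must be in (0, 1e6]")
    if not (0 < prob < 1):
        raise ValueError("prob must be in (0, 1)")
    rate = cpm / 1e6
    if rate == 1.0:
        return 1
    d = math.ceil(math.log1p(-prob) / math.log1p(-rate))
    return max(d, 1)


# ---------------------------------------------------------------------------
# negative-binomial simulation and testing
# ---------------------------------------------------------------------------

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization factors (columns = samples).

    Uses genes with non-zero counts in every sample; falls back to
    library-size ratios when no such gene exists.
    """
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=1)
    if positive.any():
        logc = np.log(counts[positive])
        log_geo = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - log_geo, axis=0))
    else:
        lib = counts.sum(axis=0)
        sf = lib / np.exp(np.log(np.where(lib > 0, lib, 1)).mean())
    return np.where(sf > 0, sf, 1.0)


@dataclass
class DispersionTrend:
    """Log-linear mean-dispersion trend: log(disp) = a + b log(mean)."""

    intercept: float
    slope: float
    floor: float = 1e-8

    def __call__(self, mean) -> np.ndarray:
        mean = np.asarray(mean, dtype=float)
        with np.errstate(divide="ignore"):
            d = np.exp(self.intercept + self.slope * np.log(np.where(mean > 0, mean, np.nan)))
        return np.where(np.isfinite(d), np.maximum(d, self.floor), self.floor)


def estimate_nb_params(
    counts, groups: Optional[Sequence] = None
) -> Tuple[pd.DataFrame, DispersionTrend]:
    """Per-gene NB mean and dispersion plus a fitted mean-dispersion trend.

    Counts are normalized by median-of-ratios size factors. Dispersion is
    the method-of-moments estimate max((var - mean) / mean^2, 0); when
    group labels are given, variances are pooled within groups so that real
    signal does not inflate the dispersion. The trend is an ordinary
    least-squares fit of log dispersion on log mean over genes with
    positive dispersion.
    """
    counts = np.asarray(counts, dtype=float)
    sf = size_factors(counts)
    norm = counts / sf
    mean = norm.mean(axis=1)
    if groups is None:
        var = norm.var(axis=1, ddof=1)
    else:
        groups = np.asarray(groups)
        num = np.zeros(norm.shape[0])
        den = 0
        for g in np.unique(groups):
            sub = norm[:, groups == g]
            if sub.shape[1] > 1:
                num += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
                den += sub.shape[1] - 1
        var = num / max(den, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var - mean) / mean**2
    disp = np.where(np.isfinite(disp), np.maximum(disp, 0.0), 0.0)
    params = pd.DataFrame({"mean": mean, "dispersion": disp})

    ok = (mean > 0) & (disp > 1e-8)
    if ok.sum() >= 2:
        x = np.log(mean[ok])
        yv = np.log(disp[ok])
        slope, intercept = np.polyfit(x, yv, 1)
    else:
        # not enough overdispersed genes: flat trend at median dispersion
        slope, intercept = 0.0, np.log(max(np.median(disp), 1e-8))
    return params, DispersionTrend(intercept=float(intercept), slope=float(slope))


@dataclass
class SimTruth:
    """Ground truth of one simulated two-group experiment."""

    table: pd.DataFrame  # gene_id, is_de, log2fc, mean, dispersion
    n_genes: int
    frac_de: float
    n_reps: int
    seed: int

    @property
    def de_genes(self) -> Set[str]:
        return set(self.table.loc[self.table["is_de"], "gene_id"])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """NB(mu, dispersion) with Poisson limit at dispersion 0."""
    mu = np.asarray(mu, dtype=float)
    disp = np.asarray(disp, dtype=float)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = disp <= 1e-12
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        r = 1.0 / disp[~pois]
        p = r / (r + mu[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def simulate_de_counts(
    n_genes: int = 10000,
    frac_de: float = 0.10,
    n_reps: int = 5,
    nb_params: Optional[pd.DataFrame] = None,
    trend: Optional[DispersionTrend] = None,
    mean_log_mu: float = 2.0,
    mean_log_sigma: float = 1.5,
    lfc_shape: float = 2.0,
    lfc_scale: float = 0.5,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, SimTruth]:
    """Simulate a two-group NB count matrix with a known DE gene set.

    Exactly ``round(frac_de * n_genes)`` genes are differentially
    expressed; their |log2FC| is Gamma(lfc_shape, lfc_scale) with random
    sign, applied symmetrically (group means mean * 2^(±lfc/2)). Baseline
    means come from ``nb_params`` (resampled rows) when provided, else from
    a log-normal; dispersions come from ``nb_params``/``trend`` or a
    default decreasing trend disp = 0.1 + 1/mean.

    Returns ``(counts, groups, truth)`` with counts genes × (2*n_reps) and
    groups a 0/1 label vector.
    """
    rng = np.random.default_rng(seed)
    if nb_params is not None:
        take = rng.integers(0, len(nb_params), size=n_genes)
        base_mean = nb_params["mean"].to_numpy()[take]
        base_mean = np.maximum(base_mean, 0.1)
        if trend is not None:
            disp = trend(base_mean)
        else:
            disp = nb_params["dispersion"].to_numpy()[take]
    else:
        base_mean = rng.lognormal(mean=mean_log_mu, sigma=mean_log_sigma, size=n_genes)
        disp = trend(base_mean) if trend is not None else 0.1 + 1.0 / base_mean

    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    lfc = np.zeros(n_genes)
    if n_de:
        mag = rng.gamma(shape=lfc_shape, scale=lfc_scale, size=n_de)
        sign = rng.choice([-1.0, 1.0], size=n_de)
        lfc[de_idx] = mag * sign

    mu1 = base_mean * 2.0 ** (lfc / 2.0)
    mu2 = base_mean * 2.0 ** (-lfc / 2.0)
    counts = np.empty((n_genes, 2 * n_reps), dtype=np.int64)
    for j in range(n_reps):
        counts[:, j] = _nb_draw(rng, mu1, disp)
    for j in range(n_reps):
        counts[:, n_reps + j] = _nb_draw(rng, mu2, disp)
    groups = np.array([0] * n_reps + [1] * n_reps)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    truth = SimTruth(
        table=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "is_de": lfc != 0.0,
                "log2fc": lfc,
                "mean": base_mean,
                "dispersion": disp,
            }
        ),
        n_genes=n_genes,
        frac_de=frac_de,
        n_reps=n_reps,
        seed=seed,
    )
    return counts, groups, truth


def nb_two_group_test(
    counts, groups, gene_ids: Optional[Sequence[str]] = None, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Moment-based NB Wald test for a two-group comparison.

    Counts are size-factor normalized; the statistic is the difference of
    log group means with a delta-method standard error using pooled
    within-group method-of-moments dispersions, referred to a t
    distribution with n1 + n2 - 2 degrees of freedom. log2FC uses a
    pseudocount on both group means. All-zero genes get p = 1, log2fc = 0.
    This is deliberately simple plumbing; externally produced DE tables are
    accepted by every evaluation function.
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    sf = size_factors(counts)
    norm = counts / sf
    a = norm[:, groups == labels[0]]
    b = norm[:, groups == labels[1]]
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1) if n1 > 1 else np.zeros(len(m1))
    v2 = b.var(axis=1, ddof=1) if n2 > 1 else np.zeros(len(m2))
    m_pool = (n1 * m1 + n2 * m2) / (n1 + n2)
    v_pool = ((n1 - 1) * v1 + (n2 - 1) * v2) / max(n1 + n2 - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (v_pool - m_pool) / m_pool**2
    disp = np.where(np.isfinite(disp), np.maximum(disp, 0.0), 0.0)

    mu1 = m1 + pseudocount
    mu2 = m2 + pseudocount
    # delta method on ln(mean + pseudocount); NB variance mu + disp*mu^2
    se2 = (m1 + disp * m1**2) / (n1 * mu1**2) + (m2 + disp * m2**2) / (n2 * mu2**2)
    log2fc = np.log2(mu1 / mu2)
    zero = (m1 == 0) & (m2 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se2 > 0, (np.log(mu1) - np.log(mu2)) / np.sqrt(se2), 0.0)
    df = max(n1 + n2 - 2, 1)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    pval = np.where(zero | (se2 == 0), 1.0, np.clip(pval, 0.0, 1.0))
    log2fc = np.where(zero, 0.0, log2fc)
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(counts.shape[0])]
    return make_de_table(gene_ids, log2fc, pval)


def power_curve(
    replicate_levels: Sequence[int] = (5, 20, 50),
    n_sims: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_genes: int = 10000,
    frac_de: float = 0.10,
    **sim_kwargs,
) -> pd.DataFrame:
    """Average true-positive rate of the built-in test per replicate level.

    For each level, ``n_sims`` datasets are simulated, tested, and the TPR
    at BH FDR ``alpha`` against the simulation truth is averaged. Returns a
    table with per-level mean and SD of the TPR.
    """
    rows = []
    for level in replicate_levels:
        tprs = []
        for s in range(n_sims):
            sim_seed = (seed * 100003 + level * 1009 + s) % (2**31 - 1)
            counts, groups, truth = simulate_de_counts(
                n_genes=n_genes, frac_de=frac_de, n_reps=level,
                seed=sim_seed, **sim_kwargs,
            )
            tab = nb_two_group_test(counts, groups, gene_ids=list(truth.table["gene_id"]))
            called = set(tab.loc[tab["padj"] <= alpha, "gene_id"])
            de = truth.de_genes
            tprs.append(len(called & de) / len(de) if de else 0.0)
        rows.append(
            {
                "n_replicates": level,
                "mean_tpr": float(np.mean(tprs)),
                "sd_tpr": float(np.std(tprs, ddof=1)) if len(tprs) > 1 else 0.0,
                "n_sims": n_sims,
            }
        )
    return pd.DataFrame(rows)


def read_de_table(path) -> pd.DataFrame:
    """Read a TSV DE table (gene_id, log2fc, pvalue[, padj])."""
    tab = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log2fc", "pvalue"} - set(tab.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if "padj" not in tab.columns:
        tab["padj"] = bh_adjust(tab["pvalue"])
    return tab[DE_TABLE_COLUMNS]


def write_de_table(table: pd.DataFrame, path) -> None:
    from ._utils import atomic_write

    with atomic_write(path) as fh:
        table.to_csv(fh, sep="\t", index=False)
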