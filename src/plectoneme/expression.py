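"""Three-strain transcriptome logic for supercoiling-responsive gene calling.

The experimental design compares three strains: a control carrying the
empty vector ("Ag"), a strain expressing catalytically dead gyrase
("Y119F", binds DNA but cannot supercoil) and a strain expressing active
gyrase ("gyrAB").  Genes responding to the *negative supercoiling activity*
are those differentially expressed between gyrAB and Y119F (the SRG set):
the Y119F comparison subtracts the burden of heterologous expression and
DNA binding, which both gyrase strains share.

The module provides

* a seeded negative-binomial count simulator with planted gene classes
  (supercoiling-responsive: shifted only in gyrAB; burden-responsive:
  shifted equally in gyrAB and Y119F; null: shifted nowhere);
* a compact internal differential-expression statistic (median-of-ratios
  normalisation, moderated t test on log2 normalised counts,
  Benjamini-Hochberg adjustment) so the set logic is testable end to end;
* strict-threshold DEG filtering and the triple-contrast set algebra;
* FPKM conversion, per-gene Z-score scaling, and a top-N sign-opposition
  comparison against an external fold-change table.

The internal statistic is not a reimplementation of a published
differential-expression method, and DEG counts obtained from real data with
external tools are not expected to be reproduced by it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

__all__ = [
    "STRAINS",
    "CONTRAST_NAMES",
    "DERecord",
    "ContrastResult",
    "SyntheticExpressionDesign",
    "generate_synthetic_counts",
    "size_factors",
    "simple_de_test",
    "filter_degs",
    "build_contrasts",
    "fpkm",
    "zscore_rows",
    "top_n_anticorrelation",
]

STRAINS = ("Ag", "Y119F", "gyrAB")
CONTRAST_NAMES = ("gyrAB_vs_Ag", "Y119F_vs_Ag", "gyrAB_vs_Y119F")


@dataclass(frozen=True)
class DERecord:
    """Per-gene differential-expression statistics."""

    gene_id: str
    log2_fold_change: float
    p_adjusted: float
    mean_expression: float

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_adjusted) or 0.0 <= self.p_adjusted <= 1.0):
            raise ValueError("p_adjusted must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticExpressionDesign:
    """Design of a synthetic three-strain count experiment.

    ``class_fractions`` orders (supercoiling_responsive, burden_responsive,
    null) and must sum to 1.  ``effect_size_log2`` is the planted absolute
    log2 fold change for the two responsive classes (sign drawn per gene).
    ``dispersion`` is the negative-binomial dispersion alpha in
    var = mu + alpha * mu^2.  Four biological replicates per strain by
    default, matching a typical bulk RNA-seq design.
    """

    n_genes: int = 1000
    class_fractions: tuple[float, float, float] = (0.1, 0.1, 0.8)
    effect_size_log2: float = 2.0
    dispersion: float = 0.1
    n_replicates: int = 4
    library_sizes: tuple[float, ...] | None = None
    baseline_log_mean: float = float(np.log(200.0))
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if any(f < 0 for f in self.class_fractions):
            raise ValueError("class_fractions must be non-negative")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per strain")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        n_samples = 3 * self.n_replicates
        if self.library_sizes is not None and len(self.library_sizes) != n_samples:
            raise ValueError(f"library_sizes must have length {n_samples}")

    @property
    def sample_names(self) -> list[str]:
        return [f"{s}_{r + 1}" for s in STRAINS for r in range(self.n_replicates)]


def generate_synthetic_counts(
    design: SyntheticExpressionDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts for 3 strains x n replicates, plus truth labels.

    Returns ``(counts, truth)``: counts indexed by gene_id with one column
    per sample; truth with columns (gene_id, gene_class, true_log2fc) where
    ``true_log2fc`` is the signed planted effect of the responsive classes.
    Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_genes
    n_sr = int(round(design.class_fractions[0] * n))
    n_burden = int(round(design.class_fractions[1] * n))
    classes = np.array(
        ["supercoiling_responsive"] * n_sr
        + ["burden_responsive"] * n_burden
        + ["null"] * (n - n_sr - n_burden)
    )
    rng.shuffle(classes)
    gene_ids = np.array([f"TK{i:04d}" for i in range(1, n + 1)])

    base_mu = rng.lognormal(design.baseline_log_mean, design.baseline_log_sd, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    effect = np.where(classes == "null", 0.0, signs * design.effect_size_log2)

    # per-strain expected means: responsive classes shift in gyrAB; the
    # burden class shifts identically in Y119F (so gyrAB vs Y119F is null
    # for it); supercoiling responders shift only in gyrAB.
    mu = {s: base_mu.copy() for s in STRAINS}
    shift = 2.0**effect
    is_sr = classes == "supercoiling_responsive"
    is_burden = classes == "burden_responsive"
    mu["gyrAB"] = np.where(is_sr | is_burden, base_mu * shift, base_mu)
    mu["Y119F"] = np.where(is_burden, base_mu * shift, base_mu)

    if design.library_sizes is None:
        lib = np.ones(3 * design.n_replicates)
    else:
        lib = np.asarray(design.library_sizes, dtype=float)
        if np.any(lib <= 0):
            raise ValueError("library sizes must be positive")

    cols = {}
    alpha = design.dispersion
    for j, name in enumerate(design.sample_names):
        strain = name.rsplit("_", 1)[0]
        m = mu[strain] * lib[j]
        # gamma-Poisson mixture: var = m + alpha m^2
        lam = rng.gamma(shape=1.0 / alpha, scale=m * alpha)
        cols[name] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "gene_class": classes, "true_log2fc": effect}
    )
    return counts, truth


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference = per-gene geometric mean)."""
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat)
    usable = np.all(np.isfinite(log_mat), axis=1)
    if not usable.any():
        raise ValueError("no gene has positive counts in every sample")
    log_ref = log_mat[usable].mean(axis=1)
    sf = np.exp(np.median(log_mat[usable] - log_ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _moderated_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample t with empirical-Bayes variance moderation.

    Per-gene pooled variances are squeezed toward a common prior
    (scaled inverse chi-square fitted to all genes by moments on
    log variance), and the residual degrees of freedom increase by the
    prior's -- the standard remedy for unstable variance estimates at
    few replicates.  Genes with zero variance in both groups get NaN.
    """
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    s2 = ((na - 1) * var_a + (nb - 1) * var_b) / df

    pos = s2 > 0
    if pos.sum() >= 2:
        z = np.log(s2[pos])
        # z ~ log s0^2 + log chi2_d/d noise; Var includes prior spread
        excess = z.var(ddof=1) - polygamma(1, df / 2.0)
        if excess > 1e-8:
            # invert trigamma(d0/2) = excess by bisection
            lo, hi = 1e-3, 1e6
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if polygamma(1, mid / 2.0) > excess:
                    lo = mid
                else:
                    hi = mid
            d0 = 0.5 * (lo + hi)
            s0_2 = float(np.exp(z.mean() - digamma(df / 2.0) + np.log(df / 2.0)
                                + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:  # variances tighter than chi-square noise: infinite prior df
            d0 = np.inf
            s0_2 = float(np.exp(z.mean() - digamma(df / 2.0) + np.log(df / 2.0)))
    else:
        d0, s0_2 = 0.0, 0.0

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 > 0:
        s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = df + d0
    else:
        s2_tilde = s2
        df_total = df

    se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
    diff = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    bad = se == 0.0
    t = np.where(bad, np.nan, t)
    p = np.where(bad, np.nan, p)
    return np.asarray(t, dtype=float), np.asarray(p, dtype=float)


def _strain_columns(counts: pd.DataFrame, strain: str) -> list[str]:
    cols = [c for c in counts.columns if c.rsplit("_", 1)[0] == strain]
    if not cols:
        raise ValueError(f"no samples found for strain {strain!r}")
    return cols


def simple_de_test(
    counts: pd.DataFrame,
    strain_test: str,
    strain_ref: str,
    design: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Per-gene differential expression of ``strain_test`` vs ``strain_ref``.

    Sample-to-strain assignment comes from ``design`` (sample -> strain) or,
    by default, from column names of the form ``<strain>_<replicate>``.
    Counts are normalised by median-of-ratios size factors computed on the
    two groups; the statistic is a two-sided moderated t test on
    log2(normalised count + 1) (empirical-Bayes variance squeeze across
    genes, essential at few replicates); p-values are Benjamini-Hochberg
    adjusted.
    Genes with zero counts in every sample are flagged ``filtered`` and get
    NaN statistics.

    Returns a frame with columns gene_id, log2FoldChange, stat, pvalue,
    padj, baseMean, filtered (log2FoldChange is test over reference).
    """
    if design is not None:
        design = pd.Series(design)
        cols_test = list(design.index[design == strain_test])
        cols_ref = list(design.index[design == strain_ref])
        if not cols_test or not cols_ref:
            raise ValueError("design does not cover both strains")
    else:
        cols_test = _strain_columns(counts, strain_test)
        cols_ref = _strain_columns(counts, strain_ref)
    if len(cols_test) < 2 or len(cols_ref) < 2:
        raise ValueError("need at least 2 replicates per strain")

    sub = counts[cols_ref + cols_test]
    sf = size_factors(sub)
    norm = sub / sf
    log_norm = np.log2(norm + 1.0)

    a = log_norm[cols_ref].to_numpy()
    b = log_norm[cols_test].to_numpy()
    mean_ref = norm[cols_ref].mean(axis=1).to_numpy()
    mean_test = norm[cols_test].mean(axis=1).to_numpy()
    base_mean = norm.mean(axis=1).to_numpy()

    all_zero = (sub.to_numpy() == 0).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mean_test) - np.log2(mean_ref)
    tstat, pval = _moderated_t(a, b)
    # constant genes (zero variance in both groups) carry no evidence
    flat = np.isnan(pval) & ~all_zero
    pval[flat] = 1.0
    tstat[flat] = 0.0

    lfc = np.where(all_zero, np.nan, lfc)
    pval_adj = np.full_like(pval, np.nan)
    keep = ~all_zero
    if keep.any():
        pval_adj[keep] = multipletests(pval[keep], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": counts.index.to_numpy(),
            "log2FoldChange": lfc,
            "stat": np.where(all_zero, np.nan, tstat),
            "pvalue": np.where(all_zero, np.nan, pval),
            "padj": pval_adj,
            "baseMean": base_mean,
            "filtered": all_zero,
        }
    )


def filter_degs(
    records: pd.DataFrame,
    fc_threshold: float = 1.25,
    padj_threshold: float = 0.05,
) -> set[str]:
    """Gene ids passing both strict thresholds.

    A gene qualifies when padj < ``padj_threshold`` and \\|fold change\\| >
    ``fc_threshold``, i.e. \\|log2FC\\| > log2(fc_threshold); both inequalities
    strict, so boundary genes are excluded.  NaN statistics never qualify.
    """
    if fc_threshold <= 0 or padj_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    lfc = records["log2FoldChange"].to_numpy(dtype=float)
    padj = records["padj"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        ok = (np.abs(lfc) > np.log2(fc_threshold)) & (padj < padj_threshold)
    return set(records["gene_id"].to_numpy()[np.nan_to_num(ok, nan=False).astype(bool)])


@dataclass(frozen=True)
class ContrastResult:
    """DEG sets of the three pairwise comparisons and their overlaps.

    The SRG (supercoiling-responsive gene) set is by definition the
    gyrAB-vs-Y119F DEG set: both strains carry the expression burden, only
    gyrAB has supercoiling activity.
    """

    deg_sets: dict[str, set[str]]
    srg_set: set[str] = field(init=False)
    overlap_counts: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        missing = set(CONTRAST_NAMES) - set(self.deg_sets)
        if missing:
            raise ValueError(f"missing comparisons: {sorted(missing)}")
        object.__setattr__(self, "srg_set", set(self.deg_sets["gyrAB_vs_Y119F"]))
        a, b, c = (self.deg_sets[k] for k in CONTRAST_NAMES)
        overlaps = {
            "gyrAB_vs_Ag&Y119F_vs_Ag": len(a & b),
            "gyrAB_vs_Ag&gyrAB_vs_Y119F": len(a & c),
            "Y119F_vs_Ag&gyrAB_vs_Y119F": len(b & c),
            "all_three": len(a & b & c),
        }
        object.__setattr__(self, "overlap_counts", overlaps)


def build_contrasts(
    tables: dict[str, pd.DataFrame],
    fc_threshold: float = 1.25,
    padj_threshold: float = 0.05,
) -> ContrastResult:
    """Apply DEG filtering to the three comparisons and collect the set algebra.

    ``tables`` maps the comparison names ``gyrAB_vs_Ag``, ``Y119F_vs_Ag``,
    ``gyrAB_vs_Y119F`` to DE tables sharing one gene universe.
    """
    missing = set(CONTRAST_NAMES) - set(tables)
    if missing:
        raise ValueError(f"missing comparisons: {sorted(missing)}")
    universes = {k: set(t["gene_id"]) for k, t in tables.items()}
    ref = universes[CONTRAST_NAMES[0]]
    for k, u in universes.items():
        if u != ref:
            diff = sorted((ref ^ u))[:10]
            raise ValueError(f"gene universe mismatch in {k}; differing ids: {diff}")
    deg_sets = {
        k: filter_degs(tables[k], fc_threshold, padj_threshold) for k in CONTRAST_NAMES
    }
    return ContrastResult(deg_sets=deg_sets)


def fpkm(
    counts: np.ndarray | pd.Series,
    gene_length_bp: np.ndarray | pd.Series,
    total_mapped: int,
) -> np.ndarray | pd.Series:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM_g = counts_g * 1e9 / (length_g * total_mapped).
    """
    lengths = np.asarray(gene_length_bp, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be > 0")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    return counts * 1e9 / (gene_length_bp * float(total_mapped))


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each row to mean 0 and scale to SD 1 (population convention).

    Rows with zero variance cannot be scaled and map to all-zero rows with
    a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples per row to Z-score")
    vals = matrix.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0.0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant row(s) mapped to zeros", stacklevel=2
        )
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (vals - mean) / safe_sd
    z[flat] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def top_n_anticorrelation(
    table: pd.DataFrame,
    reference: pd.DataFrame,
    n: int = 30,
) -> tuple[int, pd.DataFrame]:
    """Sign opposition of the top-N upregulated genes in an external dataset.

    Takes the ``n`` genes of ``table`` with the largest log2FoldChange and
    counts how many have a *negative* log2 fold change in ``reference``
    (columns gene_id, log2FoldChange).  Genes absent from the reference are
    excluded from numerator and denominator and reported in the returned
    frame with ``in_reference = False``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    top = (
        table.sort_values("log2FoldChange", ascending=False)
        .head(n)[["gene_id", "log2FoldChange"]]
        .rename(columns={"log2FoldChange": "log2fc"})
    )
    ref = reference[["gene_id", "log2FoldChange"]].rename(
        columns={"log2FoldChange": "reference_log2fc"}
    )
    merged = top.merge(ref, on="gene_id", how="left")
    merged["in_reference"] = merged["reference_log2fc"].notna()
    merged["anti_correlated"] = merged["in_reference"] & (
        merged["reference_log2fc"] < 0.0
    )
    return int(merged["anti_correlated"].sum()), merged
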