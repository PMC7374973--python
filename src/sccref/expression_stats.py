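"""Normalization and comparison statistics for count matrices.

Implements the quantities used to compare default vs SCC-informed
quantifications: counts-per-million and the log2(CPM + prior/L) transform
(L in millions of reads, so a zero count maps to the floor log2(prior/L)),
the minimum-CPM expression filter, TMM scaling factors, paired tests on
per-chromosome mapped-read totals, and per-gene / per-region fold changes
between quantifications paired by sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_regions import RegionLabel

DEFAULT_PRIOR = 0.25


@dataclass
class CountMatrix:
    """Gene-by-sample non-negative integer counts with per-sample metadata.

    ``sample_meta`` is indexed by sample id and may carry ``sex`` and
    ``reference`` (default/informed) labels; ``library_size`` defaults to the
    column sum unless overridden there.
    """

    counts: pd.DataFrame  # genes x samples, int
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.counts.columns)
        if "library_size" not in self.sample_meta.columns:
            self.sample_meta = self.sample_meta.copy()
            self.sample_meta["library_size"] = self.counts.sum(axis=0).astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.sample_meta["library_size"].astype(float)

    @classmethod
    def from_tsv(cls, path: str | Path, meta_path: str | Path | None = None) -> "CountMatrix":
        """Read a featureCounts-style TSV: gene ids in the first column.

        Known annotation columns (Chr, Start, End, Strand, Length) are
        tolerated and dropped; remaining columns are sample counts.
        """
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        drop = [c for c in df.columns if c in {"Chr", "Start", "End", "Strand", "Length"}]
        df = df.drop(columns=drop)
        meta = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", index_col=0)
            meta = meta.loc[df.columns]
        return cls(counts=df.astype(np.int64), sample_meta=meta)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.counts.to_csv(path, sep="\t", index_label="gene_id")
        return path


@dataclass
class ExprMatrix:
    """log2-CPM values on the same axes as the source counts.

    ``l_millions`` is the per-sample effective library size in millions of
    reads; every value is bounded below by the zero-count floor
    log2(prior / L) of its sample.
    """

    values: pd.DataFrame  # genes x samples, float
    prior: float
    l_millions: pd.Series
    tmm_factors: pd.Series | None = None
    sample_meta: pd.DataFrame | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def floor(self) -> pd.Series:
        """Per-sample zero-count floor log2(prior / L)."""
        return np.log2(self.prior / self.l_millions)


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million: count / (library_size / 1e6).

    Columns of a self-normalized library (library_size = column sum) sum to
    1e6 exactly up to float tolerance.
    """
    lib = counts.library_sizes
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero/negative library size for samples {bad}")
    return counts.counts / (lib / 1e6)


def log_cpm(
    counts: CountMatrix,
    prior: float = DEFAULT_PRIOR,
    tmm_factors: pd.Series | Mapping[str, float] | None = None,
) -> ExprMatrix:
    """log2(CPM + prior/L) with L the library size in millions.

    Algebraically the value is log2((count + prior) / L_millions): the prior
    count is scaled by the library so a zero count maps to the sample floor
    log2(prior / L). With the average library of 79.76 million reads and the
    default prior of 0.25 the floor is log2(0.25/79.76) = -8.32. When TMM
    factors are given, the effective library size is library_size * factor.
    """
    if prior <= 0:
        raise ValueError("prior count must be > 0")
    lib = counts.library_sizes.astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    factors = None
    if tmm_factors is not None:
        factors = pd.Series(tmm_factors).reindex(lib.index)
        lib = lib * factors
    l_millions = lib / 1e6
    vals = np.log2((counts.counts + prior) / l_millions)
    return ExprMatrix(
        values=vals,
        prior=prior,
        l_millions=l_millions,
        tmm_factors=factors,
        sample_meta=counts.sample_meta,
    )


def filter_min_cpm(
    counts: CountMatrix,
    groups: Mapping[str, str],
    min_cpm: float = 1.0,
) -> CountMatrix:
    """Keep genes whose mean CPM reaches ``min_cpm`` in at least one group.

    Library sizes (and hence CPM) are computed before filtering; gene order
    is preserved among survivors.
    """
    group_of = pd.Series({s: groups[s] for s in counts.samples})
    sizes = group_of.value_counts()
    if (sizes < 1).any() or len(sizes) == 0:
        raise ValueError("every group needs at least one sample")
    cpm_vals = cpm(counts)
    keep = pd.Series(False, index=counts.counts.index)
    for g in sizes.index:
        members = group_of.index[group_of == g]
        keep |= cpm_vals[members].mean(axis=1) >= min_cpm
    filtered = counts.counts.loc[keep]
    return CountMatrix(counts=filtered, sample_meta=counts.sample_meta.copy())


# ---------------------------------------------------------------------------
# TMM scaling factors (trimmed mean of M-values)
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: CountMatrix,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors.

    The reference sample is the library whose 75th-percentile count fraction
    is closest to the mean of those fractions (ties broken by lowest column
    index). Each sample's factor is 2**(weighted trimmed mean of gene-wise
    log2 ratios against the reference), trimming ``logratio_trim`` of the M
    values and ``abs_trim`` of the A values by rank, with inverse asymptotic
    binomial variances as weights. Factors are rescaled so their geometric
    mean is 1.
    """
    mat = counts.counts.to_numpy(dtype=float)
    lib = counts.library_sizes.to_numpy(dtype=float)
    n = mat.shape[1]
    if n < 2:
        raise ValueError("TMM needs at least 2 samples")
    f75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(n)])
    if np.allclose(f75, 0):
        raise ValueError("all upper quartiles are zero; cannot pick TMM reference")
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(n)
    for j in range(n):
        if j == ref:
            factors[j] = _tmm_pair(mat[:, j], mat[:, ref], lib[j], lib[ref],
                                   logratio_trim, abs_trim)
        else:
            factors[j] = _tmm_pair(mat[:, j], mat[:, ref], lib[j], lib[ref],
                                   logratio_trim, abs_trim)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.samples, name="tmm_factor")


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, abs_trim: float) -> float:
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("sample shares no positive genes with the TMM reference")
    o, r = obs[pos], ref[pos]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.abs(m).max() < 1e-6:  # identical relative composition
        return 1.0
    # double rank-based trim, as in the published TMM definition
    k = len(m)
    lo_m = np.floor(k * logratio_trim) + 1
    hi_m = k + 1 - lo_m
    lo_a = np.floor(k * abs_trim) + 1
    hi_a = k + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


# ---------------------------------------------------------------------------
# Paired tests on mapped-read totals
# ---------------------------------------------------------------------------

def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided paired t test; returns (t, df, p).

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y and df = n - 1. Identical
    pairs everywhere (zero variance of differences) is an error, not p = 0.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("paired t test needs at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("all paired differences identical; t statistic undefined")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float] | None = None
                         ) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test; returns (W, p).

    Zero differences are dropped. The exact null distribution is used for
    n <= 25 remaining pairs, a normal approximation with continuity
    correction above.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero")
    method = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Default-vs-informed comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Per-gene and per-region comparison of informed vs default expression."""

    fold_change: pd.DataFrame  # per gene: mean log2 (informed - default), overall + per group
    region_summary: pd.DataFrame | None = None
    tests: dict = field(default_factory=dict)


def per_gene_fold_change(
    informed: ExprMatrix,
    default: ExprMatrix,
    groups: Mapping[str, str] | None = None,
) -> ComparisonResult:
    """Mean per-gene log2 fold change of informed minus default, by sample.

    Samples are paired by id; a positive value means higher expression under
    the SCC-informed quantification. When ``groups`` maps samples to e.g. sex
    labels, per-group means are reported alongside the overall mean.
    """
    if set(informed.samples) != set(default.samples):
        raise ValueError("informed and default matrices have different sample sets")
    common = [g for g in informed.genes if g in set(default.genes)]
    diff = informed.values.loc[common] - default.values.loc[common, informed.samples]
    out = pd.DataFrame({"log2fc_mean": diff.mean(axis=1)})
    if groups is not None:
        gser = pd.Series({s: groups[s] for s in informed.samples})
        for g in sorted(gser.unique()):
            members = gser.index[gser == g]
            out[f"log2fc_{g}"] = diff[members].mean(axis=1)
    return ComparisonResult(fold_change=out)


def region_summary(
    expr: ExprMatrix,
    regions: Mapping[str, RegionLabel | str],
    groups: Mapping[str, str] | None = None,
    cpm_values: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-region (x group) mean/median of log2-CPM and, optionally, CPM.

    Every gene must carry a region label. Regions with zero genes are simply
    absent from the output. Rows are (region, group) with columns
    mean_logcpm / median_logcpm and mean_cpm / median_cpm when CPM values are
    supplied.
    """
    missing = [g for g in expr.genes if g not in regions]
    if missing:
        raise KeyError(f"genes without region labels: {missing[:5]}...")
    label = pd.Series({g: str(getattr(regions[g], "value", regions[g]))
                       for g in expr.genes})
    gser = None
    if groups is not None:
        gser = pd.Series({s: groups[s] for s in expr.samples})

    rows = []
    for region in sorted(label.unique()):
        genes = label.index[label == region]
        sub = expr.values.loc[genes]
        groups_iter = [("all", list(expr.samples))]
        if gser is not None:
            groups_iter += [(g, list(gser.index[gser == g])) for g in sorted(gser.unique())]
        for gname, members in groups_iter:
            vals = sub[members].to_numpy().ravel()
            row = {
                "region": region,
                "group": gname,
                "n_genes": len(genes),
                "mean_logcpm": float(np.mean(vals)),
                "median_logcpm": float(np.median(vals)),
            }
            if cpm_values is not None:
                cv = cpm_values.loc[genes, members].to_numpy().ravel()
                row["mean_cpm"] = float(np.mean(cv))
                row["median_cpm"] = float(np.median(cv))
            rows.append(row)
    return pd.DataFrame(rows)


def region_ratio_table(
    informed_summary: pd.DataFrame, default_summary: pd.DataFrame
) -> pd.DataFrame:
    """Ratio of mean CPM (informed/default) per region x group."""
    key = ["region", "group"]
    merged = informed_summary.merge(
        default_summary, on=key, suffixes=("_informed", "_default")
    )
    if "mean_cpm_informed" in merged:
        merged["cpm_mean_ratio"] = merged["mean_cpm_informed"] / merged["mean_cpm_default"]
    merged["logcpm_mean_diff"] = (
        merged["mean_logcpm_informed"] - merged["mean_logcpm_default"]
    )
    return merged
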