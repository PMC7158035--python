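"""Negative-binomial differential expression with consensus calling.

A deliberately transparent NB pipeline in the DESeq2 mould: median-of-ratios
size factors, a method-of-moments gene dispersion shrunk 50/50 (log scale)
toward a mean-dispersion trend, a per-strand NB log-linear model with
log-size-factor offsets, and a Wald test on the contrast coefficient.
Tissue specificity uses the conservative all-pairwise consensus rule: a
strand is up (down) in a tissue only if significantly higher (lower) than
every other sample type, and any call must be backed by at least one
replicate triplet totalling 30 raw reads.  Age contrasts are reported as
adult relative to pup.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import CountMatrix

LN2 = np.log(2.0)
MIN_DISP, MAX_DISP = 1e-8, 20.0


# ---------------------------------------------------------------------------
# normalization


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios normalization factors."""
    log_counts = np.log(counts.where(counts > 0))
    all_pos = counts.gt(0).all(axis=1)
    if all_pos.any():
        log_gm = log_counts.loc[all_pos].mean(axis=1)
        ratios = log_counts.loc[all_pos].sub(log_gm, axis=0)
    else:
        warnings.warn("no strand with all-positive counts; falling back to "
                      "positive-subset geometric means")
        log_gm = log_counts.mean(axis=1)
        ratios = log_counts.sub(log_gm, axis=0)
    sf = np.exp(ratios.median(axis=0, skipna=True))
    return sf / np.exp(np.log(sf).mean())


# ---------------------------------------------------------------------------
# dispersion


def estimate_dispersions(counts: pd.DataFrame, sf: pd.Series,
                         cells: pd.Series, shrink_weight: float = 0.5):
    """Per-strand NB dispersion: method-of-moments within design cells,
    shrunk `shrink_weight`/(1-shrink_weight) on the log scale toward a
    mean-dispersion trend binned over mean normalized count."""
    q = counts.div(sf, axis=1)
    inv_sf = 1.0 / sf
    raw = np.full(len(counts), np.nan)
    means = q.mean(axis=1).to_numpy()
    cell_ids = cells.to_numpy()
    qv = q.to_numpy()
    for i in range(qv.shape[0]):
        num = den = 0.0
        for cell in np.unique(cell_ids):
            idx = cell_ids == cell
            n = int(idx.sum())
            if n < 2:
                continue
            x = qv[i, idx]
            m = x.mean()
            v = x.var(ddof=1)
            w = n - 1
            num += w * (v - m * inv_sf[idx].mean())
            # m*m overstates mu^2 by var(m) = v/n at small n; correct it
            den += w * max(m * m - v / n, 0.0)
        if den > 0:
            raw[i] = num / den
    raw = np.clip(np.nan_to_num(raw, nan=MIN_DISP), MIN_DISP, MAX_DISP)

    ok = means > 0
    if ok.sum() >= 20:
        order = np.argsort(means[ok])
        idx_ok = np.flatnonzero(ok)[order]
        n_bins = min(10, max(2, ok.sum() // 50))
        bins = np.array_split(idx_ok, n_bins)
        bx = np.array([means[b].mean() for b in bins])
        by = np.array([max(raw[b].mean(), MIN_DISP) for b in bins])
        trend = np.interp(means, bx, by)
    else:
        trend = np.full(len(raw), max(raw[ok].mean() if ok.any() else 0.1,
                                      MIN_DISP))
    shrunk = np.exp((1 - shrink_weight) * np.log(raw)
                    + shrink_weight * np.log(np.clip(trend, MIN_DISP, MAX_DISP)))
    return pd.Series(np.clip(shrunk, MIN_DISP, MAX_DISP), index=counts.index)


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class _Design:
    X: np.ndarray
    columns: list[str]


def _design_matrix(samples: pd.DataFrame, factors: tuple[str, ...]) -> _Design:
    cols = ["intercept"]
    mats = [np.ones((len(samples), 1))]
    for factor in factors:
        levels = sorted(samples[factor].unique())
        for lvl in levels[1:]:
            cols.append(f"{factor}[{lvl}]")
            mats.append((samples[factor] == lvl).to_numpy()[:, None].astype(float))
    return _Design(np.hstack(mats), cols)


def _contrast_vector(design: _Design, factor: str, g1: str, g2: str) -> np.ndarray:
    c = np.zeros(len(design.columns))
    for name, g, sign in ((f"{factor}[{g2}]", g2, 1.0), (f"{factor}[{g1}]", g1, -1.0)):
        if name in design.columns:
            c[design.columns.index(name)] = sign
    if not c.any():
        raise ValueError(f"contrast {factor}:{g1} vs {g2} not identifiable")
    return c


def _fit_strand(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float):
    fam = sm.families.NegativeBinomial(alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100, tol=1e-9)
            return res.params, res.cov_params()
        except Exception:
            return None, None


def nb_test(
    cm: CountMatrix,
    design_factors: tuple[str, ...],
    contrast: tuple[str, str, str],
    dispersions: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-strand NB Wald test of `contrast` = (factor, group1, group2);
    the reported log2FC is group2 relative to group1."""
    counts = cm.counts
    sf = size_factors(counts)
    offset = np.log(sf.to_numpy())
    cells = cm.samples[list(design_factors)].astype(str).agg("|".join, axis=1)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, sf, cells)
    design = _design_matrix(cm.samples, design_factors)
    cvec = _contrast_vector(design, *contrast)
    factor, g1, g2 = contrast

    q = counts.div(sf, axis=1)
    in_g1 = (cm.samples[factor] == g1).to_numpy()
    in_g2 = (cm.samples[factor] == g2).to_numpy()

    rows = []
    yv = counts.to_numpy(dtype=float)
    for i, strand in enumerate(counts.index):
        y = yv[i]
        mean1 = q.iloc[i, in_g1].mean()
        mean2 = q.iloc[i, in_g2].mean()
        if y.sum() == 0:
            rows.append({"strand": strand, "log2FC": np.nan, "se": np.nan,
                         "p": np.nan, "mean_group1": mean1, "mean_group2": mean2})
            continue
        beta, cov = _fit_strand(y, design.X, offset, float(dispersions.iloc[i]))
        if beta is None:
            rows.append({"strand": strand, "log2FC": np.nan, "se": np.nan,
                         "p": np.nan, "mean_group1": mean1, "mean_group2": mean2})
            continue
        est = float(cvec @ beta)
        var = float(cvec @ cov @ cvec)
        se = np.sqrt(max(var, 0.0))
        z = est / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"strand": strand, "log2FC": est / LN2, "se": se / LN2,
                     "p": p, "mean_group1": mean1, "mean_group2": mean2})
    out = pd.DataFrame(rows).set_index("strand")
    out["contrast"] = f"{factor}:{g2}_vs_{g1}"
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# BH


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up with monotonicity; NaNs are passed
    through and excluded from the number of tests."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


# ---------------------------------------------------------------------------
# pairwise tissue contrasts and the consensus rule


def pairwise_tissue_de(cm: CountMatrix, age_factor: bool = True):
    """All 6 pairwise sample-type contrasts from a joint 4-level model with
    age as an additive fixed factor.  Keys are (t1, t2) with log2FC of t2
    relative to t1."""
    tissues = sorted(cm.samples["sample_type"].unique())
    factors = ("sample_type", "age") if age_factor else ("sample_type",)
    sf = size_factors(cm.counts)
    cells = cm.samples[list(factors)].astype(str).agg("|".join, axis=1)
    disp = estimate_dispersions(cm.counts, sf, cells)
    out = {}
    for t1, t2 in itertools.combinations(tissues, 2):
        out[(t1, t2)] = nb_test(cm, factors, ("sample_type", t1, t2),
                                dispersions=disp)
    return out


def tissue_consensus(
    pairwise: dict,
    cm: CountMatrix,
    alpha: float = 0.05,
    min_triplet: int = 30,
) -> pd.DataFrame:
    """Consensus tissue-specific calls.

    A strand is up (down) in tissue T iff q <= alpha with T-consistent sign
    in all 3 pairwise comparisons involving T.  Calls without any
    (sample_type, age) replicate triplet totalling `min_triplet` raw reads
    are dropped; the number dropped is recorded in ``.attrs['n_filtered']``.
    """
    tissues = sorted(cm.samples["sample_type"].unique())
    for t1, t2 in itertools.combinations(tissues, 2):
        if (t1, t2) not in pairwise and (t2, t1) not in pairwise:
            raise ValueError(f"missing pairwise contrast {t1} vs {t2}")
    rows = []
    n_filtered = 0
    for tissue in tissues:
        others = [t for t in tissues if t != tissue]
        for strand in cm.counts.index:
            signs, qs = [], []
            ok = True
            for other in others:
                if (tissue, other) in pairwise:
                    res = pairwise[(tissue, other)].loc[strand]
                    lfc = -res["log2FC"]  # orient as tissue relative to other
                else:
                    res = pairwise[(other, tissue)].loc[strand]
                    lfc = res["log2FC"]
                if np.isnan(res["p"]) or res["q"] > alpha or lfc == 0:
                    ok = False
                    break
                signs.append(np.sign(lfc))
                qs.append(res["q"])
            if not ok or len(set(signs)) != 1:
                continue
            direction = "up" if signs[0] > 0 else "down"
            passed = cm.triplet_max_total(strand) >= min_triplet
            if not passed:
                n_filtered += 1
                continue
            rows.append({"strand": strand, "sample_type": tissue,
                         "direction": direction, "max_q": max(qs),
                         "passed_read_filter": True})
    out = pd.DataFrame(rows, columns=["strand", "sample_type", "direction",
                                      "max_q", "passed_read_filter"])
    out.attrs["n_filtered"] = n_filtered
    return out


def age_de(
    cm: CountMatrix,
    scope: str = "all_tissues",
    alpha: float = 0.05,
    min_triplet: int = 30,
):
    """Adult-vs-pup contrasts (positive log2FC = higher in adults).

    scope='all_tissues': one joint contrast with sample type as an additive
    fixed factor.  scope='per_tissue': the model refit on each tissue's
    subset.  The >=30-read triplet filter removes significant calls lacking
    a well-covered replicate triplet.
    """
    def finalize(res: pd.DataFrame, sub: CountMatrix) -> pd.DataFrame:
        res = res.copy()
        passed = np.array([sub.triplet_max_total(s) >= min_triplet
                           for s in res.index])
        sig = (res["q"] <= alpha) & ~res["q"].isna()
        res["significant"] = sig & passed
        res["filtered_by_reads"] = sig & ~passed
        return res

    if scope == "all_tissues":
        res = nb_test(cm, ("age", "sample_type"), ("age", "pup", "adult"))
        return finalize(res, cm)
    if scope == "per_tissue":
        out = {}
        for tissue in sorted(cm.samples["sample_type"].unique()):
            sub = cm.subset_samples(cm.samples["sample_type"] == tissue)
            if sub.samples["age"].nunique() < 2:
                raise ValueError(f"both ages required in tissue {tissue}")
            res = nb_test(sub, ("age",), ("age", "pup", "adult"))
            out[tissue] = finalize(res, sub)
        return out
    raise ValueError(f"unknown scope {scope!r}")
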