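"""Methylation–expression association and tumor/normal contrasts.

Expression of a gene measured by several array probes is summarized as the
first principal component (PC1) across samples, sign-oriented to agree with
the probe of highest standard deviation and affinely rescaled to that probe's
mean and SD, so the score reads in expression units. Per-CpG methylation is
then related to the score with Pearson correlation and a two-sided t-test on
r (df = n − 2). Tumor vs paired normal methylation differences use a paired
t-test per probe, ranked by |t|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    probe: str
    r: float
    n: int
    t_stat: float
    p: float
    slope: float
    intercept: float


@dataclass
class PairedDiffResult:
    probe: str
    mean_tumor: float
    mean_normal: float
    mean_delta: float
    t_stat: float
    df: int
    p: float


def expression_pc1(submatrix: pd.DataFrame) -> pd.Series:
    """PC1 score per sample for one gene's probe × sample expression block.

    The matrix is centred per probe; PC1 is taken over samples, oriented to
    correlate positively with the highest-SD probe, and rescaled to that
    probe's mean and SD. A single-probe block returns the probe itself.
    """
    if submatrix.shape[0] < 1 or submatrix.shape[1] < 3:
        raise ValueError("need >= 1 probe and >= 3 samples")
    X = submatrix.to_numpy(dtype=float)  # probes x samples
    sds = X.std(axis=1, ddof=1)
    if not np.any(sds > 0):
        raise ValueError("zero total variance in expression block")
    top = int(np.argmax(sds))
    centered = X - X.mean(axis=1, keepdims=True)
    # PC1 over samples: leading right-singular vector of the centred block
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    score = vt[0]
    # orient toward the top-SD probe, then rescale to its moments
    ref = X[top]
    corr = np.corrcoef(score, ref)[0, 1]
    if corr < 0:
        score = -score
    score_sd = score.std(ddof=1)
    if score_sd == 0:
        raise ValueError("degenerate PC1 with zero variance")
    score = ref.mean() + ref.std(ddof=1) * (score - score.mean()) / score_sd
    return pd.Series(score, index=submatrix.columns, name="pc1")


def correlate_methylation_expression(
    beta: pd.Series, score: pd.Series
) -> CorrelationResult | None:
    """Pearson r between one CpG's β and the expression score, with t-based p.

    Pairs with missing values are dropped; returns None with a warning when
    fewer than 3 complete pairs remain or either vector is constant.
    """
    df = pd.concat([beta, score], axis=1, join="inner").dropna()
    n = len(df)
    if n < 3:
        logger.warning("probe %s: fewer than 3 complete pairs", beta.name)
        return None
    x = df.iloc[:, 0].to_numpy(dtype=float)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        logger.warning("probe %s: zero variance, correlation undefined", beta.name)
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t, p = np.inf * np.sign(r), 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationResult(
        probe=str(beta.name), r=r, n=n, t_stat=float(t), p=p,
        slope=float(slope), intercept=float(intercept),
    )


def correlate_region(
    beta_matrix: pd.DataFrame, probes: list[str], score: pd.Series
) -> list[CorrelationResult]:
    """Per-CpG correlation for every probe of a region (samples × probes β)."""
    out = []
    for p in probes:
        res = correlate_methylation_expression(beta_matrix[p], score)
        if res is not None:
            out.append(res)
    return out


def paired_tumor_normal(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    use_wilcoxon: bool = False,
) -> list[PairedDiffResult]:
    """Paired per-probe tumor-vs-normal methylation contrast, ranked by |t|.

    ``tumor`` and ``normal`` are samples × probes β frames sharing probe
    columns; ``pairs`` maps tumor sample id to its normal counterpart
    (defaults to identical sample ids). With ``use_wilcoxon`` a signed-rank
    test replaces the paired t (the statistic column then holds W).
    """
    if pairs is None:
        common = [s for s in tumor.index if s in set(normal.index)]
        pairs = [(s, s) for s in common]
    if len(pairs) < 3:
        raise ValueError("need >= 3 complete pairs")
    t_idx = [a for a, _ in pairs]
    n_idx = [b for _, b in pairs]
    probes = [p for p in tumor.columns if p in set(normal.columns)]
    results = []
    for probe in probes:
        tv = tumor.loc[t_idx, probe].to_numpy(dtype=float)
        nv = normal.loc[n_idx, probe].to_numpy(dtype=float)
        keep = np.isfinite(tv) & np.isfinite(nv)
        tv, nv = tv[keep], nv[keep]
        if tv.size < 3:
            continue
        delta = tv - nv
        df = tv.size - 1
        if np.allclose(delta, 0):
            stat, p = 0.0, 1.0
        elif use_wilcoxon:
            stat, p = stats.wilcoxon(tv, nv)
        elif delta.std(ddof=1) < 1e-12:
            stat = np.inf * np.sign(delta.mean())
            p = 0.0
        else:
            stat, p = stats.ttest_rel(tv, nv)
        results.append(
            PairedDiffResult(
                probe=probe,
                mean_tumor=float(tv.mean()),
                mean_normal=float(nv.mean()),
                mean_delta=float(delta.mean()),
                t_stat=float(stat),
                df=df,
                p=float(p),
            )
        )
    results.sort(key=lambda r: -abs(r.t_stat))
    return results


def correlations_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(r) for r in results],
        columns=["probe", "r", "n", "t_stat", "p", "slope", "intercept"],
    )


def paired_to_frame(results: list[PairedDiffResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(r) for r in results],
        columns=["probe", "mean_tumor", "mean_normal", "mean_delta", "t_stat", "df", "p"],
    )
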